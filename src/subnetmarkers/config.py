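"""Run configuration for subnetwork marker discovery."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict


@dataclass
class RunConfig:
    """Tunable parameters of the marker discovery pipeline.

    Parameters
    ----------
    theta : float
        Trade-off between per-gene discriminative power and inter-member
        LLR correlation in path scoring. ``math.inf`` reduces the path
        score to the average absolute t-score of the members.
    max_path_length : int
        Maximum number of nodes in a linear path explored by the
        dynamic-programming search (L).
    beam_width : int
        Number of top-scoring partial paths retained per (node, length)
        during the search (M).
    top_paths : int
        Number of top scoring finished paths pooled for greedy assembly (m).
    length_range : tuple[int, int]
        Inclusive (L_min, L_max) node-count range of paths admitted to the
        assembly pool.
    epsilon : float
        Relative improvement a merge must exceed to be accepted:
        a union is kept iff R_new > (1 + epsilon) * R_old.
    marker_count : int
        Number of non-overlapping subnetwork markers to extract (k).
    rng_seed : int
        Seed for every stochastic step downstream.
    t_test : str
        ``"welch"`` (unequal variances, default) or ``"student"``
        (pooled variance) two-sample t statistic.
    norm_exponent : int
        Path score normalization: S = s / l**norm_exponent. 1 makes the
        theta -> inf score the plain average |t|; 2 is available as a
        stronger length penalty.
    multi_pass : bool
        If True, the greedy path-combination step rescans the ranked path
        list until no merge is accepted; default is a single ordered pass.
    sigma_floor_factor : float
        Per-gene/class standard deviations are floored at this factor
        times the global standard deviation of the expression matrix.
    """

    theta: float = 8.0
    max_path_length: int = 8
    beam_width: int = 20
    top_paths: int = 100
    length_range: tuple[int, int] = (5, 8)
    epsilon: float = 0.01
    marker_count: int = 50
    rng_seed: int = 0
    t_test: str = "welch"
    norm_exponent: int = 1
    multi_pass: bool = False
    sigma_floor_factor: float = 1e-6

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (self.theta >= 0 or math.isinf(self.theta)):
            raise ValueError(f"theta must be >= 0 or inf, got {self.theta}")
        if self.max_path_length < 1:
            raise ValueError("max_path_length must be >= 1")
        if self.beam_width < 1:
            raise ValueError("beam_width must be >= 1")
        if self.top_paths < 1:
            raise ValueError("top_paths must be >= 1")
        lo, hi = self.length_range
        if lo > hi:
            raise ValueError(f"length_range must be (lo, hi) with lo <= hi, got {self.length_range}")
        if lo < 1:
            raise ValueError("length_range lower bound must be >= 1")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.marker_count < 1:
            raise ValueError("marker_count must be >= 1")
        if self.t_test not in ("welch", "student"):
            raise ValueError(f"t_test must be 'welch' or 'student', got {self.t_test!r}")
        if self.norm_exponent not in (1, 2):
            raise ValueError("norm_exponent must be 1 or 2")
        if self.sigma_floor_factor <= 0:
            raise ValueError("sigma_floor_factor must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["length_range"] = list(self.length_range)
        d["theta"] = "inf" if math.isinf(self.theta) else self.theta
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "theta" in d and isinstance(d["theta"], str):
            d["theta"] = math.inf if d["theta"].lower() in ("inf", "infinity") else float(d["theta"])
        if "length_range" in d:
            d["length_range"] = tuple(d["length_range"])
        return cls(**d)
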
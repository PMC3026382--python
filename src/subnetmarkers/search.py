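"""Beam dynamic programming over linear paths.

For every node v and every length l <= L the table keeps the top-M
highest-scoring simple paths of l nodes ending at v. Because the
correlation-coupled score admits no exact additive recurrence, each
candidate extension is re-scored in full; the beam (width M) is what
keeps the search tractable. With M at least the number of simple paths
per (node, length), the search is exhaustive.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .config import RunConfig
from .datasets import ValidationError

logger = logging.getLogger(__name__)

# above this many scoreable genes the full gene-gene correlation matrix is
# not materialised and candidate correlations are built from the
# standardized LLR rows instead
_DENSE_CORR_LIMIT = 3000


@dataclass
class LinearPath:
    """An ordered, duplicate-free, adjacency-respecting gene sequence."""

    genes: tuple[str, ...]
    raw_score: float
    score: float | None = None

    def __len__(self) -> int:
        return len(self.genes)


class PathTable:
    """DP table: (node, length) -> paths sorted by raw score descending."""

    def __init__(self, max_length: int, beam_width: int) -> None:
        self.max_length = max_length
        self.beam_width = beam_width
        self._entries: dict[tuple[str, int], list[LinearPath]] = {}

    def get(self, node: str, length: int) -> list[LinearPath]:
        return self._entries.get((node, length), [])

    def set(self, node: str, length: int, paths: list[LinearPath]) -> None:
        self._entries[(node, length)] = paths

    def best(self, node: str, length: int) -> LinearPath | None:
        paths = self.get(node, length)
        return paths[0] if paths else None

    def items(self) -> Iterator[tuple[tuple[str, int], list[LinearPath]]]:
        return iter(self._entries.items())

    def all_paths(self) -> Iterator[LinearPath]:
        for paths in self._entries.values():
            yield from paths


class _PathScorer:
    """Vectorised raw-score evaluation of batches of candidate paths."""

    def __init__(self, llr_values: np.ndarray, abs_t: np.ndarray, theta: float):
        from .scoring import standardize_rows

        self.theta = theta
        self.abs_t = abs_t
        self.z = standardize_rows(llr_values)
        n = llr_values.shape[0]
        if n <= _DENSE_CORR_LIMIT:
            self.corr: np.ndarray | None = self.z @ self.z.T
            np.fill_diagonal(self.corr, 1.0)
        else:
            self.corr = None

    def raw_scores(self, cand: np.ndarray) -> np.ndarray:
        """Raw scores for candidates given as an (n_cand, l) index array."""
        t = self.abs_t[cand]
        if math.isinf(self.theta):
            return t.sum(axis=1)
        l = cand.shape[1]
        if l == 1:
            return t[:, 0]
        if self.corr is not None:
            p = self.corr[cand[:, :, None], cand[:, None, :]]
        else:
            zc = self.z[cand]
            p = zc @ zc.transpose(0, 2, 1)
            idx = np.arange(l)
            p[:, idx, idx] = 1.0
        num = (t * p.sum(axis=2)).sum(axis=1) + (self.theta - 1.0) * t.sum(axis=1)
        return num / (l - 1.0 + self.theta)


def dp_search(
    network: nx.Graph,
    t_alpha: Mapping[str, float] | pd.Series,
    llr: pd.DataFrame,
    config: RunConfig,
) -> PathTable:
    """Fill the beam DP table over the given network.

    ``t_alpha`` maps genes to their (possibly signed) LLR t-scores;
    absolute values are used. Network nodes absent from the LLR matrix
    are skipped with a logged count.
    """
    nodes = [v for v in network.nodes if v in llr.index]
    skipped = network.number_of_nodes() - len(nodes)
    if skipped:
        logger.warning("%d network node(s) have no expression data and were skipped", skipped)
    node_set = set(nodes)
    index = {g: i for i, g in enumerate(llr.index)}
    abs_t = np.zeros(len(llr.index))
    for g in nodes:
        abs_t[index[g]] = abs(float(t_alpha[g]))
    scorer = _PathScorer(llr.to_numpy(dtype=float), abs_t, config.theta)

    table = PathTable(config.max_path_length, config.beam_width)
    for v in nodes:
        table.set(v, 1, [LinearPath((v,), abs_t[index[v]])])

    for l in range(2, config.max_path_length + 1):
        for v in nodes:
            cands: list[tuple[str, ...]] = []
            for u in network.neighbors(v):
                if u not in node_set:
                    continue
                for p in table.get(u, l - 1):
                    if v not in p.genes:
                        cands.append(p.genes + (v,))
            if not cands:
                continue
            idx = np.array([[index[g] for g in c] for c in cands], dtype=np.intp)
            scores = scorer.raw_scores(idx)
            order = sorted(range(len(cands)), key=lambda i: (-scores[i], cands[i]))
            keep = order[: config.beam_width]
            table.set(v, l, [LinearPath(cands[i], float(scores[i])) for i in keep])
    return table


def finalize_scores(table: PathTable, norm_exponent: int = 1) -> PathTable:
    """Attach the length-normalised score S = s / l**exp to every entry."""
    for (_, l), paths in table.items():
        for p in paths:
            p.score = p.raw_score / l**norm_exponent
    return table


def collect_top_paths(
    table: PathTable, m: int, length_range: tuple[int, int]
) -> list[LinearPath]:
    """Pool finalized paths within the length range, deduplicate
    orientation (a path and its reversal score identically), and return
    the top m by normalised score."""
    lo, hi = length_range
    pool: dict[tuple[str, ...], LinearPath] = {}
    for (_, l), paths in table.items():
        if not (lo <= l <= hi):
            continue
        for p in paths:
            if p.score is None:
                raise ValidationError("table not finalized; call finalize_scores first")
            canon = min(p.genes, p.genes[::-1])
            prev = pool.get(canon)
            if prev is None or (p.score, p.genes) > (prev.score, prev.genes):
                pool[canon] = p
    if not pool:
        raise ValidationError(
            f"no stored path has length in [{lo}, {hi}]; relax length_range "
            "or increase max_path_length"
        )
    ranked = sorted(pool.values(), key=lambda p: (-p.score, p.genes))
    return ranked[:m]
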
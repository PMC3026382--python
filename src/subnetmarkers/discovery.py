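"""Scikit-learn style estimators for LLR activity and marker discovery.

Both estimators follow the sklearn convention of samples x features (here
features are genes); the library's internal containers are genes x
samples and are transposed at the boundary. ``LLRTransformer`` turns raw
expression into per-gene log-likelihood ratios; ``SubnetworkMarkerDiscovery``
fits the whole discovery pipeline and transforms expression into a
samples x markers activity matrix that composes with sklearn pipelines
(e.g. followed by ``LogisticRegression``).
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .activity import (
    GaussianParams,
    _estimate_params_array,
    gene_t_scores,
    llr_transform,
)
from .config import RunConfig
from .datasets import ValidationError
from .search import collect_top_paths, dp_search, finalize_scores

logger = logging.getLogger(__name__)


def _check_X_y(X, y, gene_ids=None):
    """Validate samples x genes input; returns (values, labels, gene_ids).

    ``y`` must contain exactly the phenotype codes 1 and 2; gene ids come
    from, in order of priority: the explicit argument, DataFrame columns,
    or positional names ``g0``, ``g1``, ...
    """
    if isinstance(X, pd.DataFrame):
        if gene_ids is None:
            gene_ids = [str(c) for c in X.columns]
        X = X.to_numpy()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError(f"X must be 2-dimensional, got shape {X.shape}")
    y = np.asarray(y)
    if y.shape != (X.shape[0],):
        raise ValidationError("y length must equal the number of rows (samples) of X")
    classes = set(np.unique(y).tolist())
    if classes != {1, 2}:
        raise ValidationError(f"y must contain phenotypes 1 and 2, found {sorted(classes)}")
    y = y.astype(int)
    for k in (1, 2):
        if int((y == k).sum()) < 2:
            raise ValidationError(f"phenotype class {k} has fewer than 2 samples")
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(X.shape[1])]
    if len(gene_ids) != X.shape[1]:
        raise ValidationError("gene_ids length must equal the number of columns of X")
    return X, y, list(gene_ids)


class LLRTransformer(TransformerMixin, BaseEstimator):
    """Per-gene Gaussian log-likelihood ratio transform.

    ``fit`` estimates class-conditional means and (floored) standard
    deviations per gene; ``transform`` maps expression values to LLRs.
    Positive output favours phenotype 1.

    Attributes
    ----------
    params_ : GaussianParams
        Fitted per-gene, per-phenotype parameters.
    gene_ids_ : list of str
        Feature names seen during fit.
    """

    def __init__(self, sigma_floor_factor: float = 1e-6):
        self.sigma_floor_factor = sigma_floor_factor

    def fit(self, X, y, gene_ids: Sequence[str] | None = None):
        X, y, gene_ids = _check_X_y(X, y, gene_ids)
        self.params_ = _estimate_params_array(X.T, y, gene_ids, self.sigma_floor_factor)
        self.gene_ids_ = gene_ids
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "params_")
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy()
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"X has {X.shape[1]} features; transformer was fitted with {self.n_features_in_}"
            )
        return llr_transform(X.T, self.params_).T

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "gene_ids_")
        return np.asarray([f"llr_{g}" for g in self.gene_ids_], dtype=object)


class SubnetworkMarkerDiscovery(TransformerMixin, BaseEstimator):
    """Discover non-overlapping discriminative subnetwork markers.

    ``fit`` runs the full pipeline on expression + labels over the given
    interaction network: LLR transform, per-gene t-scores, beam DP search
    for correlation-coherent high-|t| linear paths, greedy merge of
    overlapping paths, and iterated network pruning. ``transform`` maps
    (new) expression to the markers' summed-LLR activities, one column
    per marker, using the parameters fitted on the training samples.

    Parameters mirror :class:`subnetmarkers.config.RunConfig`; see there
    for meanings and defaults.

    Attributes
    ----------
    subnetworks_ : list of Subnetwork
        Markers in discovery order with members, activity, R and the
        greedy accept/reject trace.
    marker_members_ : list of tuple of str
        Sorted member genes per marker.
    marker_scores_ : ndarray
        Discriminative power R per marker (training data).
    llr_ : LLRTransformer
        The fitted LLR transform reused by ``transform``.
    """

    def __init__(
        self,
        network: nx.Graph | None = None,
        theta: float = 8.0,
        max_path_length: int = 8,
        beam_width: int = 20,
        top_paths: int = 100,
        length_min: int = 5,
        length_max: int = 8,
        epsilon: float = 0.01,
        n_markers: int = 50,
        t_test: str = "welch",
        norm_exponent: int = 1,
        multi_pass: bool = False,
        sigma_floor_factor: float = 1e-6,
        random_state: int = 0,
    ):
        self.network = network
        self.theta = theta
        self.max_path_length = max_path_length
        self.beam_width = beam_width
        self.top_paths = top_paths
        self.length_min = length_min
        self.length_max = length_max
        self.epsilon = epsilon
        self.n_markers = n_markers
        self.t_test = t_test
        self.norm_exponent = norm_exponent
        self.multi_pass = multi_pass
        self.sigma_floor_factor = sigma_floor_factor
        self.random_state = random_state

    @classmethod
    def from_config(cls, network: nx.Graph, config: RunConfig) -> "SubnetworkMarkerDiscovery":
        return cls(
            network=network,
            theta=config.theta,
            max_path_length=config.max_path_length,
            beam_width=config.beam_width,
            top_paths=config.top_paths,
            length_min=config.length_range[0],
            length_max=config.length_range[1],
            epsilon=config.epsilon,
            n_markers=config.marker_count,
            t_test=config.t_test,
            norm_exponent=config.norm_exponent,
            multi_pass=config.multi_pass,
            sigma_floor_factor=config.sigma_floor_factor,
            random_state=config.rng_seed,
        )

    def _config(self) -> RunConfig:
        return RunConfig(
            theta=self.theta,
            max_path_length=self.max_path_length,
            beam_width=self.beam_width,
            top_paths=self.top_paths,
            length_range=(self.length_min, self.length_max),
            epsilon=self.epsilon,
            marker_count=self.n_markers,
            rng_seed=self.random_state,
            t_test=self.t_test,
            norm_exponent=self.norm_exponent,
            multi_pass=self.multi_pass,
            sigma_floor_factor=self.sigma_floor_factor,
        )

    def fit(self, X, y, gene_ids: Sequence[str] | None = None):
        from .assembly import greedy_combine, prune_network
        from .datasets import ValidationError as VErr

        if self.network is None:
            raise ValidationError("an interaction network is required (network=...)")
        config = self._config()
        X, y, gene_ids = _check_X_y(X, y, gene_ids)

        self.llr_ = LLRTransformer(self.sigma_floor_factor).fit(X, y, gene_ids)
        llr = pd.DataFrame(self.llr_.transform(X).T, index=gene_ids)
        t_alpha = gene_t_scores(llr, y, kind=self.t_test)

        shared = set(self.network.nodes) & set(gene_ids)
        if not shared:
            raise ValidationError(
                "no overlap between network nodes and expression gene identifiers"
            )
        working = nx.Graph(self.network.subgraph(shared))

        subnetworks = []
        for _ in range(self.n_markers):
            if working.number_of_nodes() == 0:
                logger.warning("network exhausted after %d marker(s)", len(subnetworks))
                break
            table = dp_search(working, t_alpha, llr, config)
            finalize_scores(table, self.norm_exponent)
            try:
                top = collect_top_paths(
                    table, self.top_paths, (self.length_min, self.length_max)
                )
            except VErr:
                logger.warning(
                    "no admissible path left after %d marker(s); stopping early",
                    len(subnetworks),
                )
                break
            marker = greedy_combine(
                top, llr, y,
                epsilon=self.epsilon,
                t_test=self.t_test,
                multi_pass=self.multi_pass,
            )
            subnetworks.append(marker)
            working = prune_network(working, marker)
            working.remove_nodes_from(marker.members)

        if not subnetworks:
            raise ValidationError("no marker could be identified on this network")
        self.subnetworks_ = subnetworks
        self.marker_members_ = [tuple(sorted(m.members)) for m in subnetworks]
        self.marker_scores_ = np.array([m.R for m in subnetworks])
        self.gene_ids_ = gene_ids
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        """Samples x markers activity matrix under the fitted LLR params."""
        check_is_fitted(self, "subnetworks_")
        llr = self.llr_.transform(X)  # samples x genes
        col = {g: i for i, g in enumerate(self.gene_ids_)}
        out = np.empty((llr.shape[0], len(self.marker_members_)))
        for j, members in enumerate(self.marker_members_):
            out[:, j] = llr[:, [col[g] for g in members]].sum(axis=1)
        return out

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "subnetworks_")
        return np.asarray(
            [f"marker_{i + 1:03d}" for i in range(len(self.marker_members_))], dtype=object
        )
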
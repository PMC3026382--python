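"""Greedy combination of overlapping paths into non-overlapping markers.

The top-scoring path seeds a subnetwork; remaining paths are scanned in
rank order and a path sharing at least one gene with the current
subnetwork is merged iff the merge multiplies the discriminative power R
(absolute t of the summed-LLR activity) by more than (1 + epsilon). The
accepted subnetwork is then pruned out of the network and the search
repeats, yielding pairwise-disjoint markers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .activity import subnetwork_activity, t_statistic
from .config import RunConfig
from .datasets import ExpressionDataset, ValidationError
from .search import LinearPath

logger = logging.getLogger(__name__)


@dataclass
class Subnetwork:
    """A marker: gene set with its activity vector and power R."""

    members: frozenset[str]
    source_paths: list[LinearPath]
    activity: np.ndarray
    R: float
    trace: list[dict] = field(default_factory=list)


@dataclass
class MarkerSet:
    """Markers in discovery order; member sets are pairwise disjoint."""

    markers: list[Subnetwork]
    config: RunConfig


def greedy_combine(
    paths: Sequence[LinearPath],
    llr: pd.DataFrame,
    labels,
    epsilon: float = 0.01,
    t_test: str = "welch",
    multi_pass: bool = False,
) -> Subnetwork:
    """Merge ranked overlapping paths into one subnetwork.

    ``paths`` must be sorted by score descending. The scan is a single
    ordered pass by default: a path disjoint from the current subnetwork
    at its turn is skipped and not revisited. With ``multi_pass`` the
    scan repeats until a full pass accepts nothing.
    """
    paths = list(paths)
    if not paths:
        raise ValidationError("no paths to combine")
    if epsilon < 0:
        raise ValidationError("epsilon must be >= 0")

    members = set(paths[0].genes)
    sources = [paths[0]]
    r_current = abs(t_statistic(subnetwork_activity(members, llr), labels, kind=t_test))
    trace: list[dict] = [{"path": list(paths[0].genes), "action": "init", "R": r_current}]
    merged = {0}

    while True:
        accepted_any = False
        for i, path in enumerate(paths):
            if i in merged:
                continue
            overlap = members.intersection(path.genes)
            if not overlap:
                trace.append({"path": list(path.genes), "action": "skip", "R": r_current})
                continue
            candidate = members.union(path.genes)
            r_new = abs(
                t_statistic(subnetwork_activity(candidate, llr), labels, kind=t_test)
            )
            if r_new > (1.0 + epsilon) * r_current:
                members = candidate
                sources.append(path)
                merged.add(i)
                trace.append(
                    {
                        "path": list(path.genes),
                        "action": "accept",
                        "R_before": r_current,
                        "R_after": r_new,
                    }
                )
                r_current = r_new
                accepted_any = True
            else:
                trace.append(
                    {
                        "path": list(path.genes),
                        "action": "reject",
                        "R_before": r_current,
                        "R_candidate": r_new,
                    }
                )
        if not (multi_pass and accepted_any):
            break

    return Subnetwork(
        members=frozenset(members),
        source_paths=sources,
        activity=subnetwork_activity(members, llr),
        R=r_current,
        trace=trace,
    )


def prune_network(network: nx.Graph, subnetwork: Subnetwork | Sequence[str]) -> nx.Graph:
    """Remove every edge incident to a subnetwork member.

    Member nodes become isolated but are kept, mirroring the adjacency-
    matrix zeroing view of the update; callers that want them gone can
    drop zero-degree members afterwards.
    """
    members = subnetwork.members if isinstance(subnetwork, Subnetwork) else set(subnetwork)
    pruned = network.copy()
    to_drop = [e for e in pruned.edges if e[0] in members or e[1] in members]
    pruned.remove_edges_from(to_drop)
    return pruned


def identify_markers(
    network: nx.Graph, dataset: ExpressionDataset, config: RunConfig
) -> MarkerSet:
    """Full discovery loop: DP path search, greedy combination, network
    pruning, repeated for up to ``config.marker_count`` markers.

    Thin wrapper over :class:`subnetmarkers.discovery.SubnetworkMarkerDiscovery`.
    """
    from .discovery import SubnetworkMarkerDiscovery

    est = SubnetworkMarkerDiscovery.from_config(network, config)
    est.fit(dataset.values.T, dataset.labels, gene_ids=dataset.gene_ids)
    return MarkerSet(markers=list(est.subnetworks_), config=config)
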
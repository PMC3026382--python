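"""Seeded generators for networks and two-phenotype expression data with
planted, correlated, discriminative modules.

The generator emulates the statistical structure the discovery method
assumes: a sparse undirected interaction network containing a few
connected modules whose member genes are differentially expressed
between two phenotypes and share a per-sample latent factor (so their
LLRs are correlated), surrounded by background genes with no class
signal. A planted gene g in module q with effect size delta (in units of
within-class SD) and latent loading b is generated as

    x = s_g * ((delta/2) * c + b * z) + Normal(0, noise_sd)

where c = +1/-1 encodes the phenotype, z ~ Normal(0, 1) is shared by the
module within a sample, and s_g in {+1, -1} orients the gene (so modules
can mix up- and down-regulated members, which the LLR transform
re-aligns). The loading b is calibrated so the pooled-sample correlation
between two members — class separation included, balanced classes
assumed — hits rho_target:

    rho = (delta^2/4 + b^2) / (delta^2/4 + b^2 + noise_sd^2).

Targets below the b = 0 bound are infeasible and raise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from .datasets import ExpressionDataset, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PlantedTruth:
    """Ground truth of a simulation: modules, effect sizes, correlations."""

    modules: list[list[str]]
    delta: list[float]
    rho_target: list[float]
    loading: list[float]
    gene_signs: dict[str, int]
    noise_sd: float
    seed: int

    @property
    def planted_genes(self) -> set[str]:
        return {g for module in self.modules for g in module}

    def to_dict(self) -> dict:
        return {
            "modules": self.modules,
            "delta": self.delta,
            "rho_target": self.rho_target,
            "loading": self.loading,
            "gene_signs": self.gene_signs,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }


def generate_network(
    n_nodes: int,
    model: str = "erdos_renyi",
    p: float = 0.015,
    m_attach: int = 2,
    seed: int = 0,
) -> nx.Graph:
    """Random undirected simple graph with node ids ``g0001`` ...

    ``model`` is ``erdos_renyi`` (edge probability ``p``) or
    ``barabasi_albert`` (``m_attach`` edges per new node).
    """
    if n_nodes < 2:
        raise ValidationError("n_nodes must be >= 2")
    if model == "erdos_renyi":
        if not (0.0 <= p <= 1.0):
            raise ValidationError(f"edge probability must be in [0, 1], got {p}")
        graph = nx.gnp_random_graph(n_nodes, p, seed=seed)
    elif model == "barabasi_albert":
        if not (1 <= m_attach < n_nodes):
            raise ValidationError(f"m_attach must be in [1, n_nodes), got {m_attach}")
        graph = nx.barabasi_albert_graph(n_nodes, m_attach, seed=seed)
    else:
        raise ValidationError(f"unknown network model {model!r}")
    width = max(4, len(str(n_nodes)))
    return nx.relabel_nodes(graph, {i: f"g{i + 1:0{width}d}" for i in graph.nodes})


def plant_modules(
    network: nx.Graph,
    n_modules: int,
    module_size: int,
    seed: int = 0,
    delta: float | Sequence[float] = 2.0,
    rho_target: float | Sequence[float] = 0.5,
    noise_sd: float = 1.0,
) -> PlantedTruth:
    """Select disjoint connected subgraphs as planted modules.

    Modules grow by seeded random-walk expansion over unused nodes; if
    growth stalls, an edge from the module to a random unused node is
    added to the network (in place, logged). Effect sizes and correlation
    targets may be scalars or per-module sequences; the latent loading is
    calibrated here so infeasible targets fail fast.
    """
    if n_modules * module_size > network.number_of_nodes():
        raise ValidationError(
            f"cannot pack {n_modules} modules of size {module_size} into "
            f"{network.number_of_nodes()} nodes"
        )
    deltas = _per_module(delta, n_modules, "delta")
    rhos = _per_module(rho_target, n_modules, "rho_target")
    loadings = [
        _calibrate_loading(d, r, noise_sd) for d, r in zip(deltas, rhos)
    ]

    rng = np.random.default_rng(seed)
    unused = set(network.nodes)
    modules: list[list[str]] = []
    for _ in range(n_modules):
        module = _grow_module(network, unused, module_size, rng)
        unused -= set(module)
        modules.append(sorted(module))

    signs = {
        g: int(rng.choice([1, -1]))
        for module in modules
        for g in module
    }
    return PlantedTruth(
        modules=modules,
        delta=deltas,
        rho_target=rhos,
        loading=loadings,
        gene_signs=signs,
        noise_sd=noise_sd,
        seed=seed,
    )


def _per_module(value, n_modules: int, name: str) -> list[float]:
    if np.isscalar(value):
        return [float(value)] * n_modules
    values = [float(v) for v in value]
    if len(values) != n_modules:
        raise ValidationError(f"{name} must be scalar or length {n_modules}")
    return values


def _calibrate_loading(delta: float, rho: float, noise_sd: float) -> float:
    """Latent loading b hitting the pooled within-module correlation target."""
    if not (0.0 <= rho < 1.0):
        raise ValidationError(f"rho_target must be in [0, 1), got {rho}")
    base = delta**2 / 4.0
    rho_min = base / (base + noise_sd**2)
    needed = rho * noise_sd**2 / (1.0 - rho) - base
    if needed < -1e-12:
        raise ValidationError(
            f"rho_target={rho} is unattainable with delta={delta}, "
            f"noise_sd={noise_sd}: class separation alone induces "
            f"correlation {rho_min:.3f} (the feasible lower bound)"
        )
    return float(np.sqrt(max(needed, 0.0)))


def _grow_module(
    network: nx.Graph, unused: set[str], size: int, rng: np.random.Generator
) -> list[str]:
    """Random-walk growth of one connected module over unused nodes."""
    candidates = sorted(unused)
    start = candidates[int(rng.integers(len(candidates)))]
    module = [start]
    stalls = 0
    while len(module) < size:
        frontier = sorted(
            {n for g in module for n in network.neighbors(g)} & unused - set(module)
        )
        if frontier:
            module.append(frontier[int(rng.integers(len(frontier)))])
            continue
        # growth stalled: wire the module to a fresh unused node
        outside = sorted(unused - set(module))
        if not outside:
            raise ValidationError("module packing exhausted all nodes")
        new = outside[int(rng.integers(len(outside)))]
        anchor = module[int(rng.integers(len(module)))]
        network.add_edge(anchor, new)
        logger.info("module growth stalled; added edge %s-%s", anchor, new)
        module.append(new)
        stalls += 1
    return module


def generate_expression(
    truth: PlantedTruth,
    network: nx.Graph,
    n1: int = 100,
    n2: int = 100,
    noise_sd: float | None = None,
    seed: int = 0,
) -> ExpressionDataset:
    """Two-phenotype expression for every network node.

    Background genes are Normal(0, noise_sd) in both classes; planted
    genes follow the signed class-shift + latent-factor model in the
    module docstring. The first ``n1`` samples are phenotype 1.
    """
    if n1 < 3 or n2 < 3:
        raise ValidationError("need at least 3 samples per phenotype")
    noise_sd = truth.noise_sd if noise_sd is None else noise_sd
    rng = np.random.default_rng(seed)
    genes = sorted(network.nodes)
    n = n1 + n2
    c = np.concatenate([np.ones(n1), -np.ones(n2)])
    values = rng.normal(0.0, noise_sd, size=(len(genes), n))
    row = {g: i for i, g in enumerate(genes)}
    for module, delta, b in zip(truth.modules, truth.delta, truth.loading):
        z = rng.normal(0.0, 1.0, size=n)
        for g in module:
            s = truth.gene_signs[g]
            values[row[g]] += s * ((delta / 2.0) * c + b * z)
    return ExpressionDataset(
        gene_ids=genes,
        sample_ids=[f"s{j + 1:04d}" for j in range(n)],
        values=values,
        labels=np.concatenate([np.full(n1, 1), np.full(n2, 2)]).astype(int),
    )


def planted_fixture(
    n_nodes: int = 300,
    n_modules: int = 3,
    module_size: int = 6,
    delta: float = 2.0,
    rho_target: float = 0.5,
    n1: int = 100,
    n2: int = 100,
    noise_sd: float = 1.0,
    p: float = 0.015,
    seed: int = 42,
) -> tuple[nx.Graph, PlantedTruth, ExpressionDataset]:
    """The standard study conditions in one call: a 300-node sparse
    network with three planted 6-gene modules (delta = 2, rho = 0.5) and
    100 + 100 samples."""
    network = generate_network(n_nodes, "erdos_renyi", p=p, seed=seed)
    truth = plant_modules(
        network, n_modules, module_size, seed=seed,
        delta=delta, rho_target=rho_target, noise_sd=noise_sd,
    )
    dataset = generate_expression(truth, network, n1=n1, n2=n2, seed=seed + 1)
    return network, truth, dataset
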
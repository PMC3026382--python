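"""Domain containers and readers/writers.

Expression data is a genes x samples real matrix with a binary phenotype
label (1 or 2) per sample; the interaction network is an undirected simple
graph over the same gene/protein identifier namespace. Identifiers are
required to be pre-matched: no probe-to-gene or gene-to-protein mapping is
performed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Input violates a structural invariant."""


class ParseError(ValueError):
    """Input file could not be parsed."""


@dataclass
class ExpressionDataset:
    """Two-phenotype gene expression matrix.

    ``values`` is genes x samples; ``labels`` holds one phenotype in
    {1, 2} per sample. Both phenotype classes must contain at least two
    samples so that class-conditional variances are estimable.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = pd.Index(self.gene_ids)
            dupes = sorted(set(dupes[dupes.duplicated()]))
            raise ValidationError(f"duplicated gene identifiers: {dupes[:5]}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicated sample identifiers")
        if self.labels.shape != (len(self.sample_ids),):
            raise ValidationError("labels length does not match sample count")
        bad = set(np.unique(self.labels)) - {1, 2}
        if bad:
            raise ValidationError(f"phenotype labels must be 1 or 2, found {sorted(bad)}")
        for k in (1, 2):
            if int(np.sum(self.labels == k)) < 2:
                raise ValidationError(
                    f"phenotype class {k} has fewer than 2 samples; "
                    "variance estimation requires >= 2 per class"
                )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def class_indices(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.labels == k)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_samples(self, idx: Sequence[int]) -> "ExpressionDataset":
        idx = np.asarray(idx, dtype=int)
        return ExpressionDataset(
            gene_ids=self.gene_ids,
            sample_ids=[self.sample_ids[i] for i in idx],
            values=self.values[:, idx],
            labels=self.labels[idx],
        )


def read_expression(matrix_path: str | Path, labels_path: str | Path) -> ExpressionDataset:
    """Read a genes x samples TSV (header = sample ids) and a two-column
    (sample_id, phenotype) labels TSV into a validated dataset.

    Samples present in the matrix but absent from the labels file are
    dropped with a warning; labels for unknown samples are ignored with a
    warning.
    """
    matrix_path, labels_path = Path(matrix_path), Path(labels_path)
    try:
        df = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"cannot read expression matrix {matrix_path}: {exc}") from exc
    try:
        values = df.astype(float)
    except ValueError:
        for gene, row in df.iterrows():
            for sample, cell in row.items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ParseError(
                        f"non-numeric expression value {cell!r} at gene {gene!r}, "
                        f"sample {sample!r} in {matrix_path}"
                    ) from None
        raise
    if values.index.duplicated().any():
        dupes = sorted(set(values.index[values.index.duplicated()]))
        raise ValidationError(
            f"duplicated gene row identifiers in {matrix_path}: {dupes[:5]}; "
            "collapse multi-probe genes upstream"
        )

    labels = _read_labels(labels_path)
    matrix_samples = [str(s) for s in values.columns]
    kept = [s for s in matrix_samples if s in labels]
    dropped = [s for s in matrix_samples if s not in labels]
    if dropped:
        logger.warning(
            "%d sample(s) in %s have no phenotype label and were dropped: %s",
            len(dropped), matrix_path.name, dropped[:5],
        )
    extra = sorted(set(labels) - set(matrix_samples))
    if extra:
        logger.warning("%d labelled sample(s) absent from the matrix were ignored", len(extra))
    if not kept:
        raise ValidationError("no sample is shared between the matrix and the labels file")
    return ExpressionDataset(
        gene_ids=[str(g) for g in values.index],
        sample_ids=kept,
        values=values[kept].to_numpy(dtype=float),
        labels=np.array([labels[s] for s in kept], dtype=int),
    )


def _read_labels(path: Path) -> dict[str, int]:
    labels: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected two tab-separated columns")
            sample, phen = parts[0].strip(), parts[1].strip()
            try:
                value = int(float(phen))
            except ValueError:
                if lineno == 1:  # tolerate a header row
                    continue
                raise ParseError(f"{path}:{lineno}: phenotype {phen!r} is not numeric") from None
            if value not in (1, 2):
                raise ValidationError(f"{path}:{lineno}: phenotype must be 1 or 2, got {value}")
            labels[sample] = value
    return labels


def read_network(path: str | Path, dialect: str = "edge_list") -> nx.Graph:
    """Read an undirected simple PPI graph.

    ``edge_list``: two tab- (or whitespace-) separated identifier columns
    per line. ``sif``: ``nodeA <relation> nodeB`` lines; the relation is
    ignored. Duplicate / reversed-duplicate edges collapse; self-loops are
    discarded with a logged count.
    """
    if dialect not in ("edge_list", "sif"):
        raise ValueError(f"unknown dialect {dialect!r}; expected 'edge_list' or 'sif'")
    graph = nx.Graph()
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if dialect == "edge_list":
                if len(parts) < 2:
                    raise ParseError(f"{path}:{lineno}: expected two columns")
                a, b = parts[0], parts[1]
            else:
                if len(parts) == 1:
                    graph.add_node(parts[0])  # SIF allows isolated nodes
                    continue
                if len(parts) < 3:
                    raise ParseError(f"{path}:{lineno}: expected 'nodeA relation nodeB'")
                a, b = parts[0], parts[2]
            if a == b:
                n_self += 1
                graph.add_node(a)
                continue
            graph.add_edge(a, b)
    if n_self:
        logger.warning("discarded %d self-loop(s) while reading %s", n_self, path)
    return graph


def write_network(graph: nx.Graph, path: str | Path) -> None:
    """Write a graph as a two-column tab-separated edge list.

    Isolated nodes are written as self-loop lines (``v\\tv``): the reader
    discards the loop but keeps the node, so round-trips preserve the
    node set exactly.
    """
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{a}\t{b}\n")
        for node in sorted(n for n in graph.nodes if graph.degree(n) == 0):
            fh.write(f"{node}\t{node}\n")


def induce_network(graph: nx.Graph, dataset: ExpressionDataset) -> nx.Graph:
    """Subgraph on the nodes measured in the expression data.

    Keeps every edge among shared nodes; isolated nodes are retained.
    """
    shared = set(graph.nodes) & set(dataset.gene_ids)
    if not shared:
        raise ValidationError(
            "no overlap between network nodes and expression gene identifiers; "
            "check that both use the same namespace"
        )
    return nx.Graph(graph.subgraph(shared))


def write_markers_gmt(markers: Sequence, path: str | Path) -> None:
    """Write markers in GMT format, one line per marker.

    Columns: name (``marker_001`` ...), description carrying the
    discriminative power R to 4 decimals, then member gene ids. The given
    (rank) order is preserved.
    """
    markers = list(markers)
    if not markers:
        raise ValidationError("refusing to write an empty marker list")
    with open(path, "w") as fh:
        for i, marker in enumerate(markers, start=1):
            members = sorted(marker.members)
            fh.write(f"marker_{i:03d}\tR={marker.R:.4f}\t" + "\t".join(members) + "\n")


def read_gmt(path: str | Path) -> list[tuple[str, list[str]]]:
    """Read a GMT file as (name, member genes) pairs, order preserved."""
    out: list[tuple[str, list[str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT lines need name, description, >=1 gene")
            out.append((parts[0], [g for g in parts[2:] if g]))
    return out
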
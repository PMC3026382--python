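"""Probabilistic activity inference.

Each gene's expression is modelled per phenotype as a Gaussian; the
log-likelihood ratio (LLR) of a measurement x for gene i is

    alpha(x) = log f_i^1(x) - log f_i^2(x)
             = log(sigma2/sigma1) - (x - mu1)^2 / (2 sigma1^2)
                                  + (x - mu2)^2 / (2 sigma2^2)

(natural log). Positive values favour phenotype 1. The activity of a gene
set in a sample is the sum of its members' LLRs, and a marker's
discriminative power R is the absolute two-sample t statistic of that
activity between the phenotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class GaussianParams:
    """Per-gene, per-phenotype Gaussian parameters.

    ``mu`` and ``sigma`` have shape (2, n_genes); row 0 is phenotype 1.
    Standard deviations are floored at ``sigma_floor`` (> 0) so the LLR is
    finite even for genes constant within a class.
    """

    gene_ids: list[str]
    mu: np.ndarray
    sigma: np.ndarray
    sigma_floor: float

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if self.mu.shape != (2, n) or self.sigma.shape != (2, n):
            raise ValidationError("GaussianParams arrays must have shape (2, n_genes)")
        if self.sigma_floor <= 0 or np.any(self.sigma < self.sigma_floor):
            raise ValidationError("standard deviations must be floored at sigma_floor > 0")


def estimate_params(
    dataset: ExpressionDataset, sigma_floor_factor: float = 1e-6
) -> GaussianParams:
    """Empirical class-conditional means and standard deviations.

    Standard deviations use the unbiased (n-1) estimator and are floored
    at ``sigma_floor_factor`` times the global standard deviation of the
    whole expression matrix (or at the factor itself if the matrix is
    globally constant).
    """
    return _estimate_params_array(
        dataset.values, dataset.labels, dataset.gene_ids, sigma_floor_factor
    )


def _estimate_params_array(
    values: np.ndarray,
    labels: np.ndarray,
    gene_ids: Sequence[str],
    sigma_floor_factor: float = 1e-6,
) -> GaussianParams:
    labels = np.asarray(labels)
    mus, sigmas = [], []
    for k in (1, 2):
        cols = values[:, labels == k]
        if cols.shape[1] < 2:
            raise ValidationError(f"phenotype class {k} has fewer than 2 samples")
        mus.append(cols.mean(axis=1))
        sigmas.append(cols.std(axis=1, ddof=1))
    global_sd = float(values.std())
    floor = sigma_floor_factor * (global_sd if global_sd > 0 else 1.0)
    sigma = np.maximum(np.vstack(sigmas), floor)
    return GaussianParams(list(gene_ids), np.vstack(mus), sigma, floor)


def llr_transform(values: np.ndarray, params: GaussianParams) -> np.ndarray:
    """Entrywise LLR of a genes x samples matrix under fitted parameters."""
    mu1, mu2 = params.mu[0][:, None], params.mu[1][:, None]
    s1, s2 = params.sigma[0][:, None], params.sigma[1][:, None]
    return (
        np.log(s2 / s1)
        - (values - mu1) ** 2 / (2.0 * s1**2)
        + (values - mu2) ** 2 / (2.0 * s2**2)
    )


def compute_llr(dataset: ExpressionDataset, params: GaussianParams) -> pd.DataFrame:
    """LLR matrix with the same genes x samples layout as the dataset."""
    if params.gene_ids != dataset.gene_ids:
        raise ValidationError("parameter gene ids do not match the dataset")
    return pd.DataFrame(
        llr_transform(dataset.values, params),
        index=dataset.gene_ids,
        columns=dataset.sample_ids,
    )


def subnetwork_activity(members: Iterable[str], llr: pd.DataFrame) -> np.ndarray:
    """Per-sample activity of a gene set: the sum of member-gene LLRs."""
    members = list(members)
    if not members:
        raise ValidationError("member set is empty")
    missing = [g for g in members if g not in llr.index]
    if missing:
        raise KeyError(f"member gene(s) absent from the LLR matrix: {missing[:5]}")
    return llr.loc[members].to_numpy().sum(axis=0)


def t_statistic(values, labels, kind: str = "welch") -> float:
    """Two-sample t statistic, phenotype 1 minus phenotype 2.

    Welch's form (default) uses per-class variances; ``kind="student"``
    pools them. A degenerate denominator (both classes with zero spread)
    returns 0 with a warning rather than raising.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    a, b = values[labels == 1], values[labels == 2]
    if a.size < 2 or b.size < 2:
        raise ValidationError("t statistic requires >= 2 samples in each class")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    if kind == "welch":
        denom = np.sqrt(va / na + vb / nb)
    elif kind == "student":
        pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        denom = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    else:
        raise ValueError(f"unknown t statistic kind {kind!r}")
    if denom == 0.0:
        logger.warning("degenerate zero spread in both classes; returning t = 0")
        return 0.0
    return float((a.mean() - b.mean()) / denom)


def gene_t_scores(llr: pd.DataFrame, labels, kind: str = "welch") -> pd.Series:
    """Per-gene t statistic of the LLR rows (t_alpha), vectorised."""
    labels = np.asarray(labels)
    values = llr.to_numpy()
    a, b = values[:, labels == 1], values[:, labels == 2]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValidationError("t statistic requires >= 2 samples in each class")
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    na, nb = a.shape[1], b.shape[1]
    if kind == "welch":
        denom = np.sqrt(va / na + vb / nb)
    elif kind == "student":
        pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        denom = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    else:
        raise ValueError(f"unknown t statistic kind {kind!r}")
    diff = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0), 0.0)
    return pd.Series(t, index=llr.index, name="t_alpha")


def discriminative_power(
    members: Iterable[str], llr: pd.DataFrame, labels, kind: str = "welch"
) -> float:
    """R of a gene set: |t| of its summed-LLR activity."""
    return abs(t_statistic(subnetwork_activity(members, llr), labels, kind=kind))
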
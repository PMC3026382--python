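"""Correlation-weighted discriminative scoring of linear paths.

A path of l genes is scored by a weighted sum of the members' absolute
LLR t-scores. The weights come from the Pearson correlation matrix P of
the members' LLR rows through

    Sigma' = (P + (theta - 1) I) / (l - 1 + theta),     l >= 2
    Sigma' = [1]                                        l = 1

so that at theta = 0 each gene is weighted by its average correlation
with the other members, and as theta -> infinity Sigma' -> I and the
score reduces to the plain average |t| of the members. The raw score is
s = |t|^T Sigma' J (J the all-ones vector) and the length-normalised
score is S = s / l**norm_exponent (default exponent 1, which preserves
the theta -> infinity average-|t| limit).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import ValidationError


def standardize_rows(values: np.ndarray) -> np.ndarray:
    """Center each row and scale to unit norm, so Z @ Z.T is the Pearson
    correlation matrix. Zero-variance rows become all-zero rows (their
    correlation with anything is defined as 0)."""
    z = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(z, axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(norms > 0, z / np.where(norms > 0, norms, 1.0), 0.0)
    return z


def llr_correlation(genes: Sequence[str], llr: pd.DataFrame) -> np.ndarray:
    """Pearson correlation matrix of the members' LLR rows.

    Samples from both phenotypes are pooled. A zero-variance gene gets
    correlation 0 against every other gene and a diagonal entry of 1.
    """
    genes = list(genes)
    if not genes:
        raise ValidationError("empty gene list")
    z = standardize_rows(llr.loc[genes].to_numpy(dtype=float))
    p = z @ z.T
    np.fill_diagonal(p, 1.0)
    return np.clip(p, -1.0, 1.0)


def sigma_prime(P: np.ndarray, theta: float, l: int | None = None) -> np.ndarray:
    """Weight matrix Sigma' derived from the correlation matrix and theta."""
    P = np.asarray(P, dtype=float)
    if l is None:
        l = P.shape[0]
    if P.shape != (l, l):
        raise ValidationError(f"correlation matrix shape {P.shape} does not match l={l}")
    if not math.isinf(theta) and theta < 0:
        raise ValidationError(f"theta must be nonnegative, got {theta}")
    if l == 1:
        return np.ones((1, 1))
    if math.isinf(theta):
        return np.eye(l)
    return (P + (theta - 1.0) * np.eye(l)) / (l - 1.0 + theta)


def path_score(
    genes: Sequence[str],
    t_alpha: Sequence[float],
    P: np.ndarray,
    theta: float,
    norm_exponent: int = 1,
) -> tuple[float, float]:
    """Score a path: raw s = |t|^T Sigma' J and normalised S = s / l**exp.

    ``t_alpha`` holds the members' t-scores aligned with ``genes``;
    absolute values are taken here, so signed scores may be passed.
    """
    genes = list(genes)
    t = np.abs(np.asarray(t_alpha, dtype=float))
    l = len(genes)
    if t.shape != (l,):
        raise ValidationError(f"{l} genes but {t.shape[0]} t-scores")
    s = float(t @ sigma_prime(P, theta, l) @ np.ones(l))
    return s, s / l**norm_exponent
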
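"""Marker evaluation: discriminative-power summaries, baseline marker
schemes, and the nested cross-validation classification harness.

The harness mirrors the marker-evaluation protocol the package is built
around: markers are fixed up front; each repeat draws a stratified
ten-fold split; per test fold the nine training folds are split 6/3 into
a marker-ranking set (ranks markers by |t| of their activity and fits the
logistic-regression classifier) and a feature-selection set (forward
selection keeps a marker iff it strictly increases the selection-set
AUC); the selected model is scored by AUC on the held-out fold. LLR
parameters are always estimated on training folds only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .activity import (
    _estimate_params_array,
    gene_t_scores,
    llr_transform,
    subnetwork_activity,
    t_statistic,
)
from .datasets import ExpressionDataset, ValidationError

logger = logging.getLogger(__name__)


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC with phenotype 1 as positive.

    Ties contribute 1/2. Equals the probability that a random phenotype-1
    sample outscores a random phenotype-2 sample.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC requires both phenotype classes")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def error_at_tpr(scores, labels, tpr_grid: Sequence[float]) -> np.ndarray:
    """Best misclassification rate achievable at each sensitivity level.

    A sample is called phenotype 1 when its score is at or above the
    threshold. For each target TPR, the reported error is the minimum
    overall misclassification rate over thresholds whose sensitivity is
    at least that target; the returned array has rows (tpr, error). A
    perfectly separating score thus has zero error at every level, and
    at TPR = 1 the error is the fraction of phenotype-2 samples scoring
    at or above the lowest phenotype-1 score.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    is_pos = labels == 1
    n_pos, n_neg = int(is_pos.sum()), int((~is_pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("error_at_tpr requires both phenotype classes")
    # evaluate every distinct threshold once (plus +inf = predict nothing)
    thresholds = np.unique(scores)
    tpr = np.array([(scores[is_pos] >= thr).mean() for thr in thresholds])
    err = np.array(
        [((scores >= thr) != is_pos).mean() for thr in thresholds]
    )
    rows = []
    for t in tpr_grid:
        if not (0.0 <= t <= 1.0):
            raise ValidationError(f"TPR target must be in [0, 1], got {t}")
        ok = tpr >= t
        rows.append((float(t), float(err[ok].min()) if ok.any() else float(n_pos) / len(scores)))
    return np.asarray(rows)


def marker_activity_tscores(
    marker_definitions: Sequence[tuple[str, Sequence[str]]],
    llr: pd.DataFrame,
    labels,
    t_test: str = "welch",
) -> pd.Series:
    """|t| of the summed-LLR activity per marker, indexed by marker name."""
    out = {}
    for name, genes in marker_definitions:
        out[name] = abs(t_statistic(subnetwork_activity(genes, llr), labels, kind=t_test))
    return pd.Series(out, name="abs_t")


def mean_topk_tscore(
    marker_definitions: Sequence[tuple[str, Sequence[str]]],
    llr: pd.DataFrame,
    labels,
    K_values: Sequence[int] = (10, 20, 30, 40, 50),
    t_test: str = "welch",
) -> pd.Series:
    """Mean absolute activity t-score of the top K markers, per K.

    Markers may have been discovered on a different dataset than the one
    providing ``llr`` (cross-dataset evaluation). K larger than the
    marker count falls back to all markers with a logged note.
    """
    t = np.sort(marker_activity_tscores(marker_definitions, llr, labels, t_test).to_numpy())[::-1]
    out = {}
    for K in K_values:
        k = int(K)
        if k > t.size:
            logger.info("K=%d exceeds marker count %d; using all markers", k, t.size)
            k = t.size
        if k < 1:
            raise ValidationError("K must be >= 1")
        out[int(K)] = float(t[:k].mean())
    return pd.Series(out, name="mean_topk_abs_t")


def gene_marker_baseline(
    marker_definitions: Sequence[tuple[str, Sequence[str]]],
    llr: pd.DataFrame,
    labels,
    top_n: int = 50,
    t_test: str = "welch",
) -> list[tuple[str, list[str]]]:
    """Single-gene baseline: top ``top_n`` genes by |t| of their LLR among
    all genes covered by the given markers, as singleton markers.

    Depends only on the union of covered genes, not on marker order.
    """
    covered = sorted({g for _, genes in marker_definitions for g in genes})
    if not covered:
        raise ValidationError("marker definitions cover no genes")
    t = gene_t_scores(llr.loc[covered], labels, kind=t_test).abs()
    ranked = sorted(covered, key=lambda g: (-t[g], g))
    return [(g, [g]) for g in ranked[: min(top_n, len(ranked))]]


def average_t_ranking(
    gene_sets: Sequence[tuple[str, Sequence[str]]],
    llr: pd.DataFrame,
    labels,
    t_test: str = "welch",
) -> list[tuple[str, float]]:
    """Rank gene sets by the mean absolute LLR t-score of their members
    (the average-|t| pathway-ranking scheme). Members absent from the LLR
    matrix are skipped with a warning; a set losing all members scores 0.
    Ties break by set name.
    """
    t = gene_t_scores(llr, labels, kind=t_test).abs()
    scored = []
    for name, genes in gene_sets:
        genes = list(genes)
        if not genes:
            raise ValidationError(f"gene set {name!r} is empty")
        present = [g for g in genes if g in t.index]
        if len(present) < len(genes):
            logger.warning(
                "set %s: %d member(s) absent from the data", name, len(genes) - len(present)
            )
        scored.append((name, float(t[present].mean()) if present else 0.0))
    return sorted(scored, key=lambda kv: (-kv[1], kv[0]))


def mean_expression_activity(
    members: Iterable[str],
    dataset: ExpressionDataset,
    norm_mean: pd.Series | None = None,
    norm_sd: pd.Series | None = None,
) -> np.ndarray:
    """Mean-expression activity: per-sample mean of the members'
    z-normalised expression (the averaging baseline scheme).

    Normalisation statistics default to the dataset's own per-gene mean
    and standard deviation; pass training-set statistics explicitly when
    evaluating held-out samples.
    """
    members = list(members)
    if not members:
        raise ValidationError("member set is empty")
    df = dataset.to_frame()
    missing = [g for g in members if g not in df.index]
    if missing:
        raise KeyError(f"member gene(s) absent from the dataset: {missing[:5]}")
    sub = df.loc[members]
    mu = sub.mean(axis=1) if norm_mean is None else norm_mean.loc[members]
    sd = sub.std(axis=1, ddof=1) if norm_sd is None else norm_sd.loc[members]
    sd = sd.replace(0.0, 1.0)
    z = sub.sub(mu, axis=0).div(sd, axis=0)
    return z.to_numpy().mean(axis=0)


@dataclass
class CVResult:
    """Nested cross-validation outcome.

    ``fold_records`` holds one dict per (repeat, fold) with the test AUC,
    the selected marker names, and the sample-index sets used for
    parameter estimation, ranking, selection and testing (kept so tests
    can audit that the held-out fold never leaks into fitting).
    """

    fold_records: list[dict]
    mean_auc: float
    pooled_scores: np.ndarray
    pooled_labels: np.ndarray

    def error_curve(self, tpr_grid: Sequence[float] = tuple(np.linspace(0.1, 1.0, 10))) -> np.ndarray:
        return error_at_tpr(self.pooled_scores, self.pooled_labels, tpr_grid)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "repeat": r["repeat"],
                    "fold": r["fold"],
                    "n_features": len(r["selected"]),
                    "test_auc": r["test_auc"],
                }
                for r in self.fold_records
            ]
        )


def _marker_activities(
    values: np.ndarray,
    gene_index: Mapping[str, int],
    marker_definitions: Sequence[tuple[str, Sequence[str]]],
) -> np.ndarray:
    """Markers x samples activity matrix by summing rows of ``values``."""
    out = np.empty((len(marker_definitions), values.shape[1]))
    for j, (_, genes) in enumerate(marker_definitions):
        out[j] = values[[gene_index[g] for g in genes]].sum(axis=0)
    return out


def nested_cv(
    dataset: ExpressionDataset,
    marker_definitions: Sequence[tuple[str, Sequence[str]]],
    activity_scheme: str = "llr_sum",
    n_repeats: int = 5,
    n_folds: int = 10,
    n_ranking_folds: int = 6,
    n_selection_folds: int = 3,
    max_features: int = 50,
    t_test: str = "welch",
    penalty: str | None = None,
    sigma_floor_factor: float = 1e-6,
    seed: int = 0,
) -> CVResult:
    """Nested cross-validation of fixed marker definitions.

    Marker discovery is not re-run inside the loop (markers are inputs);
    everything estimated from data — Gaussian LLR parameters or
    z-normalisation statistics, marker ranking, forward selection and the
    classifier — uses training folds only. ``activity_scheme`` is
    ``"llr_sum"`` (summed member LLRs) or ``"mean_expression"`` (mean of
    z-normalised member expression). The AUC averaged over all
    repeats x folds is the headline number.
    """
    if activity_scheme not in ("llr_sum", "mean_expression"):
        raise ValidationError(f"unknown activity scheme {activity_scheme!r}")
    if n_ranking_folds + n_selection_folds != n_folds - 1:
        raise ValidationError(
            "ranking folds + selection folds must equal n_folds - 1 "
            f"(got {n_ranking_folds}+{n_selection_folds} vs {n_folds - 1})"
        )
    markers = _clean_definitions(marker_definitions, dataset)
    gene_index = {g: i for i, g in enumerate(dataset.gene_ids)}
    rng = np.random.default_rng(seed)
    y = dataset.labels

    records: list[dict] = []
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    for rep in range(n_repeats):
        folds = _draw_folds(y, n_folds, rng)
        for fold_i, test_idx in enumerate(folds):
            train_folds = [f for j, f in enumerate(folds) if j != fold_i]
            order = rng.permutation(len(train_folds))
            rank_idx = np.concatenate([train_folds[j] for j in order[:n_ranking_folds]])
            sel_idx = np.concatenate([train_folds[j] for j in order[n_ranking_folds:]])
            est_idx = np.concatenate([rank_idx, sel_idx])

            if activity_scheme == "llr_sum":
                params = _estimate_params_array(
                    dataset.values[:, est_idx], y[est_idx], dataset.gene_ids,
                    sigma_floor_factor,
                )
                acts = _marker_activities(
                    llr_transform(dataset.values, params), gene_index, markers
                )
            else:
                train_vals = dataset.values[:, est_idx]
                mu = train_vals.mean(axis=1, keepdims=True)
                sd = train_vals.std(axis=1, ddof=1, keepdims=True)
                sd[sd == 0.0] = 1.0
                z = (dataset.values - mu) / sd
                acts = np.empty((len(markers), dataset.n_samples))
                for j, (_, genes) in enumerate(markers):
                    acts[j] = z[[gene_index[g] for g in genes]].mean(axis=0)

            ranking = _rank_markers(markers, acts, y, rank_idx, t_test)[:max_features]
            selected, test_scores, test_auc, sel_auc_top1, sel_auc_final = _forward_select(
                markers, acts, y, ranking, rank_idx, sel_idx, test_idx, penalty
            )
            records.append(
                {
                    "repeat": rep,
                    "fold": fold_i,
                    "selected": [markers[j][0] for j in selected],
                    "test_auc": test_auc,
                    "selection_auc_top1": sel_auc_top1,
                    "selection_auc_final": sel_auc_final,
                    "estimation_idx": np.sort(est_idx),
                    "ranking_idx": np.sort(rank_idx),
                    "selection_idx": np.sort(sel_idx),
                    "test_idx": np.sort(test_idx),
                }
            )
            pooled_scores.append(test_scores)
            pooled_labels.append(y[test_idx])

    return CVResult(
        fold_records=records,
        mean_auc=float(np.mean([r["test_auc"] for r in records])),
        pooled_scores=np.concatenate(pooled_scores),
        pooled_labels=np.concatenate(pooled_labels),
    )


def _clean_definitions(
    marker_definitions: Sequence[tuple[str, Sequence[str]]], dataset: ExpressionDataset
) -> list[tuple[str, tuple[str, ...]]]:
    known = set(dataset.gene_ids)
    cleaned = []
    for name, genes in marker_definitions:
        present = tuple(g for g in genes if g in known)
        if len(present) < len(list(genes)):
            logger.warning(
                "marker %s: %d gene(s) absent from the dataset",
                name, len(list(genes)) - len(present),
            )
        if present:
            cleaned.append((str(name), present))
        else:
            logger.warning("marker %s dropped: no member measured", name)
    if not cleaned:
        raise ValidationError("no marker has any measured member gene")
    return cleaned


def _draw_folds(y: np.ndarray, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Stratified folds; redraws (logged) if any fold is single-class."""
    for attempt in range(20):
        skf = StratifiedKFold(
            n_splits=n_folds, shuffle=True, random_state=int(rng.integers(2**31 - 1))
        )
        folds = [test for _, test in skf.split(np.zeros(len(y)), y)]
        if all(len(np.unique(y[f])) == 2 for f in folds):
            return folds
        logger.warning("single-class fold drawn (attempt %d); redrawing split", attempt + 1)
    raise ValidationError(
        "could not draw a stratified split with both classes in every fold; "
        "too few samples per class for this fold count"
    )


def _rank_markers(markers, acts, y, rank_idx, t_test) -> list[int]:
    scores = [
        abs(t_statistic(acts[j, rank_idx], y[rank_idx], kind=t_test))
        for j in range(len(markers))
    ]
    return sorted(range(len(markers)), key=lambda j: (-scores[j], markers[j][0]))


def _fit_lr(X, y, penalty):
    # unpenalized by default; "l2" adds ridge shrinkage for tiny runs
    C = 1.0 if penalty == "l2" else np.inf
    model = make_pipeline(
        StandardScaler(),
        LogisticRegression(C=C, solver="lbfgs", max_iter=1000),
    )
    import warnings

    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    return model


def _proba_pos(model, X) -> np.ndarray:
    classes = list(model.classes_)
    return model.predict_proba(X)[:, classes.index(1)]


def _forward_select(markers, acts, y, ranking, rank_idx, sel_idx, test_idx, penalty):
    """Greedy forward selection by strict selection-set AUC improvement.

    Starts from the top-ranked marker; each later marker is kept iff
    adding it strictly increases the AUC of a classifier fitted on the
    ranking set and scored on the selection set. Returns the selected
    marker indices, test-fold scores and test AUC of the final model.
    """
    selected = [ranking[0]]
    model = _fit_lr(acts[selected][:, rank_idx].T, y[rank_idx], penalty)
    best = auc(_proba_pos(model, acts[selected][:, sel_idx].T), y[sel_idx])
    top1 = best
    for j in ranking[1:]:
        trial = selected + [j]
        trial_model = _fit_lr(acts[trial][:, rank_idx].T, y[rank_idx], penalty)
        trial_auc = auc(_proba_pos(trial_model, acts[trial][:, sel_idx].T), y[sel_idx])
        if trial_auc > best:
            selected, model, best = trial, trial_model, trial_auc
    test_scores = _proba_pos(model, acts[selected][:, test_idx].T)
    return selected, test_scores, auc(test_scores, y[test_idx]), top1, best
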
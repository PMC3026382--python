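"""Independent reference implementations used only by tests.

Everything here is deliberately naive — explicit loops, textbook
formulas, exhaustive enumeration — and shares no code with the package
paths it cross-checks.
"""

import itertools
import math

import numpy as np


def welch_t(a, b) -> float:
    """Textbook Welch two-sample t, group a minus group b."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va = sum((x - a.mean()) ** 2 for x in a) / (len(a) - 1)
    vb = sum((x - b.mean()) ** 2 for x in b) / (len(b) - 1)
    return (a.mean() - b.mean()) / math.sqrt(va / len(a) + vb / len(b))


def pearson(x, y) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    denom = math.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        return 0.0
    return float((xc * yc).sum() / denom)


def brute_path_score(genes, llr_df, t_alpha, theta, norm_exponent=1):
    """Path score via explicit double loops over the adopted Sigma'."""
    genes = list(genes)
    l = len(genes)
    t = [abs(float(t_alpha[g])) for g in genes]
    rows = [llr_df.loc[g].to_numpy() for g in genes]
    s = 0.0
    if l == 1:
        s = t[0]
    elif math.isinf(theta):
        s = sum(t)
    else:
        for i in range(l):
            for j in range(l):
                rho = 1.0 if i == j else pearson(rows[i], rows[j])
                sigma_ij = (rho + (theta - 1.0) * (i == j)) / (l - 1.0 + theta)
                s += t[i] * sigma_ij
    return s, s / l**norm_exponent


def enumerate_paths_ending_at(graph, endpoint, length):
    """All simple paths of exactly `length` nodes ending at `endpoint`."""
    paths = []

    def extend(path):
        if len(path) == length:
            paths.append(tuple(reversed(path)))
            return
        for nbr in graph.neighbors(path[-1]):
            if nbr not in path:
                extend(path + [nbr])

    extend([endpoint])  # build backwards from the endpoint
    return paths


def exhaustive_best_paths(graph, llr_df, t_alpha, theta, max_length):
    """Best raw score and arg-max path set per (node, length)."""
    best = {}
    for v in graph.nodes:
        for l in range(1, max_length + 1):
            scored = []
            for path in enumerate_paths_ending_at(graph, v, l):
                s, _ = brute_path_score(path, llr_df, t_alpha, theta)
                scored.append((s, path))
            if scored:
                top = max(s for s, _ in scored)
                best[(v, l)] = (top, {p for s, p in scored if math.isclose(s, top, rel_tol=1e-9)})
    return best


def pair_count_auc(scores, labels) -> float:
    """AUC by exhaustive concordant/discordant pair counting; phenotype 1
    is the positive class and ties count 1/2."""
    scores, labels = np.asarray(scores, float), np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 2]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        if p > n:
            total += 1.0
        elif p == n:
            total += 0.5
    return total / (len(pos) * len(neg))
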
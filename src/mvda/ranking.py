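"""Class-separability ranking of prototype features.

Two rankers are provided:

* :func:`cat_score` — correlation-adjusted t-scores.  Per-contrast shrinkage
  t-statistics are decorrelated by R^{-1/2}, the inverse square root of the
  shrinkage feature correlation matrix, so that correlated features share
  credit instead of each inheriting the full marginal effect.  Multi-class
  data are handled by one-vs-rest contrasts whose squared CAT-scores are
  summed into a single non-negative score per feature.

* :func:`rf_importance` — permutation importance (mean decrease in accuracy)
  of a random forest, measured on a held-out stratified split; negative
  importances are floored at zero.

A ranking is consumed through :func:`cumulative_cut`: the shortest prefix
holding a requested fraction of the total score mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import train_test_split

from .datatypes import LabelVector, ValidationError, ViewMatrix

__all__ = [
    "RankedFeatures",
    "cat_score",
    "rf_importance",
    "cumulative_cut",
    "shrinkage_correlation",
]

RANKING_METHODS = ("cat_score", "rf_importance")


@dataclass
class RankedFeatures:
    view_name: str
    feature_ids: list[str]  # ordered by decreasing score
    scores: np.ndarray  # non-negative, non-increasing
    method: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.feature_ids) != self.scores.shape[0]:
            raise ValidationError("ids and scores differ in length")
        if np.any(self.scores < 0):
            raise ValidationError("scores must be non-negative")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValidationError("scores must be sorted non-increasing")


def _ranked(view_name: str, ids: list[str], scores: np.ndarray, method: str) -> RankedFeatures:
    order = sorted(range(len(ids)), key=lambda i: (-scores[i], ids[i]))
    return RankedFeatures(
        view_name=view_name,
        feature_ids=[ids[i] for i in order],
        scores=scores[order],
        method=method,
    )


def _check_supervised(view: ViewMatrix, labels: LabelVector) -> np.ndarray:
    if view.patient_ids != labels.patient_ids:
        raise ValidationError("view and labels are not aligned")
    labels.require_supervised()
    y = labels.as_codes()
    counts = np.bincount(y)
    if np.any(counts < 2):
        small = labels.classes[int(np.argmin(counts))]
        raise ValidationError(f"class {small!r} has fewer than 2 patients")
    return y


def shrinkage_correlation(z: np.ndarray) -> tuple[np.ndarray, float]:
    """Schäfer–Strimmer shrinkage of the feature correlation matrix.

    ``z`` is features x samples, already centered.  Off-diagonal sample
    correlations are shrunk toward zero with the analytic intensity
    ``lambda* = sum Var(r_ij) / sum r_ij^2`` (clipped to [0, 1]).
    Returns the shrunk matrix and the intensity.
    """
    f, n = z.shape
    if n < 3:
        raise ValidationError("need at least 3 samples to shrink correlations")
    sd = z.std(axis=1, ddof=1)
    sd[sd == 0] = 1.0
    w = z / sd[:, None]
    r = (w @ w.T) / (n - 1)
    np.fill_diagonal(r, 1.0)
    # var of each r_ij from the products of standardized observations
    prod_mean = r * (n - 1) / n
    var_sum = 0.0
    r2_sum = 0.0
    for i in range(f):
        p = w[i][None, :] * w  # (f, n) products for row i
        v = (n / (n - 1) ** 3) * ((p - prod_mean[i][:, None]) ** 2).sum(axis=1)
        v[i] = 0.0
        var_sum += v.sum()
        row2 = r[i] ** 2
        row2[i] = 0.0
        r2_sum += row2.sum()
    lam = 1.0 if r2_sum == 0 else float(np.clip(var_sum / r2_sum, 0.0, 1.0))
    r_shrunk = (1.0 - lam) * r
    np.fill_diagonal(r_shrunk, 1.0)
    return r_shrunk, lam


def _inv_sqrt(r: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(r)
    vals = np.clip(vals, 1e-10, None)
    return (vecs * (vals**-0.5)) @ vecs.T


def cat_score(
    view: ViewMatrix,
    labels: LabelVector,
    correlation: np.ndarray | None = None,
) -> RankedFeatures:
    """Correlation-adjusted t-score ranking.

    ``correlation`` may be supplied (e.g. the identity) to bypass the
    shrinkage estimate; with an identity correlation the CAT-scores equal the
    ordinary (shrinkage-variance) t-scores.
    """
    y = _check_supervised(view, labels)
    x = view.values
    f, n = x.shape
    k = y.max() + 1

    # pooled within-class residuals
    resid = x.copy()
    for c in range(k):
        mask = y == c
        resid[:, mask] -= x[:, mask].mean(axis=1, keepdims=True)
    dof = max(n - k, 1)
    v = (resid**2).sum(axis=1) / dof

    # shrink variances toward their median (stabilizes small-n pooled t)
    w2 = resid**2
    var_of_v = (n / ((n - 1) ** 3 or 1)) * ((w2 - w2.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    target = float(np.median(v))
    denom = ((v - target) ** 2).sum()
    lam_v = 1.0 if denom == 0 else float(np.clip(var_of_v.sum() / denom, 0.0, 1.0))
    v_shrunk = lam_v * target + (1.0 - lam_v) * v
    v_shrunk[v_shrunk <= 0] = np.finfo(float).tiny

    if correlation is None:
        correlation, _ = shrinkage_correlation(resid)
    r_inv_sqrt = _inv_sqrt(correlation)

    total = np.zeros(f)
    for c in range(k):
        n1 = int((y == c).sum())
        n0 = n - n1
        diff = x[:, y == c].mean(axis=1) - x[:, y != c].mean(axis=1)
        t = diff / np.sqrt(v_shrunk * (1.0 / n1 + 1.0 / n0))
        cat = r_inv_sqrt @ t
        total += cat**2
    return _ranked(view.name, list(view.feature_ids), total, "cat_score")


def rf_importance(
    view: ViewMatrix,
    labels: LabelVector,
    n_trees: int = 1000,
    seed: int = 0,
    n_repeats: int = 10,
    test_size: float = 0.3,
) -> RankedFeatures:
    """Random-forest permutation importance (mean decrease in accuracy).

    The forest is fit on a stratified training split and each feature is
    permuted on the held-out split; the mean accuracy drop is its score.
    Deterministic given ``seed``.
    """
    y = _check_supervised(view, labels)
    x = view.values.T  # patients x features
    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y, test_size=test_size, stratify=y, random_state=seed
    )
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    ).fit(x_tr, y_tr)
    imp = permutation_importance(
        forest, x_te, y_te, n_repeats=n_repeats, random_state=seed, n_jobs=1
    )
    scores = np.maximum(imp.importances_mean, 0.0)
    return _ranked(view.name, list(view.feature_ids), scores, "rf_importance")


def cumulative_cut(ranked: RankedFeatures, fraction: float) -> list[str]:
    """Shortest ranking prefix whose score mass reaches ``fraction`` of the total."""
    if not (0.0 < fraction <= 1.0):
        raise ValidationError(f"fraction {fraction} outside (0, 1]")
    total = float(ranked.scores.sum())
    if total <= 0:
        raise ValidationError(
            f"all scores are zero for view {ranked.view_name!r}; nothing to cut"
        )
    cum = np.cumsum(ranked.scores)
    n = int(np.searchsorted(cum, fraction * total - 1e-12)) + 1
    return ranked.feature_ids[:n]
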
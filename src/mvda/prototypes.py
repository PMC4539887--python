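"""Per-view dimension reduction: feature clustering and prototype selection.

Each view is reduced by (1) dropping low-variance features, (2) clustering
the remaining features in correlation space, and (3) keeping one *prototype*
per feature cluster — the member most correlated with the others.  Candidate
clusterings are scored with a composite validity index

    VAL = 1/4 * ( (IC+1)/2  +  1 - (EC+1)/2  +  (1 - S)  +  CG )

where, with Pearson correlation as the similarity currency,

* ``IC`` (complete diameter): mean over clusters of the *minimum* pairwise
  correlation inside the cluster — cohesion of the least similar members;
* ``EC`` (complete linkage): mean over cluster pairs of the minimum
  cross-cluster correlation — separation of the least similar cross pair;
* ``S = #singletons / (K - 1)`` penalizes singleton clusters;
* ``CG = 1 - K / N`` is the compression gain for reducing N features to K
  prototypes.

High VAL means cohesive, well-separated, singleton-free, strongly
compressing clusterings.  ``S`` can exceed 1 when there are more than K-1
singletons; VAL is then allowed below 0 rather than clamped, so the identity
above always holds exactly.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._cluster import ALGORITHMS, cluster_rows
from .datatypes import ValidationError, ViewMatrix

__all__ = [
    "FeatureClustering",
    "ValComponents",
    "PrototypeSet",
    "variance_filter",
    "correlation_matrix",
    "cluster_features",
    "val_components",
    "tune_k",
    "select_prototypes",
    "extract_prototypes",
    "default_k_grid",
]

log = logging.getLogger("mvda")


@dataclass
class FeatureClustering:
    """A hard partition of one view's features."""

    view_name: str
    algorithm: str
    k: int
    assignment: np.ndarray  # cluster index per feature
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        if self.assignment.shape[0] != len(self.feature_ids):
            raise ValidationError("assignment length != number of features")
        if self.k < 2:
            raise ValidationError("k must be >= 2")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def members(self, cluster: int) -> np.ndarray:
        return np.where(self.assignment == cluster)[0]

    @property
    def cluster_indices(self) -> list[int]:
        return sorted(set(self.assignment.tolist()))


@dataclass
class ValComponents:
    IC: float
    EC: float
    S: float
    CG: float

    @property
    def VAL(self) -> float:
        return 0.25 * (
            (self.IC + 1.0) / 2.0 + 1.0 - (self.EC + 1.0) / 2.0 + (1.0 - self.S) + self.CG
        )


@dataclass
class PrototypeSet:
    view_name: str
    prototype_ids: list[str]
    cluster_of_feature: dict[str, int]
    chosen_algorithm: str
    chosen_k: int


def variance_filter(view: ViewMatrix, keep_fraction: float = 0.5) -> ViewMatrix:
    """Keep the ``ceil(keep_fraction * F)`` highest-variance features.

    Ties at the cut boundary are broken toward the lower feature index; the
    original feature order is preserved in the output.
    """
    if not (0.0 < keep_fraction <= 1.0):
        raise ValidationError(f"keep_fraction {keep_fraction} outside (0, 1]")
    if view.n_features == 0:
        raise ValidationError("empty view")
    variances = view.values.var(axis=1, ddof=1) if view.n_patients > 1 else np.zeros(
        view.n_features
    )
    n_keep = math.ceil(keep_fraction * view.n_features)
    order = np.argsort(-variances, kind="stable")  # stable: ties -> lower index
    kept = np.sort(order[:n_keep])
    return view.restrict_features([view.feature_ids[i] for i in kept])


def correlation_matrix(view: ViewMatrix) -> np.ndarray:
    """Feature x feature Pearson correlation across patients."""
    if view.n_patients < 2:
        raise ValidationError("need at least 2 patients for correlations")
    sd = view.values.std(axis=1)
    if np.any(sd == 0):
        bad = view.feature_ids[int(np.argmax(sd == 0))]
        raise ValidationError(
            f"zero-variance feature {bad!r}; apply variance_filter first"
        )
    corr = np.corrcoef(view.values)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def cluster_features(
    view: ViewMatrix,
    algorithm: str,
    k: int,
    seed: int = 0,
    corr: np.ndarray | None = None,
) -> FeatureClustering:
    """Cluster features in 1 - Pearson correlation geometry."""
    if not (2 <= k < view.n_features):
        raise ValidationError(f"k={k} out of range [2, {view.n_features - 1}]")
    labels = cluster_rows(
        view.values, algorithm=algorithm, k=k, seed=seed, metric="correlation", corr=corr
    )
    return FeatureClustering(
        view_name=view.name,
        algorithm=algorithm,
        k=k,
        assignment=labels,
        feature_ids=list(view.feature_ids),
    )


def val_components(fc: FeatureClustering, corr: np.ndarray) -> ValComponents:
    """Score a feature clustering: IC, EC, singleton factor, compression gain."""
    n = fc.n_features
    if corr.shape != (n, n):
        raise ValidationError("correlation matrix does not match the clustering")
    clusters = fc.cluster_indices
    k = len(clusters)
    if k < 2:
        raise ValidationError("VAL undefined for a single cluster (S = N/(K-1))")
    members = [fc.members(c) for c in clusters]

    ic_terms = []
    for m in members:
        if m.size >= 2:
            sub = corr[np.ix_(m, m)]
            iu = np.triu_indices(m.size, k=1)
            ic_terms.append(float(sub[iu].min()))
    if ic_terms:
        ic = float(np.mean(ic_terms))
    else:
        warnings.warn(
            "all clusters are singletons; IC undefined, set to 0", RuntimeWarning
        )
        ic = 0.0

    ec_terms = []
    for a in range(k):
        for b in range(a + 1, k):
            ec_terms.append(float(corr[np.ix_(members[a], members[b])].min()))
    ec = float(np.mean(ec_terms))

    n_singletons = sum(1 for m in members if m.size == 1)
    s = n_singletons / (k - 1)
    cg = 1.0 - k / n
    return ValComponents(IC=ic, EC=ec, S=s, CG=cg)


def default_k_grid(n_features: int, n_points: int = 10) -> list[int]:
    """Log-spaced candidate cluster counts between 2 and min(F/2, 100)."""
    hi = max(2, min(n_features // 2, 100))
    grid = np.unique(
        np.round(np.geomspace(2, hi, num=n_points)).astype(int)
    )
    return [int(g) for g in grid if 2 <= g < n_features]


@dataclass
class TuneResult:
    best_k: int
    top2_algorithms: list[str]
    table: pd.DataFrame  # columns: algorithm, k, IC, EC, S, CG, VAL

    def clustering_for(self, algorithm: str, k: int) -> "FeatureClustering":
        key = (algorithm, int(k))
        return self._clusterings[key]

    _clusterings: dict = field(default_factory=dict, repr=False)


def tune_k(
    view: ViewMatrix,
    algorithms: list[str] | None = None,
    k_grid: list[int] | None = None,
    seed: int = 0,
    corr: np.ndarray | None = None,
) -> TuneResult:
    """Search cluster counts: per-k score is the mean VAL across algorithms.

    The k with the highest mean VAL wins (ties toward the smaller k, i.e.
    stronger compression); the two algorithms with the highest VAL at that k
    are reported as candidates for prototype extraction.
    """
    if algorithms is None:
        algorithms = list(ALGORITHMS)
    if corr is None:
        corr = correlation_matrix(view)
    if k_grid is None:
        k_grid = default_k_grid(view.n_features)
    if not k_grid:
        raise ValidationError("empty k grid")

    rows = []
    clusterings: dict[tuple[str, int], FeatureClustering] = {}
    for alg in algorithms:
        for k in k_grid:
            try:
                fc = cluster_features(view, alg, k, seed=seed, corr=corr)
                comp = val_components(fc, corr)
            except Exception as exc:  # noqa: BLE001 - cell recorded as missing
                log.warning(
                    "tune_k: %s at k=%d failed on view %s: %s",
                    alg, k, view.name, exc,
                )
                continue
            clusterings[(alg, k)] = fc
            rows.append(
                {
                    "view": view.name,
                    "algorithm": alg,
                    "k": k,
                    "IC": comp.IC,
                    "EC": comp.EC,
                    "S": comp.S,
                    "CG": comp.CG,
                    "VAL": comp.VAL,
                }
            )
    if not rows:
        raise ValidationError(f"no clustering succeeded on view {view.name!r}")
    table = pd.DataFrame(rows)
    per_k = table.groupby("k")["VAL"].mean()
    best_val = per_k.max()
    best_k = int(min(k for k, v in per_k.items() if v >= best_val - 1e-12))
    at_k = table[table["k"] == best_k].sort_values(
        ["VAL", "algorithm"], ascending=[False, True], kind="stable"
    )
    top2 = list(at_k["algorithm"].head(2))
    result = TuneResult(best_k=best_k, top2_algorithms=top2, table=table)
    result._clusterings = clusterings
    return result


def select_prototypes(fc: FeatureClustering, corr: np.ndarray) -> PrototypeSet:
    """Pick one prototype per cluster: the member with the highest mean
    correlation to the other members (ties toward the lexicographically
    smallest feature id); singletons represent themselves."""
    prototypes: list[str] = []
    for c in fc.cluster_indices:
        m = fc.members(c)
        if m.size == 1:
            prototypes.append(fc.feature_ids[int(m[0])])
            continue
        sub = corr[np.ix_(m, m)]
        mean_to_others = (sub.sum(axis=1) - 1.0) / (m.size - 1)
        candidates = sorted(
            range(m.size),
            key=lambda i: (-mean_to_others[i], fc.feature_ids[int(m[i])]),
        )
        prototypes.append(fc.feature_ids[int(m[candidates[0]])])
    return PrototypeSet(
        view_name=fc.view_name,
        prototype_ids=prototypes,
        cluster_of_feature={
            f: int(c) for f, c in zip(fc.feature_ids, fc.assignment)
        },
        chosen_algorithm=fc.algorithm,
        chosen_k=fc.k,
    )


def extract_prototypes(
    view: ViewMatrix,
    keep_fraction: float = 0.5,
    algorithms: list[str] | None = None,
    k_grid: list[int] | None = None,
    seed: int = 0,
) -> tuple[ViewMatrix, PrototypeSet, TuneResult]:
    """Full per-view reduction: filter, tune, cluster, select prototypes.

    Returns the view restricted to the prototypes, the prototype set, and the
    tuning table.  The winning algorithm is the top-ranked of the two best at
    the selected k.
    """
    filtered = variance_filter(view, keep_fraction)
    corr = correlation_matrix(filtered)
    tuned = tune_k(filtered, algorithms=algorithms, k_grid=k_grid, seed=seed, corr=corr)
    fc = tuned.clustering_for(tuned.top2_algorithms[0], tuned.best_k)
    protos = select_prototypes(fc, corr)
    reduced = filtered.restrict_features(protos.prototype_ids)
    return reduced, protos, tuned
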
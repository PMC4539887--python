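"""Per-view patient clustering on the selected prototypes.

Patients are clustered with K equal to the number of known classes (the
default; overridable), each clustering is scored against the class labels by
majority-vote impurity, and the best (algorithm, ranking method, cumulative
cut) combination is kept per view.  The winning hard partitions, encoded as
patients x clusters indicator matrices, are the inputs to late integration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._cluster import ALGORITHMS, cluster_rows
from .datatypes import LabelVector, ValidationError, ViewMatrix
from .ranking import RankedFeatures, cat_score, cumulative_cut, rf_importance
from .validation import impurity

__all__ = [
    "Membership",
    "cluster_patients",
    "clustering_error",
    "select_best_per_view",
    "BestViewClustering",
    "DEFAULT_CUTS",
]

log = logging.getLogger("mvda")

DEFAULT_CUTS = (0.6, 0.7, 0.8, 0.9)

# tie precedence when several grid cells reach the same error
_ALG_PRECEDENCE = ("kmeans", "pam", "ward", "spectral")


@dataclass
class Membership:
    """A hard patient clustering as a patients x clusters indicator matrix."""

    view_name: str
    matrix: np.ndarray  # (n_patients, n_clusters) in {0,1}
    patient_ids: list[str]
    cluster_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2:
            raise ValidationError("membership matrix must be 2-D")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValidationError("membership entries must be 0/1")
        if not np.all(self.matrix.sum(axis=1) == 1):
            raise ValidationError("each patient must belong to exactly one cluster")
        if np.any(self.matrix.sum(axis=0) == 0):
            raise ValidationError("empty cluster column; drop it before constructing")
        if self.matrix.shape[0] != len(self.patient_ids):
            raise ValidationError("row count != number of patients")
        if self.matrix.shape[1] != len(self.cluster_ids):
            raise ValidationError("column count != number of clusters")

    @property
    def n_clusters(self) -> int:
        return self.matrix.shape[1]

    @property
    def partition(self) -> np.ndarray:
        """Cluster index per patient."""
        return self.matrix.argmax(axis=1)

    @classmethod
    def from_partition(
        cls,
        partition: np.ndarray | list,
        patient_ids: list[str],
        view_name: str,
    ) -> "Membership":
        """Build an indicator membership from a label-per-patient vector.

        Empty clusters (labels never used) are dropped and logged.
        """
        part = np.asarray(partition)
        uniq = sorted(set(part.tolist()))
        matrix = np.zeros((len(patient_ids), len(uniq)), dtype=int)
        for j, u in enumerate(uniq):
            matrix[part == u, j] = 1
        return cls(
            view_name=view_name,
            matrix=matrix,
            patient_ids=list(patient_ids),
            cluster_ids=[f"{view_name}:{u}" for u in uniq],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.patient_ids, columns=self.cluster_ids)


def cluster_patients(
    view: ViewMatrix,
    algorithm: str,
    k: int,
    seed: int = 0,
    standardize: bool = True,
) -> Membership:
    """Hard-cluster patients using the view's features as coordinates."""
    n = view.n_patients
    if k > n:
        raise ValidationError(f"K={k} exceeds {n} patients")
    if k < 2:
        raise ValidationError("K must be >= 2")
    x = view.values.T.copy()  # patients x features
    if standardize:
        mu = x.mean(axis=0, keepdims=True)
        sd = x.std(axis=0, keepdims=True)
        sd[sd == 0] = 1.0
        x = (x - mu) / sd
    labels = cluster_rows(x, algorithm=algorithm, k=k, seed=seed, metric="euclidean")
    return Membership.from_partition(labels, view.patient_ids, view.name)


def clustering_error(membership: Membership, labels: LabelVector) -> float:
    """Majority-vote impurity of a clustering against the class labels.

    The dispersion of the cluster/class confusion matrix: the fraction of
    patients whose class differs from their cluster's majority class.  Shared
    with the validation module (single implementation).
    """
    if membership.patient_ids != labels.patient_ids:
        raise ValidationError("membership and labels are not aligned")
    return impurity(membership.partition, labels.labels)


@dataclass
class BestViewClustering:
    membership: Membership
    algorithm: str
    ranking_method: str
    cut: float
    error: float
    grid: pd.DataFrame  # full (algorithm, method, cut) -> error log


def _silhouette_on_correlation(view: ViewMatrix, membership: Membership) -> float:
    from sklearn.metrics import silhouette_score

    corr = np.corrcoef(view.values.T)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    return float(
        silhouette_score(dist, membership.partition, metric="precomputed")
    )


def select_best_per_view(
    view: ViewMatrix,
    labels: LabelVector | None,
    rankings: dict[str, RankedFeatures] | None = None,
    algorithms: tuple[str, ...] = _ALG_PRECEDENCE,
    cuts: tuple[float, ...] = DEFAULT_CUTS,
    k: int | None = None,
    seed: int = 0,
) -> BestViewClustering:
    """Grid-search (algorithm x ranking method x cumulative cut) for one view.

    Every candidate clustering is scored by :func:`clustering_error` and the
    argmin is returned; ties follow the precedence kmeans > pam > ward >
    spectral, then cat_score before rf_importance, then the smaller cut.
    With no labels the score is the negative silhouette in 1-correlation
    distance (lower is better, consistent with the error ordering).

    ``rankings`` maps method name to a :class:`RankedFeatures`; when omitted
    (small views) the full feature set is the only candidate.
    """
    if labels is not None and k is None:
        labels.require_supervised()
        k = labels.n_classes
    if k is None:
        raise ValidationError("k must be given when labels are absent")

    if rankings:
        candidates = [
            (method, cut, cumulative_cut(rankings[method], cut))
            for method in sorted(rankings, key=lambda m: (m != "cat_score", m))
            for cut in sorted(cuts)
        ]
    else:
        candidates = [("all", 1.0, list(view.feature_ids))]

    rows = []
    best = None
    for alg_rank, alg in enumerate(
        sorted(algorithms, key=lambda a: _ALG_PRECEDENCE.index(a))
    ):
        for meth_rank, (method, cut, features) in enumerate(candidates):
            sub = view.restrict_features(features)
            try:
                membership = cluster_patients(sub, alg, k, seed=seed)
            except Exception as exc:  # noqa: BLE001
                log.warning(
                    "select_best_per_view: %s/%s/%.1f failed on %s: %s",
                    alg, method, cut, view.name, exc,
                )
                continue
            if labels is not None:
                err = clustering_error(membership, labels)
            else:
                err = -_silhouette_on_correlation(sub, membership)
            rows.append(
                {
                    "view": view.name,
                    "algorithm": alg,
                    "ranking_method": method,
                    "cut": cut,
                    "n_features": len(features),
                    "error": err,
                }
            )
            key = (err, alg_rank, meth_rank)
            if best is None or key < best[0]:
                best = (key, membership, alg, method, cut, err)
    if best is None:
        raise ValidationError(f"no candidate clustering succeeded on {view.name!r}")
    _, membership, alg, method, cut, err = best
    return BestViewClustering(
        membership=membership,
        algorithm=alg,
        ranking_method=method,
        cut=cut,
        error=err,
        grid=pd.DataFrame(rows),
    )
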
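"""Clustering quality and stability metrics.

* :func:`impurity` — fraction of patients whose class label differs from
  their cluster's majority label.
* :func:`nmi` — mutual information between two partitions normalized by the
  cluster entropies (geometric mean by default).
* :func:`loo_stability` — leave-one-out stability: rerun a clustering
  pipeline with each patient removed in turn and average the pairwise NMI
  between the resulting partitions on their shared patients.
* :func:`borda_count` — rank aggregation of feature lists across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import normalized_mutual_info_score

from .datatypes import MultiViewDataset, ValidationError

__all__ = [
    "impurity",
    "nmi",
    "loo_stability",
    "borda_count",
    "StabilityResult",
]

log = logging.getLogger("mvda")

_NMI_NORMS = {"sqrt": "geometric", "max": "max", "mean": "arithmetic"}


def impurity(partition: Sequence, labels: Sequence) -> float:
    """Majority-vote impurity of a partition against class labels, in [0, 1].

    Invariant under relabeling of the clusters.
    """
    part = np.asarray(partition)
    labs = np.asarray(labels)
    if part.shape[0] != labs.shape[0]:
        raise ValidationError("partition and labels differ in length")
    n = part.shape[0]
    mismatched = 0
    for c in np.unique(part):
        cluster_labels = labs[part == c]
        _, counts = np.unique(cluster_labels, return_counts=True)
        mismatched += cluster_labels.size - counts.max()
    return mismatched / n


def nmi(p1: Sequence, p2: Sequence, norm: str = "sqrt") -> float:
    """Normalized mutual information between two partitions of one patient set.

    ``norm`` selects the entropy normalization: ``sqrt`` (default,
    ``I / sqrt(H1 * H2)``), ``max`` or ``mean``.  Two identical single-cluster
    partitions score 1; a constant partition against a varying one scores 0.
    """
    a = np.asarray(p1)
    b = np.asarray(p2)
    if a.shape[0] != b.shape[0]:
        raise ValidationError("partitions are over different patient sets")
    if norm not in _NMI_NORMS:
        raise ValidationError(f"unknown normalization {norm!r}")
    return float(normalized_mutual_info_score(a, b, average_method=_NMI_NORMS[norm]))


@dataclass
class StabilityResult:
    """Pairwise-NMI stability of leave-one-out reruns."""

    nmi_matrix: np.ndarray  # (N, N), symmetric, unit diagonal
    stability: float  # mean of the matrix
    partitions: list[dict]  # per run: patient_id -> cluster
    failed_runs: list[str]


def loo_stability(
    dataset: MultiViewDataset,
    pipeline: Callable[[MultiViewDataset], Sequence],
    norm: str = "sqrt",
) -> StabilityResult:
    """Leave-one-out stability of a clustering pipeline.

    ``pipeline`` maps a dataset to a cluster label per patient (aligned with
    ``dataset.patient_ids``).  It is rerun once per left-out patient; entry
    (i, j) of the matrix is the NMI between runs i and j restricted to the
    patients present in both (N - 2 of them), and the reported stability is
    the mean of the full matrix.  Failing runs are excluded and logged.
    """
    patient_ids = dataset.patient_ids
    if len(patient_ids) < 3:
        raise ValidationError("leave-one-out stability needs at least 3 patients")
    partitions: list[dict] = []
    kept: list[str] = []
    failed: list[str] = []
    for pid in patient_ids:
        sub = dataset.drop_patient(pid)
        try:
            part = np.asarray(pipeline(sub))
        except Exception as exc:  # noqa: BLE001
            log.warning("loo_stability: run without %s failed: %s", pid, exc)
            failed.append(pid)
            continue
        if part.shape[0] != sub.n_patients:
            failed.append(pid)
            log.warning("loo_stability: run without %s returned wrong length", pid)
            continue
        partitions.append(dict(zip(sub.patient_ids, part.tolist())))
        kept.append(pid)
    m = len(partitions)
    if m < 2:
        raise ValidationError("fewer than 2 leave-one-out runs succeeded")
    mat = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            common = [p for p in partitions[i] if p in partitions[j]]
            a = [partitions[i][p] for p in common]
            b = [partitions[j][p] for p in common]
            mat[i, j] = mat[j, i] = nmi(a, b, norm=norm)
    return StabilityResult(
        nmi_matrix=mat,
        stability=float(mat.mean()),
        partitions=partitions,
        failed_runs=failed,
    )


def borda_count(rank_lists: Sequence[Sequence[str]]) -> list[str]:
    """Aggregate ordered feature lists by Borda count.

    A feature at position p of a length-L list earns L - p points (top of the
    list earns L); features absent from a list earn 0 from it.  The output is
    ordered by decreasing total, ties broken lexicographically.
    """
    if not rank_lists:
        raise ValidationError("no rank lists given")
    scores: dict[str, float] = {}
    for lst in rank_lists:
        length = len(lst)
        for pos, feat in enumerate(lst):
            scores[feat] = scores.get(feat, 0.0) + (length - pos)
    return sorted(scores, key=lambda f: (-scores[f], f))
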
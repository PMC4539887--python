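"""Labeling meta-clusters and testing subclass significance.

Each meta-cluster is labeled with its majority class and tested for
enrichment of that class with a one-sided Fisher's exact test on the 2x2
table {in cluster / not in cluster} x {majority class / other classes}.
A significant meta-cluster that does not contain its whole class is a
candidate *subclass* — a coherent subgroup within a known class.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .datatypes import LabelVector, ValidationError

__all__ = ["label_and_test", "fisher_enrichment_p"]

log = logging.getLogger("mvda")


def fisher_enrichment_p(in_cluster_majority: int, cluster_size: int,
                        class_total: int, n: int) -> float:
    """One-sided Fisher p: P(X >= a) for X ~ Hypergeom(n, class_total, cluster_size)."""
    return float(hypergeom.sf(in_cluster_majority - 1, n, class_total, cluster_size))


def label_and_test(
    partition,
    labels: LabelVector,
    contributions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-meta-cluster majority label, Fisher enrichment p-value, contributions.

    Returns one row per non-empty meta-cluster with columns ``cluster``,
    ``size``, ``majority_class``, ``majority_count``, ``p_value`` (raw,
    one-sided enrichment), ``p_adj_bh`` and, when a contribution matrix is
    given, one ``contrib_<view>`` column per view.  A majority tie is broken
    toward the lexicographically smallest class label (and logged).
    """
    part = np.asarray(partition)
    labs = np.asarray(labels.labels)
    if part.shape[0] != labs.shape[0]:
        raise ValidationError("partition and labels differ in length")
    n = part.shape[0]
    class_totals = {c: int((labs == c).sum()) for c in labels.classes}

    rows = []
    for ci, c in enumerate(sorted(set(part.tolist()))):
        members = labs[part == c]
        size = int(members.size)
        if size == 0:  # pragma: no cover - argmax partitions have no empty ids
            log.warning("meta-cluster %s is empty; excluded from the report", c)
            continue
        uniq, counts = np.unique(members, return_counts=True)
        top = counts.max()
        tied = sorted(uniq[counts == top])
        if len(tied) > 1:
            log.info("meta-cluster %s: majority tie between %s; taking %s",
                     c, tied, tied[0])
        majority = tied[0]
        p = fisher_enrichment_p(int(top), size, class_totals[str(majority)], n)
        row = {
            "cluster": c,
            "size": size,
            "majority_class": str(majority),
            "majority_count": int(top),
            "p_value": p,
        }
        if contributions is not None:
            col = contributions.columns[ci]
            for view in contributions.index:
                row[f"contrib_{view}"] = float(contributions.loc[view, col])
        rows.append(row)
    report = pd.DataFrame(rows)
    report["p_adj_bh"] = multipletests(report["p_value"], method="fdr_bh")[1]
    # keep p-value columns adjacent
    cols = [c for c in report.columns if not c.startswith("contrib_")]
    cols += [c for c in report.columns if c.startswith("contrib_")]
    return report[cols]
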
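"""End-to-end orchestration of the four-stage analysis.

Stage 1 reduces each view to prototype features; stage 2 ranks prototypes by
class separability; stage 3 clusters patients per view with the best
(algorithm, ranker, cut) combination; stage 4 integrates the per-view
clusterings into meta-clusters, labels them, and reports per-view
contributions.  A leave-one-out stability wrapper reruns stages 2-4 with the
stage-1 prototypes held fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import MultiViewDataset, ValidationError, ViewMatrix
from .integration import MetaClustering, integrate
from .patients import BestViewClustering, DEFAULT_CUTS, select_best_per_view
from .prototypes import PrototypeSet, TuneResult, extract_prototypes
from .ranking import RANKING_METHODS, cat_score, rf_importance
from .subclasses import label_and_test
from .validation import StabilityResult, impurity, loo_stability, nmi

__all__ = ["MVDAConfig", "MVDAResult", "run_prototype_stage", "run_pipeline",
           "pipeline_stability"]

log = logging.getLogger("mvda")


@dataclass
class MVDAConfig:
    """Tunable knobs of the full pipeline (defaults follow the library's
    documented conventions; see docs/methods.md)."""

    keep_fraction: float = 0.5
    feature_algorithms: tuple[str, ...] = ("ward", "kmeans", "pam", "spectral")
    k_grid: tuple[int, ...] | None = None
    min_features_for_ranking: int = 10
    ranking_methods: tuple[str, ...] = RANKING_METHODS
    rf_trees: int = 300
    cuts: tuple[float, ...] = DEFAULT_CUTS
    patient_algorithms: tuple[str, ...] = ("kmeans", "pam", "ward", "spectral")
    patient_k: int | None = None  # default: number of classes
    integration_method: str = "MF"
    mode: str = "unsupervised"
    meta_k_range: tuple[int, ...] | None = None
    n_restarts: int = 10
    max_iter: int = 500
    prior_weight: float = 1.0
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class MVDAResult:
    prototypes: dict[str, PrototypeSet]
    reduced_views: dict[str, ViewMatrix]
    tuning: dict[str, TuneResult]
    rankings: dict[str, dict[str, object]]
    best_per_view: dict[str, BestViewClustering]
    meta: MetaClustering
    report: pd.DataFrame | None
    metrics: dict[str, float]


def run_prototype_stage(
    dataset: MultiViewDataset, config: MVDAConfig
) -> tuple[dict[str, ViewMatrix], dict[str, PrototypeSet], dict[str, TuneResult]]:
    """Stage 1 on every view: variance filter, k tuning, prototype selection."""
    reduced, protos, tuning = {}, {}, {}
    for view in dataset.views:
        r, p, t = extract_prototypes(
            view,
            keep_fraction=config.keep_fraction,
            algorithms=list(config.feature_algorithms),
            k_grid=list(config.k_grid) if config.k_grid else None,
            seed=config.seed,
        )
        reduced[view.name], protos[view.name], tuning[view.name] = r, p, t
        log.info("view %s: %d features -> %d prototypes (%s, k=%d)",
                 view.name, view.n_features, r.n_features,
                 p.chosen_algorithm, p.chosen_k)
    return reduced, protos, tuning


def _rank_view(view: ViewMatrix, dataset: MultiViewDataset, config: MVDAConfig):
    """Stage 2 for one reduced view; returns {} when ranking is skipped."""
    if dataset.labels is None or view.n_features < config.min_features_for_ranking:
        return {}
    rankings = {}
    if "cat_score" in config.ranking_methods:
        rankings["cat_score"] = cat_score(view, dataset.labels)
    if "rf_importance" in config.ranking_methods:
        rankings["rf_importance"] = rf_importance(
            view, dataset.labels, n_trees=config.rf_trees, seed=config.seed
        )
    # a ranker whose scores are all zero cannot be cut; drop it
    return {m: r for m, r in rankings.items() if r.scores.sum() > 0}


def run_pipeline(
    dataset: MultiViewDataset,
    config: MVDAConfig | None = None,
    reduced_views: dict[str, ViewMatrix] | None = None,
) -> MVDAResult:
    """Run stages 1-4 and assemble metrics.

    ``reduced_views`` may carry precomputed stage-1 outputs (used by the
    leave-one-out stability wrapper, where prototypes are held fixed).
    """
    config = config or MVDAConfig()
    if reduced_views is None:
        reduced_views, protos, tuning = run_prototype_stage(dataset, config)
    else:
        protos, tuning = {}, {}

    rankings: dict[str, dict] = {}
    best: dict[str, BestViewClustering] = {}
    for view in dataset.views:
        red = reduced_views[view.name]
        rk = _rank_view(red, dataset, config)
        rankings[view.name] = rk
        best[view.name] = select_best_per_view(
            red,
            dataset.labels,
            rankings=rk or None,
            algorithms=config.patient_algorithms,
            cuts=config.cuts,
            k=config.patient_k,
            seed=config.seed,
        )

    meta = integrate(
        dataset,
        [best[v.name].membership for v in dataset.views],
        method=config.integration_method,
        mode=config.mode,
        k_range=list(config.meta_k_range) if config.meta_k_range else None,
        seed=config.seed,
        prior_weight=config.prior_weight,
        n_restarts=config.n_restarts,
        max_iter=config.max_iter,
    )

    report = None
    metrics: dict[str, float] = {}
    if dataset.labels is not None:
        report = label_and_test(meta.partition, dataset.labels, meta.contributions)
        metrics["impurity"] = impurity(meta.partition, dataset.labels.labels)
        metrics["nmi_vs_classes"] = nmi(meta.partition, dataset.labels.as_codes())
        for name, b in best.items():
            metrics[f"impurity_{name}"] = b.error
    return MVDAResult(
        prototypes=protos,
        reduced_views=reduced_views,
        tuning=tuning,
        rankings=rankings,
        best_per_view=best,
        meta=meta,
        report=report,
        metrics=metrics,
    )


def pipeline_stability(
    dataset: MultiViewDataset,
    config: MVDAConfig | None = None,
    reduced_views: dict[str, ViewMatrix] | None = None,
) -> StabilityResult:
    """Leave-one-out stability of stages 2-4 with stage-1 prototypes fixed.

    The prototypes are extracted once on the full dataset; each rerun drops
    one patient, repeats ranking, patient clustering and integration, and
    the pairwise NMI matrix of the resulting meta-partitions is averaged.
    """
    config = config or MVDAConfig()
    if reduced_views is None:
        reduced_views, _, _ = run_prototype_stage(dataset, config)

    def _run(sub: MultiViewDataset) -> np.ndarray:
        sub_reduced = {
            name: v.restrict_patients(sub.patient_ids)
            for name, v in reduced_views.items()
        }
        result = run_pipeline(sub, config, reduced_views=sub_reduced)
        return result.meta.partition

    return loo_stability(dataset, _run)


def write_results(result: MVDAResult, out_dir: str | Path, config: MVDAConfig) -> None:
    """Write memberships, contributions, subclass report and manifest as text."""
    from . import io as mio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, b in result.best_per_view.items():
        b.membership.to_frame().to_csv(out / f"membership_{name}.tsv", sep="\t")
        b.grid.to_csv(out / f"grid_{name}.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"patient_id": result.meta.patient_ids, "meta_cluster": result.meta.partition}
    ).to_csv(out / "meta_partition.tsv", sep="\t", index=False)
    result.meta.contributions.to_csv(out / "contributions.tsv", sep="\t")
    if result.report is not None:
        result.report.to_csv(out / "subclass_report.tsv", sep="\t", index=False)
    manifest = {
        "config": config.to_dict(),
        "metrics": {k: float(v) for k, v in result.metrics.items()},
        "meta": {
            "method": result.meta.method,
            "k": int(result.meta.k),
            "k_effective": int(result.meta.k_effective),
            "mode": result.meta.mode,
            "converged": bool(result.meta.converged),
        },
    }
    mio.write_manifest(manifest, out / "manifest.yaml")
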
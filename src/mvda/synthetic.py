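"""Synthetic multi-view datasets with planted patient subclasses.

The generator emulates the structure that makes multi-omics subtyping
interesting: patients carry a two-level grouping (classes split into
subclasses), each view contains blocks of correlated features, and a block
can be *informative* for one subclass — its features are mean-shifted in the
patients of that subclass.  Because a subclass can be driven by a chosen
subset of views, the per-view contribution of the integration step has a
known target.

Correlated blocks use a shared-latent-factor construction,

    x = sqrt(rho) * z + sqrt(1 - rho) * eps,

which gives an exact population within-block correlation of ``rho``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datatypes import LabelVector, MultiViewDataset, ValidationError, ViewMatrix

__all__ = [
    "SyntheticViewSpec",
    "SyntheticSpec",
    "SyntheticGroundTruth",
    "generate",
    "write_synthetic",
]


@dataclass
class SyntheticViewSpec:
    """Configuration of one synthetic view.

    ``driven_subclasses`` lists the global subclass indices whose signal this
    view carries; ``None`` means every subclass.  A view that drives no
    subclass (empty tuple) is pure noise.
    """

    n_features: int = 100
    n_informative_blocks: int = 4
    block_size: int = 10
    within_block_correlation: float = 0.5
    effect_size: float = 2.0
    noise_sd: float = 1.0
    driven_subclasses: tuple[int, ...] | None = None
    name: str | None = None


@dataclass
class SyntheticSpec:
    """Full study configuration: patients, class structure, views, seed."""

    n_patients: int = 200
    n_classes: int = 2
    subclasses_per_class: tuple[int, ...] = (2, 2)
    views: tuple[SyntheticViewSpec, ...] = field(
        default_factory=lambda: (SyntheticViewSpec(), SyntheticViewSpec())
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2 or self.n_classes < 1:
            raise ValidationError("n_patients and n_classes must be positive")
        if len(self.subclasses_per_class) != self.n_classes:
            raise ValidationError(
                "subclasses_per_class must have one entry per class"
            )
        if any(s < 1 for s in self.subclasses_per_class):
            raise ValidationError("all subclass counts must be positive")
        n_sub = sum(self.subclasses_per_class)
        if self.n_patients < n_sub:
            raise ValidationError("fewer patients than subclasses")
        for i, v in enumerate(self.views):
            if v.n_features < 1 or v.block_size < 1 or v.n_informative_blocks < 0:
                raise ValidationError(f"view {i}: counts must be positive")
            if v.block_size * v.n_informative_blocks > v.n_features:
                raise ValidationError(
                    f"view {i}: {v.n_informative_blocks} blocks of size "
                    f"{v.block_size} exceed {v.n_features} features"
                )
            if not (0.0 <= v.within_block_correlation < 1.0):
                raise ValidationError(f"view {i}: correlation must be in [0,1)")
            if v.noise_sd <= 0:
                raise ValidationError(f"view {i}: noise_sd must be > 0")
            if v.driven_subclasses is not None and any(
                s < 0 or s >= n_sub for s in v.driven_subclasses
            ):
                raise ValidationError(f"view {i}: subclass index out of range")

    @property
    def n_subclasses(self) -> int:
        return sum(self.subclasses_per_class)


@dataclass
class SyntheticGroundTruth:
    """Planted structure: who belongs where, and which features/views drive it."""

    class_of_patient: list[str]
    subclass_of_patient: list[str]
    subclass_codes: np.ndarray  # global subclass index per patient
    class_codes: np.ndarray
    informative_features: dict[str, dict[int, list[str]]]  # view -> subclass -> ids
    feature_blocks: dict[str, list[list[str]]]  # view -> blocks of feature ids
    view_driving_each_subclass: dict[int, list[str]]  # subclass -> view names


def _partition_counts(total: int, groups: int) -> list[int]:
    base, extra = divmod(total, groups)
    return [base + (1 if g < extra else 0) for g in range(groups)]


def generate(spec: SyntheticSpec) -> tuple[MultiViewDataset, SyntheticGroundTruth]:
    """Generate a dataset and its ground truth; bit-reproducible from ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    n_sub = spec.n_subclasses

    # Subclass sizes: as even as possible, exact and deterministic.
    sub_sizes = _partition_counts(n, n_sub)
    subclass_codes = np.repeat(np.arange(n_sub), sub_sizes)
    sub_to_class = np.repeat(
        np.arange(spec.n_classes), list(spec.subclasses_per_class)
    )
    class_codes = sub_to_class[subclass_codes]
    width = len(str(n))
    patient_ids = [f"P{i + 1:0{width}d}" for i in range(n)]
    class_names = [f"C{c + 1}" for c in class_codes]
    sub_names = [f"C{sub_to_class[s] + 1}.S{s + 1}" for s in subclass_codes]

    views: list[ViewMatrix] = []
    informative: dict[str, dict[int, list[str]]] = {}
    blocks_of: dict[str, list[list[str]]] = {}
    driving: dict[int, list[str]] = {s: [] for s in range(n_sub)}

    for vi, vs in enumerate(spec.views):
        vname = vs.name if vs.name is not None else f"view{vi + 1}"
        fwidth = len(str(vs.n_features))
        feature_ids = [f"{vname}_f{j + 1:0{fwidth}d}" for j in range(vs.n_features)]
        rho = vs.within_block_correlation
        values = vs.noise_sd * rng.standard_normal((vs.n_features, n))
        targets = (
            tuple(range(n_sub)) if vs.driven_subclasses is None else vs.driven_subclasses
        )
        view_blocks: list[list[str]] = []
        view_info: dict[int, list[str]] = {}
        for b in range(vs.n_informative_blocks):
            rows = slice(b * vs.block_size, (b + 1) * vs.block_size)
            latent = rng.standard_normal(n)
            eps = rng.standard_normal((vs.block_size, n))
            values[rows, :] = vs.noise_sd * (
                np.sqrt(rho) * latent[None, :] + np.sqrt(1.0 - rho) * eps
            )
            ids = feature_ids[rows]
            view_blocks.append(ids)
            if targets:
                sub = targets[b % len(targets)]
                values[rows, :] += vs.effect_size * (subclass_codes == sub)[None, :]
                view_info.setdefault(sub, []).extend(ids)
                if vname not in driving[sub]:
                    driving[sub].append(vname)
        views.append(
            ViewMatrix(
                name=vname,
                values=values,
                feature_ids=feature_ids,
                patient_ids=patient_ids,
            )
        )
        informative[vname] = view_info
        blocks_of[vname] = view_blocks

    labels = LabelVector(labels=class_names, patient_ids=patient_ids)
    truth = SyntheticGroundTruth(
        class_of_patient=class_names,
        subclass_of_patient=sub_names,
        subclass_codes=subclass_codes,
        class_codes=class_codes,
        informative_features=informative,
        feature_blocks=blocks_of,
        view_driving_each_subclass=driving,
    )
    return MultiViewDataset(views=views, labels=labels), truth


def write_synthetic(
    dataset: MultiViewDataset,
    truth: SyntheticGroundTruth,
    out_dir: str | Path,
) -> None:
    """Write the generated views, labels and ground truth as TSV files."""
    from . import io as mio
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for v in dataset.views:
        mio.write_view(v, out / f"{v.name}.tsv")
    if dataset.labels is not None:
        mio.write_labels(dataset.labels, out / "labels.tsv")
    pd.DataFrame(
        {
            "patient_id": dataset.patient_ids,
            "class": truth.class_of_patient,
            "subclass": truth.subclass_of_patient,
        }
    ).to_csv(out / "ground_truth.tsv", sep="\t", index=False)
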
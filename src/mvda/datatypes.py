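"""Core containers for multi-view patient datasets.

A *view* is one omics layer (mRNA, miRNA, protein, CNV, ...) measured on a
shared set of patients, stored as a real-valued matrix with features in rows
and patients in columns.  A dataset bundles several views over the same
patient axis, optionally with a class label per patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ViewMatrix",
    "LabelVector",
    "MultiViewDataset",
]


class ValidationError(ValueError):
    """Raised when an input container violates its structural contract."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class ViewMatrix:
    """One omics layer: a features x patients real matrix with identifiers.

    Parameters
    ----------
    name
        View identifier (e.g. ``"mrna"``).
    values
        Array of shape ``(n_features, n_patients)``; must be finite.
    feature_ids, patient_ids
        Row / column identifiers, unique within the view.
    """

    name: str
    values: np.ndarray
    feature_ids: list[str]
    patient_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError(f"view {self.name!r}: values must be 2-D")
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.patient_ids = [str(p) for p in self.patient_ids]
        if self.values.shape[0] != len(self.feature_ids):
            raise ValidationError(
                f"view {self.name!r}: {self.values.shape[0]} rows but "
                f"{len(self.feature_ids)} feature ids"
            )
        if self.values.shape[1] != len(self.patient_ids):
            raise ValidationError(
                f"view {self.name!r}: {self.values.shape[1]} columns but "
                f"{len(self.patient_ids)} patient ids"
            )
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.patient_ids, "patient")
        if not np.all(np.isfinite(self.values)):
            r, c = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"view {self.name!r}: non-finite value at feature "
                f"{self.feature_ids[r]!r}, patient {self.patient_ids[c]!r} "
                "(load with imputation enabled or clean the input)"
            )

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_patients(self) -> int:
        return self.values.shape[1]

    def restrict_features(self, feature_ids: Sequence[str]) -> "ViewMatrix":
        """Return a copy restricted to ``feature_ids`` in the given order."""
        index = {f: i for i, f in enumerate(self.feature_ids)}
        try:
            rows = [index[f] for f in feature_ids]
        except KeyError as exc:  # pragma: no cover - defensive
            raise ValidationError(f"unknown feature id {exc.args[0]!r}") from exc
        return ViewMatrix(
            name=self.name,
            values=self.values[rows, :].copy(),
            feature_ids=list(feature_ids),
            patient_ids=list(self.patient_ids),
        )

    def restrict_patients(self, patient_ids: Sequence[str]) -> "ViewMatrix":
        """Return a copy restricted to ``patient_ids`` in the given order."""
        index = {p: i for i, p in enumerate(self.patient_ids)}
        try:
            cols = [index[p] for p in patient_ids]
        except KeyError as exc:
            raise ValidationError(f"unknown patient id {exc.args[0]!r}") from exc
        return ViewMatrix(
            name=self.name,
            values=self.values[:, cols].copy(),
            feature_ids=list(self.feature_ids),
            patient_ids=list(patient_ids),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.patient_ids
        )


@dataclass
class LabelVector:
    """Class labels aligned to a patient axis."""

    labels: list[str]
    patient_ids: list[str]

    def __post_init__(self) -> None:
        self.labels = [str(l) for l in self.labels]
        self.patient_ids = [str(p) for p in self.patient_ids]
        if len(self.labels) != len(self.patient_ids):
            raise ValidationError(
                f"{len(self.labels)} labels but {len(self.patient_ids)} patients"
            )
        _check_unique(self.patient_ids, "patient")

    @property
    def classes(self) -> list[str]:
        """Distinct class labels, lexicographically ordered."""
        return sorted(set(self.labels))

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def as_codes(self) -> np.ndarray:
        """Integer codes following the order of :attr:`classes`."""
        lut = {c: i for i, c in enumerate(self.classes)}
        return np.array([lut[l] for l in self.labels], dtype=int)

    def restrict(self, patient_ids: Sequence[str]) -> "LabelVector":
        index = {p: i for i, p in enumerate(self.patient_ids)}
        try:
            rows = [index[p] for p in patient_ids]
        except KeyError as exc:
            raise ValidationError(f"unknown patient id {exc.args[0]!r}") from exc
        return LabelVector(
            labels=[self.labels[i] for i in rows], patient_ids=list(patient_ids)
        )

    def require_supervised(self) -> None:
        if self.n_classes < 2:
            raise ValidationError(
                "supervised steps require at least 2 distinct classes"
            )


@dataclass
class MultiViewDataset:
    """An ordered collection of views sharing one patient axis."""

    views: list[ViewMatrix]
    labels: LabelVector | None = None

    def __post_init__(self) -> None:
        if not self.views:
            raise ValidationError("a dataset needs at least one view")
        ref = self.views[0].patient_ids
        for v in self.views[1:]:
            if v.patient_ids != ref:
                raise ValidationError(
                    f"view {v.name!r} has a different patient axis than "
                    f"{self.views[0].name!r}; align the dataset first"
                )
        if self.labels is not None and self.labels.patient_ids != ref:
            raise ValidationError("labels are not aligned to the view patient axis")
        _check_unique([v.name for v in self.views], "view")

    @property
    def patient_ids(self) -> list[str]:
        return self.views[0].patient_ids

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def view_names(self) -> list[str]:
        return [v.name for v in self.views]

    def view(self, name: str) -> ViewMatrix:
        for v in self.views:
            if v.name == name:
                return v
        raise KeyError(name)

    def drop_patient(self, patient_id: str) -> "MultiViewDataset":
        """Leave-one-out helper: dataset without one patient."""
        keep = [p for p in self.patient_ids if p != patient_id]
        if len(keep) == len(self.patient_ids):
            raise KeyError(patient_id)
        return MultiViewDataset(
            views=[v.restrict_patients(keep) for v in self.views],
            labels=self.labels.restrict(keep) if self.labels is not None else None,
        )
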
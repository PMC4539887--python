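"""Reading and writing delimited matrices, labels and run artifacts.

Matrices are plain delimited text (TSV by default, comma autodetected from
the header line) with a header row of patient ids and a first column of
feature ids.  Decimal points only; no locale-specific separators.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .datatypes import LabelVector, MultiViewDataset, ValidationError, ViewMatrix

__all__ = [
    "load_view",
    "write_view",
    "load_labels",
    "write_labels",
    "align_dataset",
    "write_manifest",
]

log = logging.getLogger("mvda")

_NA_MARKERS = {"", "na", "nan", "null", "n/a"}


def _sniff_sep(path: Path) -> str:
    header = path.open("r", encoding="utf-8").readline()
    return "\t" if "\t" in header else ","


def _parse_cell(raw: str, row_id: str, col_id: str) -> float:
    s = raw.strip()
    if s.lower() in _NA_MARKERS:
        return np.nan
    try:
        return float(s)
    except ValueError:
        raise ValidationError(
            f"malformed numeric cell {raw!r} at row {row_id!r}, column {col_id!r}"
        ) from None


def load_view(
    path: str | Path,
    orientation: str = "features_in_rows",
    name: str | None = None,
    missing: str = "reject",
) -> ViewMatrix:
    """Load one view from a delimited text file.

    Parameters
    ----------
    path
        Delimited file with a header row and an id column.
    orientation
        ``"features_in_rows"`` (default) or ``"patients_in_rows"``; the
        returned matrix is always features x patients.
    missing
        ``"reject"`` (default) raises on any missing cell;
        ``"median_impute"`` replaces missing cells by the per-feature median.
    """
    path = Path(path)
    if orientation not in ("features_in_rows", "patients_in_rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    if missing not in ("reject", "median_impute"):
        raise ValidationError(f"unknown missing-value policy {missing!r}")
    sep = _sniff_sep(path)
    frame = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    row_ids = [str(i) for i in frame.index]
    col_ids = [str(c) for c in frame.columns]
    if len(set(row_ids)) != len(row_ids):
        dup = next(i for i in row_ids if row_ids.count(i) > 1)
        raise ValidationError(f"duplicate id {dup!r} in {path.name}")
    values = np.empty(frame.shape, dtype=float)
    raw = frame.to_numpy()
    for i, rid in enumerate(row_ids):
        for j, cid in enumerate(col_ids):
            values[i, j] = _parse_cell(raw[i, j], rid, cid)
    if orientation == "patients_in_rows":
        values = values.T
        feature_ids, patient_ids = col_ids, row_ids
    else:
        feature_ids, patient_ids = row_ids, col_ids
    n_missing = int(np.isnan(values).sum())
    if n_missing:
        if missing == "reject":
            r, c = np.argwhere(np.isnan(values))[0]
            raise ValidationError(
                f"{path.name}: missing value at feature {feature_ids[r]!r}, "
                f"patient {patient_ids[c]!r} (policy 'reject')"
            )
        med = np.nanmedian(values, axis=1, keepdims=True)
        idx = np.where(np.isnan(values))
        values[idx] = np.take(med[:, 0], idx[0])
        log.info("%s: imputed %d missing cells with feature medians", path.name, n_missing)
    return ViewMatrix(
        name=name if name is not None else path.stem,
        values=values,
        feature_ids=feature_ids,
        patient_ids=patient_ids,
    )


def write_view(view: ViewMatrix, path: str | Path, sep: str = "\t") -> None:
    view.to_frame().to_csv(Path(path), sep=sep, index_label="feature_id")


def load_labels(path: str | Path) -> LabelVector:
    """Load a two-column (patient_id, class) delimited file."""
    path = Path(path)
    sep = _sniff_sep(path)
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if frame.shape[1] < 2:
        raise ValidationError(f"{path.name}: expected (patient_id, class) columns")
    return LabelVector(
        labels=list(frame.iloc[:, 1]), patient_ids=list(frame.iloc[:, 0])
    )


def write_labels(labels: LabelVector, path: str | Path, sep: str = "\t") -> None:
    pd.DataFrame(
        {"patient_id": labels.patient_ids, "class": labels.labels}
    ).to_csv(Path(path), sep=sep, index=False)


def align_dataset(
    views: Sequence[ViewMatrix], labels: LabelVector | None = None
) -> MultiViewDataset:
    """Restrict views (and labels) to the shared patients, canonically ordered.

    The canonical order is the lexicographic sort of the patient-id
    intersection, which makes runs reproducible regardless of input file
    order.  Idempotent: aligning an aligned dataset changes nothing.
    """
    if not views:
        raise ValidationError("no views given")
    common = set(views[0].patient_ids)
    for v in views[1:]:
        common &= set(v.patient_ids)
    if labels is not None:
        common &= set(labels.patient_ids)
    if len(common) < 2:
        raise ValidationError(
            f"patient intersection across views has {len(common)} patients; "
            "need at least 2"
        )
    order = sorted(common)
    dropped = {v.name: len(v.patient_ids) - len(order) for v in views}
    if any(dropped.values()):
        log.info("align_dataset: dropped patients per view: %s", dropped)
    log.debug("align_dataset: canonical patient order: %s", order)
    return MultiViewDataset(
        views=[v.restrict_patients(order) for v in views],
        labels=labels.restrict(order) if labels is not None else None,
    )


def write_manifest(config: dict, path: str | Path) -> None:
    """Write a machine-readable run manifest (YAML) echoing configuration."""
    with Path(path).open("w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
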
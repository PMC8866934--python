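"""Reading, validating and assembling the per-cell and clinical tables.

Two delimited text tables define a cohort:

``cells.csv``
    one row per sorted cell: ``patient_id, cell_id, cell_class`` followed by
    the 34 feature columns named ``<parameter>_<channel>`` (see
    :mod:`ctcstrat.vocab`).  Extra columns are preserved as pass-through
    metadata.

``clinical.csv``
    one row per patient: ``patient_id, os_months, os_event, bone_met``.

Both tables are comma-separated UTF-8 with ``.`` decimal and a header row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, TableParseError, ValidationError
from .vocab import CHANNELS, FLUOR_CHANNELS, FEATURE_NAMES, CellClass

#: Dichotomization horizon for overall survival, months.
DEFAULT_OS_THRESHOLD = 30.0

_CELL_REQUIRED = ("patient_id", "cell_id", "cell_class") + FEATURE_NAMES
_CLINICAL_REQUIRED = ("patient_id", "os_months", "os_event", "bone_met")


@dataclass(frozen=True)
class CellRecord:
    """One sorted cell with its 34 image-derived features."""

    patient_id: str
    cell_id: str
    cell_class: CellClass
    features: Mapping[str, float]
    extra: Mapping[str, str] = field(default_factory=dict)

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems: list[str] = []
        missing = set(FEATURE_NAMES) - set(self.features)
        unknown = set(self.features) - set(FEATURE_NAMES)
        if missing:
            problems.append(f"missing features {sorted(missing)}")
        if unknown:
            problems.append(f"unknown features {sorted(unknown)}")
        if missing or unknown:
            return problems
        f = self.features
        for ch in CHANNELS:
            for par in ("circularity", "circularityOV"):
                v = f[f"{par}_{ch}"]
                if not (0.0 < v <= 1.0):
                    problems.append(f"{par}_{ch}={v} outside (0, 1]")
            for par in ("diameter", "perimeter", "mean_intensity", "max_intensity"):
                if f[f"{par}_{ch}"] < 0:
                    problems.append(f"{par}_{ch}={f[f'{par}_{ch}']} negative")
        for ch in FLUOR_CHANNELS:
            bg = f[f"mean_intensity_bgsub_{ch}"]
            if bg < 0:
                problems.append(f"mean_intensity_bgsub_{ch}={bg} negative")
            if bg > f[f"mean_intensity_{ch}"] + 1e-9:
                problems.append(
                    f"mean_intensity_bgsub_{ch}={bg} exceeds mean_intensity_{ch}"
                )
        return problems


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-patient outcomes: follow-up, vital status and bone metastasis.

    ``os_class`` dichotomizes overall survival at a horizon (default 30
    months): a patient observed or censored beyond the horizon survived past
    it; a patient who died at or before it did not; a patient censored at or
    before the horizon is indeterminate (``None``).
    """

    patient_id: str
    os_months: float
    os_event: bool
    bone_met: bool
    os_threshold: float = DEFAULT_OS_THRESHOLD

    def __post_init__(self) -> None:
        if not (self.os_months >= 0) or math.isnan(self.os_months):
            raise ValidationError(
                f"patient {self.patient_id!r}: os_months={self.os_months} must be >= 0"
            )

    @property
    def os_class(self) -> Optional[bool]:
        if self.os_months > self.os_threshold:
            return True
        if self.os_event:
            return False
        return None  # censored before the horizon: unknowable

    @property
    def os_indeterminate(self) -> bool:
        return self.os_class is None


@dataclass
class Cohort:
    """Cross-referenced per-cell and clinical tables."""

    cells: list[CellRecord]
    clinical: list[ClinicalRecord]

    @property
    def patient_ids(self) -> list[str]:
        return [c.patient_id for c in self.clinical]

    def cells_frame(self) -> pd.DataFrame:
        """Long per-cell table (one row per cell, 34 feature columns)."""
        rows = []
        for c in self.cells:
            row = {"patient_id": c.patient_id, "cell_id": c.cell_id,
                   "cell_class": c.cell_class.value}
            row.update(c.features)
            rows.append(row)
        return pd.DataFrame(rows, columns=list(_CELL_REQUIRED))

    def clinical_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": [r.patient_id for r in self.clinical],
                "os_months": [r.os_months for r in self.clinical],
                "os_event": [r.os_event for r in self.clinical],
                "bone_met": [r.bone_met for r in self.clinical],
            }
        )

    def cell_counts(self) -> pd.DataFrame:
        """Per-patient tallies (all clinical patients, zeros included)."""
        counts = pd.DataFrame(
            0,
            index=pd.Index(self.patient_ids, name="patient_id"),
            columns=["total_cells", "n_CD45pos", "n_eCTC"],
        )
        for c in self.cells:
            counts.loc[c.patient_id, "total_cells"] += 1
            if c.cell_class is CellClass.CD45POS:
                counts.loc[c.patient_id, "n_CD45pos"] += 1
            elif c.cell_class is CellClass.ECTC:
                counts.loc[c.patient_id, "n_eCTC"] += 1
        return counts


def _parse_bool(value, column: str, row: int) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in {"1", "true", "t", "yes"}:
        return True
    if s in {"0", "false", "f", "no"}:
        return False
    raise TableParseError(f"row {row}: cannot parse {column}={value!r} as boolean")


def read_cell_table(path: str | Path, dialect: Optional[dict] = None) -> list[CellRecord]:
    """Read and validate a per-cell feature table.

    Raises :class:`SchemaError` for missing columns, :class:`TableParseError`
    for non-numeric feature values (with the offending row number) and
    :class:`ValidationError` for unknown class labels or invariant
    violations (listing the offending cells).
    """
    dialect = dialect or {}
    df = pd.read_csv(path, sep=dialect.get("sep", ","),
                     decimal=dialect.get("decimal", "."),
                     dtype={"patient_id": str, "cell_id": str},
                     float_precision="round_trip")
    missing = [c for c in _CELL_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"cell table {path}: missing required column(s) {missing}")

    for col in FEATURE_NAMES:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            # +2: header line plus 1-based indexing
            raise TableParseError(
                f"cell table {path}: non-numeric value {df.loc[bad[0], col]!r} "
                f"in column {col}, row {bad[0] + 2}"
            )
        if coerced.isna().any():
            r = int(df.index[coerced.isna()][0])
            raise TableParseError(
                f"cell table {path}: empty value in column {col}, row {r + 2}"
            )
        df[col] = coerced.astype(float)

    valid_labels = {c.value for c in CellClass}
    unknown = sorted(set(df["cell_class"].astype(str)) - valid_labels)
    if unknown:
        raise ValidationError(
            f"cell table {path}: unknown cell_class label(s) {unknown}; "
            f"expected one of {sorted(valid_labels)}"
        )

    extra_cols = [c for c in df.columns if c not in _CELL_REQUIRED]
    records: list[CellRecord] = []
    offenders: list[str] = []
    for _, row in df.iterrows():
        rec = CellRecord(
            patient_id=str(row["patient_id"]),
            cell_id=str(row["cell_id"]),
            cell_class=CellClass(row["cell_class"]),
            features={k: float(row[k]) for k in FEATURE_NAMES},
            extra={k: str(row[k]) for k in extra_cols},
        )
        problems = rec.validate()
        if problems:
            offenders.append(f"cell {rec.patient_id}/{rec.cell_id}: {'; '.join(problems)}")
        records.append(rec)
    if offenders:
        raise ValidationError(
            f"cell table {path}: {len(offenders)} invalid cell(s):\n" + "\n".join(offenders)
        )
    return records


def read_clinical_table(path: str | Path,
                        os_threshold: float = DEFAULT_OS_THRESHOLD) -> list[ClinicalRecord]:
    """Read and validate the per-patient clinical table."""
    df = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")
    missing = [c for c in _CLINICAL_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"clinical table {path}: missing required column(s) {missing}")
    dup = df["patient_id"][df["patient_id"].duplicated()].tolist()
    if dup:
        raise ValidationError(f"clinical table {path}: duplicate patient_id(s) {sorted(set(dup))}")
    records = []
    for i, row in df.iterrows():
        os_months = float(row["os_months"])
        if os_months < 0 or math.isnan(os_months):
            raise ValidationError(
                f"clinical table {path}: negative os_months for patient {row['patient_id']!r}"
            )
        records.append(
            ClinicalRecord(
                patient_id=str(row["patient_id"]),
                os_months=os_months,
                os_event=_parse_bool(row["os_event"], "os_event", i + 2),
                bone_met=_parse_bool(row["bone_met"], "bone_met", i + 2),
                os_threshold=os_threshold,
            )
        )
    return records


def assemble_cohort(cells: Sequence[CellRecord],
                    clinical: Sequence[ClinicalRecord]) -> Cohort:
    """Cross-reference the two tables into a :class:`Cohort`.

    Every cell must belong to a clinical patient; duplicate
    ``(patient_id, cell_id)`` pairs are rejected.  Patients with zero cells
    of some (or every) class are legitimate and retained.
    """
    known = {r.patient_id for r in clinical}
    if len(known) != len(clinical):
        raise ValidationError("duplicate patient_id in clinical records")
    orphans = sorted({c.patient_id for c in cells} - known)
    if orphans:
        raise ValidationError(f"cells reference patient_id(s) absent from clinical: {orphans}")
    seen: set[tuple[str, str]] = set()
    for c in cells:
        key = (c.patient_id, c.cell_id)
        if key in seen:
            raise ValidationError(f"duplicate cell {key}")
        seen.add(key)
    return Cohort(cells=list(cells), clinical=list(clinical))


def write_cell_table(cells: Iterable[CellRecord], path: str | Path) -> None:
    rows = []
    for c in cells:
        row = {"patient_id": c.patient_id, "cell_id": c.cell_id,
               "cell_class": c.cell_class.value}
        row.update({k: c.features[k] for k in FEATURE_NAMES})
        row.update(c.extra)
        rows.append(row)
    # %.17g keeps every float bit, so write -> read is an exact identity
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def write_clinical_table(clinical: Iterable[ClinicalRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in clinical],
            "os_months": [r.os_months for r in clinical],
            "os_event": [r.os_event for r in clinical],
            "bone_met": [r.bone_met for r in clinical],
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_cohort(directory: str | Path,
                os_threshold: float = DEFAULT_OS_THRESHOLD) -> Cohort:
    """Read ``cells.csv`` + ``clinical.csv`` from a directory."""
    directory = Path(directory)
    cells = read_cell_table(directory / "cells.csv")
    clinical = read_clinical_table(directory / "clinical.csv", os_threshold=os_threshold)
    return assemble_cohort(cells, clinical)


def write_cohort(cohort: Cohort, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_cell_table(cohort.cells, directory / "cells.csv")
    write_clinical_table(cohort.clinical, directory / "clinical.csv")
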
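"""Per-patient aggregation of single-cell features into a design matrix.

Single cells are not comparable across patients, so each patient's cell
population (per class) is summarized by five descriptive statistics per
feature — mean, sample SD, 25th percentile, median, 75th percentile —
yielding 34 x 5 = 170 columns per cell class, plus cell-count features
(total cells, absolute and relative eCTC / CD45pos counts).

Percentiles use linear interpolation between order statistics
(h = (n-1)p); the SD uses the n-1 denominator.  A patient with no cells of
a class gets missing markers for that class's statistics (never an
exception); a single cell leaves the SD missing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import CellRecord, Cohort
from .errors import AnalysisError
from .vocab import COUNT_COLUMNS, FEATURE_NAMES, STATISTICS, CellClass

_CLASS_CHOICES = ("eCTC", "CD45pos", "both")
_TARGET_CHOICES = ("OS", "BM")


def summarize(values: Sequence[float], statistic: str) -> float:
    """One descriptive statistic of a value list; NaN when undefined."""
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; expected one of {STATISTICS}")
    arr = np.asarray(values, float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        return float("nan")
    if statistic == "mean":
        return float(arr.mean())
    if statistic == "SD":
        return float(arr.std(ddof=1)) if arr.size >= 2 else float("nan")
    q = {"25th": 25, "median": 50, "75th": 75}[statistic]
    return float(np.percentile(arr, q))  # linear interpolation


def _class_stats_frame(cell_df: pd.DataFrame, cls: CellClass) -> pd.DataFrame:
    """Patients x 170 statistics for one cell class (patients with cells only)."""
    sub = cell_df[cell_df["cell_class"] == cls.value]
    if sub.empty:
        return pd.DataFrame(
            columns=[f"{f}_{s}" for f in FEATURE_NAMES for s in STATISTICS]
        )
    g = sub.groupby("patient_id")[list(FEATURE_NAMES)]
    pieces = {
        "mean": g.mean(),
        "SD": g.std(ddof=1),
        "25th": g.quantile(0.25),
        "median": g.quantile(0.5),
        "75th": g.quantile(0.75),
    }
    out = pd.concat(
        {s: frame for s, frame in pieces.items()}, axis=1
    )  # columns: (stat, feature)
    out.columns = [f"{feat}_{stat}" for stat, feat in out.columns]
    return out[[f"{f}_{s}" for f in FEATURE_NAMES for s in STATISTICS]]


def _count_features(cell_df: pd.DataFrame, patient_ids: Sequence[str],
                    pct_ectc_denominator: str = "non_cd45") -> pd.DataFrame:
    """Cell-count features for every clinical patient (zeros allowed).

    ``pct_eCTC`` is the fraction of eCTC among the patient's CTC-candidate
    cells, i.e. all non-CD45pos cells (configurable to ``"total"``).
    """
    idx = pd.Index(patient_ids, name="patient_id")
    total = cell_df.groupby("patient_id").size().reindex(idx, fill_value=0)
    by_class = (
        cell_df.groupby(["patient_id", "cell_class"]).size().unstack(fill_value=0)
    )
    n_ectc = by_class.get(CellClass.ECTC.value, pd.Series(0, index=by_class.index))
    n_cd45 = by_class.get(CellClass.CD45POS.value, pd.Series(0, index=by_class.index))
    n_ectc = n_ectc.reindex(idx, fill_value=0)
    n_cd45 = n_cd45.reindex(idx, fill_value=0)
    if pct_ectc_denominator == "non_cd45":
        denom = (total - n_cd45).astype(float)
    elif pct_ectc_denominator == "total":
        denom = total.astype(float)
    else:
        raise ValueError(f"unknown pct_eCTC denominator {pct_ectc_denominator!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_ectc = np.where(denom > 0, n_ectc / denom, np.nan)
        pct_cd45 = np.where(total > 0, n_cd45 / total.astype(float), np.nan)
    return pd.DataFrame(
        {
            "total_cells": total.astype(float),
            "n_eCTC": n_ectc.astype(float),
            "n_CD45pos": n_cd45.astype(float),
            "pct_eCTC": pct_ectc,
            "pct_CD45pos": pct_cd45,
        },
        index=idx,
    )


def aggregate_patient(cells: Sequence[CellRecord], cls: CellClass) -> dict[str, float]:
    """170 statistics + counts for a single patient's cells of one class."""
    pids = {c.patient_id for c in cells}
    if len(pids) > 1:
        raise ValueError(f"cells belong to multiple patients: {sorted(pids)}")
    out: dict[str, float] = {}
    class_cells = [c for c in cells if c.cell_class is cls]
    for f in FEATURE_NAMES:
        values = [c.features[f] for c in class_cells]
        for s in STATISTICS:
            out[f"{f}_{s}"] = summarize(values, s)
    n_ectc = sum(c.cell_class is CellClass.ECTC for c in cells)
    n_cd45 = sum(c.cell_class is CellClass.CD45POS for c in cells)
    total = len(cells)
    out["total_cells"] = float(total)
    out["n_eCTC"] = float(n_ectc)
    out["n_CD45pos"] = float(n_cd45)
    non_cd45 = total - n_cd45
    out["pct_eCTC"] = n_ectc / non_cd45 if non_cd45 else float("nan")
    out["pct_CD45pos"] = n_cd45 / total if total else float("nan")
    return out


@dataclass
class CohortMatrix:
    """Patients x features design matrix with a binary target and survival columns."""

    X: pd.DataFrame            # indexed by patient_id
    y: np.ndarray              # bool, aligned with X rows
    target: str                # "OS" or "BM"
    cell_class: str            # "eCTC", "CD45pos" or "both"
    os_months: np.ndarray
    os_event: np.ndarray

    @property
    def patient_ids(self) -> list[str]:
        return list(self.X.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y):
            raise ValueError("X / y length mismatch")
        all_missing = [c for c in self.X.columns if self.X[c].isna().all()]
        if all_missing:
            raise AnalysisError(f"feature column(s) entirely missing: {all_missing}")

    def to_csv(self, path) -> None:
        out = self.X.copy()
        out.insert(0, "target", self.y.astype(int))
        out.insert(1, "os_months", self.os_months)
        out.insert(2, "os_event", self.os_event.astype(int))
        out.to_csv(path, index=True, index_label="patient_id")

    @classmethod
    def from_csv(cls, path, target: str = "OS", cell_class: str = "eCTC") -> "CohortMatrix":
        df = pd.read_csv(path, dtype={"patient_id": str}).set_index("patient_id")
        y = df.pop("target").astype(bool).to_numpy()
        os_months = df.pop("os_months").to_numpy(float)
        os_event = df.pop("os_event").astype(bool).to_numpy()
        return cls(X=df, y=y, target=target, cell_class=cell_class,
                   os_months=os_months, os_event=os_event)


def build_matrix(cohort: Cohort, cls: str = "eCTC", target: str = "OS",
                 os_threshold: Optional[float] = None,
                 pct_ectc_denominator: str = "non_cd45") -> CohortMatrix:
    """Assemble the design matrix for one cell class and one binary target.

    * single-class matrices drop patients without any cell of that class;
    * ``cls="both"`` takes the union of both classes' statistics with class
      prefixes, keeping patients with at least one cell of either class;
    * ``target="OS"`` excludes patients whose 30-month status is
      indeterminate (censored at or before the horizon).
    """
    if cls not in _CLASS_CHOICES:
        raise ValueError(f"cls must be one of {_CLASS_CHOICES}")
    if target not in _TARGET_CHOICES:
        raise ValueError(f"target must be one of {_TARGET_CHOICES}")

    cell_df = cohort.cells_frame()
    clin = {r.patient_id: r for r in cohort.clinical}
    counts = _count_features(cell_df, cohort.patient_ids, pct_ectc_denominator)

    if cls == "both":
        ectc = _class_stats_frame(cell_df, CellClass.ECTC).add_prefix("eCTC_")
        cd45 = _class_stats_frame(cell_df, CellClass.CD45POS).add_prefix("CD45pos_")
        stats = ectc.join(cd45, how="outer")
    else:
        cc = CellClass.ECTC if cls == "eCTC" else CellClass.CD45POS
        stats = _class_stats_frame(cell_df, cc)
    stats.index.name = "patient_id"
    # patients with zero cells of the requested class(es) are dropped
    keep = [p for p in cohort.patient_ids if p in stats.index]
    X = stats.loc[keep].join(counts.loc[keep])

    rows, ys, os_m, os_e = [], [], [], []
    for pid in keep:
        rec = clin[pid]
        if os_threshold is not None:
            from dataclasses import replace
            rec = replace(rec, os_threshold=os_threshold)
        if target == "OS":
            label = rec.os_class
            if label is None:
                continue  # indeterminate: censored before the horizon
        else:
            label = rec.bone_met
        rows.append(pid)
        ys.append(bool(label))
        os_m.append(rec.os_months)
        os_e.append(rec.os_event)

    y = np.asarray(ys, bool)
    for level in (True, False):
        if (y == level).sum() < 2:
            raise AnalysisError(
                f"target {target} level {level} has fewer than 2 patients after "
                "exclusions (for OS, patients censored before the horizon are "
                "indeterminate and excluded)"
            )
    Xr = X.loc[rows]
    dead = [c for c in Xr.columns if Xr[c].isna().all()]
    if dead:
        import warnings

        warnings.warn(
            f"dropping {len(dead)} feature column(s) with no observed value: {dead[:5]}...",
            stacklevel=2,
        )
        Xr = Xr.drop(columns=dead)
    return CohortMatrix(
        X=Xr,
        y=y,
        target=target,
        cell_class=cls,
        os_months=np.asarray(os_m, float),
        os_event=np.asarray(os_e, bool),
    )
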
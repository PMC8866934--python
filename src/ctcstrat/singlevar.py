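"""Single-variable analysis: Youden-optimal cutoff and leave-one-out prediction.

For one feature, ROC-style threshold analysis picks the cutoff maximizing
the Youden index J = sensitivity + specificity - 1, scanning midpoints
between consecutive distinct values in both orientations (high predicts
positive / low predicts positive).  Out-of-sample predictions use
leave-one-out: the cutoff is re-fit on every subset of n-1 patients and
applied to the held-out patient, so no prediction ever sees its own row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .aggregate import CohortMatrix
from .errors import AnalysisError

HIGH = "high_predicts_positive"
LOW = "low_predicts_positive"


@dataclass(frozen=True)
class CutoffResult:
    """Best threshold for one feature against a binary target."""

    cutoff: float
    orientation: str  # HIGH or LOW
    youden_j: float
    sensitivity: float
    specificity: float

    def classify(self, values) -> np.ndarray:
        values = np.asarray(values, float)
        if self.orientation == HIGH:
            return values > self.cutoff
        return values <= self.cutoff


@dataclass(frozen=True)
class BinaryMetrics:
    """2x2 contingency table with derived predictive metrics.

    Ratios with a zero denominator are NaN and listed in ``undefined``
    rather than silently reported as 0.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    @staticmethod
    def _ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")

    @property
    def ppv(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self._ratio(self.tn, self.tn + self.fn)

    @property
    def sensitivity(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        return self._ratio(self.tp + self.tn, self.tp + self.fp + self.fn + self.tn)

    @property
    def undefined(self) -> frozenset[str]:
        out = set()
        for name in ("ppv", "npv", "sensitivity", "specificity", "accuracy"):
            if np.isnan(getattr(self, name)):
                out.add(name)
        return frozenset(out)

    def as_dict(self) -> dict[str, float]:
        return {
            "TP": self.tp, "FP": self.fp, "FN": self.fn, "TN": self.tn,
            "PPV": self.ppv, "NPV": self.npv,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "accuracy": self.accuracy,
        }


def contingency_metrics(predicted, actual) -> BinaryMetrics:
    """Tabulate predictions against truth; exact counts, no rounding."""
    predicted = np.asarray(predicted, bool)
    actual = np.asarray(actual, bool)
    if predicted.shape != actual.shape:
        raise ValueError(f"length mismatch: {predicted.shape} vs {actual.shape}")
    return BinaryMetrics(
        tp=int((predicted & actual).sum()),
        fp=int((predicted & ~actual).sum()),
        fn=int((~predicted & actual).sum()),
        tn=int((~predicted & ~actual).sum()),
    )


def best_cutoff(values, target) -> CutoffResult:
    """Maximal-Youden cutoff over all candidate thresholds and orientations.

    Candidates are midpoints between consecutive sorted distinct values.
    Ties prefer the smallest cutoff, then the high-predicts-positive
    orientation.  A constant feature yields the degenerate J = 0 result
    with a warning.
    """
    values = np.asarray(values, float)
    target = np.asarray(target, bool)
    if values.shape != target.shape:
        raise ValueError("values / target length mismatch")
    if np.isnan(values).any():
        raise ValueError("values contain NaN; impute before cutoff fitting")
    if target.all() or not target.any():
        raise AnalysisError("both target levels must be present to fit a cutoff")

    distinct = np.unique(values)
    if distinct.size < 2:
        warnings.warn("constant feature: degenerate cutoff with J = 0", stacklevel=2)
        return CutoffResult(cutoff=float(distinct[0]), orientation=HIGH,
                            youden_j=0.0, sensitivity=0.0, specificity=1.0)

    n_pos = int(target.sum())
    n_neg = int(target.size - n_pos)
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    best: Optional[CutoffResult] = None
    for cut in candidates:
        high = values > cut
        tp_h = int((high & target).sum())
        tn_h = int((~high & ~target).sum())
        for orientation in (HIGH, LOW):
            if orientation == HIGH:
                sens, spec = tp_h / n_pos, tn_h / n_neg
            else:
                sens = (n_pos - tp_h) / n_pos
                spec = (n_neg - tn_h) / n_neg
            j = sens + spec - 1.0
            if best is None or j > best.youden_j + 1e-12:
                best = CutoffResult(float(cut), orientation, j, sens, spec)
    assert best is not None
    return best


@dataclass
class SingleVariableLOO:
    """Leave-one-out cutoff predictions for one feature."""

    feature: str
    predictions: np.ndarray            # bool, aligned with matrix rows
    cutoffs: list[CutoffResult]        # per fold
    metrics: BinaryMetrics


def loo_single_variable(matrix: CohortMatrix, feature: str) -> SingleVariableLOO:
    """LOO prediction: each patient classified by a cutoff fit without it.

    Missing feature values are imputed with the training-fold median (never
    using the held-out patient).
    """
    if feature not in matrix.feature_names:
        raise KeyError(f"feature {feature!r} not in matrix")
    values = matrix.X[feature].to_numpy(float)
    y = matrix.y
    n = values.size
    for level in (True, False):
        if (y == level).sum() < 3:
            raise AnalysisError(f"need >= 3 patients per target level, got "
                                f"{int((y == level).sum())} for {level}")
    preds = np.zeros(n, bool)
    cutoffs: list[CutoffResult] = []
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        train_v, train_y = values[mask], y[mask]
        med = np.nanmedian(train_v)
        if np.isnan(med):
            raise AnalysisError(f"feature {feature!r}: no observed training value in fold {i}")
        train_v = np.where(np.isnan(train_v), med, train_v)
        cut = best_cutoff(train_v, train_y)
        x = values[i] if not np.isnan(values[i]) else med
        preds[i] = bool(cut.classify([x])[0])
        cutoffs.append(cut)
    return SingleVariableLOO(
        feature=feature,
        predictions=preds,
        cutoffs=cutoffs,
        metrics=contingency_metrics(preds, y),
    )
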
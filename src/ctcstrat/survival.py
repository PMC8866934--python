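"""Kaplan-Meier estimation, median survival and the two-group log-rank test.

The product-limit estimator steps only at observed event times,

    S(t) = prod_{t_i <= t} (1 - d_i / n_i),

with events preceding censorings at tied times (censored subjects at t_i
still count as at risk).  The log-rank statistic compares observed and
expected event counts across the pooled event times and is referred to a
chi-square distribution with one degree of freedom.  These strata are
typically the leave-one-out *predicted* groups of an upstream model, so
the curves measure out-of-sample stratification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import chi2


@dataclass
class KMCurve:
    """Product-limit survival curve for one group."""

    event_times: np.ndarray     # distinct times with >= 1 event, ascending
    survival: np.ndarray        # S(t) just after each event time
    at_risk: np.ndarray         # n_i at each event time
    n_events: np.ndarray        # d_i at each event time
    censor_times: np.ndarray    # times of censored subjects
    n_subjects: int
    label: str = ""

    def survival_at(self, t: float) -> float:
        """Step-function lookup; S(0) = 1."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])

    @property
    def median(self) -> Optional[float]:
        return km_median(self)

    def as_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.event_times,
                "n_at_risk": self.at_risk,
                "n_events": self.n_events,
                "survival": self.survival,
            }
        )


def km_estimate(times, events, label: str = "") -> KMCurve:
    """Kaplan-Meier curve from right-censored follow-up times."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    if times.size == 0:
        raise ValueError("empty survival input")
    if times.shape != events.shape:
        raise ValueError("times / events length mismatch")
    if (times < 0).any() or np.isnan(times).any():
        raise ValueError("survival times must be non-negative and finite")

    event_times = np.unique(times[events])
    surv, risks, ds = [], [], []
    s = 1.0
    for t in event_times:
        n_i = int((times >= t).sum())
        d_i = int(((times == t) & events).sum())
        s *= 1.0 - d_i / n_i
        surv.append(s)
        risks.append(n_i)
        ds.append(d_i)
    return KMCurve(
        event_times=event_times,
        survival=np.asarray(surv, float),
        at_risk=np.asarray(risks, int),
        n_events=np.asarray(ds, int),
        censor_times=np.sort(times[~events]),
        n_subjects=times.size,
        label=label,
    )


def km_median(curve: KMCurve) -> Optional[float]:
    """Smallest time with S(t) <= 0.5; None when the curve never reaches it."""
    below = np.nonzero(curve.survival <= 0.5)[0]
    if below.size == 0:
        return None
    return float(curve.event_times[below[0]])


@dataclass
class LogRankResult:
    """Two-group log-rank comparison."""

    statistic: float            # chi-square, 1 df
    p_value: float
    observed: np.ndarray        # per-group event counts
    expected: np.ndarray        # per-group expected events under H0


def logrank(times, events, group) -> LogRankResult:
    """Standard two-group log-rank test.

    At every pooled distinct event time the expected events per group
    follow the at-risk proportions; the statistic is
    (sum(O - E))^2 / sum(V) with the hypergeometric variance terms.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    group = np.asarray(group, bool)
    if not (times.shape == events.shape == group.shape):
        raise ValueError("times / events / group length mismatch")
    if group.all() or not group.any():
        raise ValueError("both groups must be non-empty")

    o1 = e1 = var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & group).sum())
        dead = (times == t) & events
        d = int(dead.sum())
        d1 = int((dead & group).sum())
        o1 += d1
        e1 += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    total_events = int(events.sum())
    if var == 0:
        stat = 0.0
    else:
        stat = (o1 - e1) ** 2 / var
    observed = np.array([o1, total_events - o1])
    expected = np.array([e1, total_events - e1])
    return LogRankResult(
        statistic=float(stat),
        p_value=float(chi2.sf(stat, 1)) if var > 0 else 1.0,
        observed=observed,
        expected=expected,
    )
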
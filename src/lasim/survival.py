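"""Kaplan-Meier duration analysis with right-censoring.

Product-limit estimator with the log-transformed Greenwood 95% CI (the
default of R's survival toolchain, used here for comparability) and
Brookmeyer-Crowley inversion for the median CI.  Undefined medians and
bounds (curve never reaching 0.5) are reported as NaN and rendered "-".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from lasim.simulator import DurationRecord

__all__ = ["KMCurve", "km_estimate", "duration_report", "km_export"]

_Z95 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class KMCurve:
    """A fitted product-limit curve with median and 95% CI."""

    times: np.ndarray  # distinct observed times, ascending
    survival: np.ndarray  # S(t) just after each time
    at_risk: np.ndarray  # n at risk just before each time
    n_events: np.ndarray  # events at each time
    n_censored: np.ndarray  # censorings at each time
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    median: float  # NaN when S never reaches <= 0.5
    median_ci: tuple[float, float]  # (lower, upper), NaN when undefined
    n: int
    events: int

    def survival_at(self, t: float) -> float:
        """Step-function value S(t) (right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _median_from_curve(times: np.ndarray, surv: np.ndarray) -> float:
    """Smallest time with S(t) <= 0.5, NaN if never reached."""
    below = surv <= 0.5 + 1e-12
    if not below.any():
        return float("nan")
    return float(times[np.argmax(below)])


def km_estimate(records: list[DurationRecord] | pd.DataFrame) -> KMCurve:
    """Fit the product-limit estimator to right-censored duration records.

    Accepts a list of :class:`DurationRecord` or a DataFrame with columns
    ``time_min`` and ``event``.
    """
    if isinstance(records, pd.DataFrame):
        t = records["time_min"].to_numpy(dtype=float)
        e = records["event"].to_numpy(dtype=bool)
    else:
        if not records:
            raise ValueError("records must be non-empty")
        t = np.array([r.time for r in records], dtype=float)
        e = np.array([r.event for r in records], dtype=bool)
    if t.size == 0:
        raise ValueError("records must be non-empty")
    if np.any(t <= 0):
        raise ValueError("times must be > 0")

    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    utimes = np.unique(t)
    n_total = t.size

    d = np.array([(e & (t == u)).sum() for u in utimes], dtype=int)
    c = np.array([(~e & (t == u)).sum() for u in utimes], dtype=int)
    removed = np.concatenate(([0], np.cumsum(d + c)[:-1]))
    n_risk = n_total - removed

    with np.errstate(divide="ignore", invalid="ignore"):
        frac = 1.0 - d / n_risk
        surv = np.cumprod(frac)
        # Greenwood variance of log S, then log-transform CI: S * exp(+-z*se)
        green = np.cumsum(np.where(n_risk > d, d / (n_risk * (n_risk - d.astype(float))), np.inf))
        se_log = np.sqrt(green)
        lo = surv * np.exp(-_Z95 * se_log)
        hi = np.minimum(surv * np.exp(_Z95 * se_log), 1.0)
    lo = np.where(surv > 0, lo, 0.0)
    hi = np.where(surv > 0, hi, np.nan)

    median = _median_from_curve(utimes, surv)
    # Brookmeyer-Crowley: the median CI is where the pointwise bands cross 0.5
    med_lo = _median_from_curve(utimes, lo)
    med_hi = _median_from_curve(utimes, np.where(np.isnan(hi), 0.0, hi))

    return KMCurve(
        times=utimes,
        survival=surv,
        at_risk=n_risk,
        n_events=d,
        n_censored=c,
        ci_lower=lo,
        ci_upper=hi,
        median=median,
        median_ci=(med_lo, med_hi),
        n=n_total,
        events=int(e.sum()),
    )


def _fmt(x: float) -> str:
    return "-" if np.isnan(x) else f"{x:g}"


def duration_report(cohorts: dict[tuple[str, str], list[DurationRecord]]) -> pd.DataFrame:
    """Summarize durations per (drug/arm, condition) in a median table.

    ``cohorts`` maps ``(arm_label, condition)`` to duration records; empty
    record lists yield an n=0 row with undefined medians.  Columns:
    drug, condition, n, events, median, ci_lower, ci_upper, median_fmt.
    """
    if not cohorts:
        raise ValueError("at least one condition is required")
    rows = []
    for (arm_label, condition), records in cohorts.items():
        if records:
            curve = km_estimate(records)
            median, (lo, hi) = curve.median, curve.median_ci
            n, events = curve.n, curve.events
        else:
            median = lo = hi = float("nan")
            n = events = 0
        rows.append(
            {
                "drug": arm_label,
                "condition": condition,
                "n": n,
                "events": events,
                "median": median,
                "ci_lower": lo,
                "ci_upper": hi,
                "median_fmt": f"{_fmt(median)} [{_fmt(lo)}, {_fmt(hi)}]",
            }
        )
    return pd.DataFrame(rows)


def km_export(curve: KMCurve) -> pd.DataFrame:
    """Step-function export for plotting: one row per distinct time."""
    return pd.DataFrame(
        {
            "time_min": curve.times,
            "survival": curve.survival,
            "n_risk": curve.at_risk,
            "n_events": curve.n_events,
            "n_censored": curve.n_censored,
            "ci_lower": curve.ci_lower,
            "ci_upper": curve.ci_upper,
        }
    )
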
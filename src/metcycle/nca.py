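"""Non-compartmental analysis (NCA) of simulated concentration profiles.

Exposure metrics are computed by the linear trapezoidal rule on the
simulator's dense grid, with linear interpolation at window edges when a
requested integration window does not land on grid points.  The day-1
accumulation ratio of a q8h regimen is AUC(8-16 h) / AUC(0-8 h).  Group
contrasts use Welch's unequal-variance t test on per-subject endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import ProfileResult, TID_INTERVAL

__all__ = [
    "NCAResult",
    "GroupComparison",
    "auc",
    "cmax_tmax",
    "accumulation_ratio",
    "nca_profile",
    "nca_table",
    "compare_groups",
]


@dataclass(frozen=True)
class NCAResult:
    """Model-free exposure endpoints for one subject and analyte."""

    cmax: float                # mmol/L
    tmax: float                # h
    auc_0_8h: float            # mmol*h/L
    auc_8_16h: float
    auc_last: float            # to the last observed time point
    auc_total: float           # to the end of the simulated window (no
                               # terminal-slope extrapolation)
    accumulation_ratio: float  # AUC(8-16)/AUC(0-8); nan if undefined


@dataclass(frozen=True)
class GroupComparison:
    mean_a: float
    mean_b: float
    ratio: float          # mean_a / mean_b
    t_stat: float
    p_value: float
    n_a: int
    n_b: int


def auc(times: Sequence[float], conc: Sequence[float],
        window: tuple[float, float] | None = None) -> float:
    """Linear-trapezoid area under conc(t) over ``window`` (default: the full
    span), interpolating linearly at window edges."""
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.ndim != 1 or t.size < 2 or t.shape != c.shape:
        raise ValueError("need >= 2 matching time/concentration points")
    if (np.diff(t) < 0).any():
        raise ValueError("times must be ascending")
    if window is None:
        return float(np.trapezoid(c, t))
    a, b = float(window[0]), float(window[1])
    if b < a:
        raise ValueError("window must be (lo, hi) with hi >= lo")
    if a < t[0] or b > t[-1]:
        raise ValueError("window extends beyond the observed span")
    inside = (t > a) & (t < b)
    tt = np.concatenate(([a], t[inside], [b]))
    cc = np.concatenate(([np.interp(a, t, c)], c[inside], [np.interp(b, t, c)]))
    return float(np.trapezoid(cc, tt))


def cmax_tmax(times: Sequence[float], conc: Sequence[float]) -> tuple[float, float]:
    """Maximum concentration and the earliest time attaining it."""
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    i = int(np.argmax(c))  # argmax returns the first maximizer
    return float(c[i]), float(t[i])


def accumulation_ratio(times: Sequence[float], conc: Sequence[float],
                       interval: float = TID_INTERVAL) -> float:
    """Day-1 accumulation ratio AUC(interval..2*interval) / AUC(0..interval)."""
    lo = auc(times, conc, (0.0, interval))
    hi = auc(times, conc, (interval, 2 * interval))
    return float(hi / lo) if lo > 0 else float("nan")


def nca_profile(times: Sequence[float], conc: Sequence[float],
                interval: float = TID_INTERVAL) -> NCAResult:
    """All NCA endpoints for one concentration-time profile."""
    t = np.asarray(times, dtype=float)
    cmax, tmax = cmax_tmax(t, conc)
    a_total = auc(t, conc)
    have_day1 = t[-1] >= 2 * interval
    a08 = auc(t, conc, (0.0, interval)) if t[-1] >= interval else float("nan")
    a816 = auc(t, conc, (interval, 2 * interval)) if have_day1 else float("nan")
    ar = a816 / a08 if have_day1 and a08 > 0 else float("nan")
    return NCAResult(cmax=cmax, tmax=tmax, auc_0_8h=a08, auc_8_16h=a816,
                     auc_last=a_total, auc_total=a_total,
                     accumulation_ratio=ar)


def nca_table(profiles: Sequence[ProfileResult], analyte: str = "met",
              use_observed: bool = False) -> pd.DataFrame:
    """One NCA row per subject for the chosen analyte ('met' or 'hcy')."""
    if analyte not in ("met", "hcy"):
        raise ValueError("analyte must be 'met' or 'hcy'")
    rows = []
    for pr in profiles:
        c = getattr(pr, f"c_{analyte}_obs" if use_observed else f"c_{analyte}")
        r = nca_profile(pr.times, c)
        rows.append({"ID": pr.subject_id, "ZDF": pr.group, "ANALYTE": analyte,
                     "CMAX": r.cmax, "TMAX": r.tmax, "AUC_0_8": r.auc_0_8h,
                     "AUC_8_16": r.auc_8_16h, "AUC_LAST": r.auc_last,
                     "AUC_TOTAL": r.auc_total, "AR": r.accumulation_ratio})
    return pd.DataFrame(rows)


def compare_groups(values_a: Sequence[float],
                   values_b: Sequence[float]) -> GroupComparison:
    """Welch two-sample comparison of per-subject endpoints (a vs b)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    if np.array_equal(a, b):
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_ind(a, b, equal_var=False)
    mb = float(np.mean(b))
    return GroupComparison(mean_a=float(np.mean(a)), mean_b=mb,
                           ratio=float(np.mean(a) / mb) if mb != 0 else float("nan"),
                           t_stat=float(t_stat), p_value=float(p),
                           n_a=int(a.size), n_b=int(b.size))
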
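"""Growth-curve analysis: exponential rates, diauxic lag, threshold coupling.

The diauxic lag is operationalized as the time between the instantaneous
growth rate falling below a fraction ``alpha`` of the first-phase maximum and
subsequently rising above the same fraction of the second-phase maximum,
after 5-point smoothing of log2 OD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

__all__ = [
    "GrowthSummary",
    "exponential_growth_rate",
    "diauxic_lag_length",
    "threshold_lag_correlation",
    "summarize_curves",
]

RATE_WINDOW = (2.0**-6, 2.0**-4)  # OD600 bounds of the rate-fit window


@dataclass
class GrowthSummary:
    strain_id: str
    condition: str
    rate: Optional[float]  # doublings / hour
    lag_hours: Optional[float]  # None when no second phase detected
    flags: tuple[str, ...] = ()


def _check_curve(time_h: np.ndarray, od600: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(time_h, float)
    od = np.asarray(od600, float)
    if t.size != od.size:
        raise ValueError("time and OD arrays must have equal length")
    if t.size < 20:
        raise ValueError(f"need >= 20 samples, got {t.size}")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time points must be strictly increasing")
    if np.any(od <= 0):
        raise ValueError("OD600 values must be positive")
    return t, od


def exponential_growth_rate(time_h: np.ndarray, od600: np.ndarray) -> float:
    """Mean log2 OD slope while OD600 is between 2^-6 and 2^-4."""
    t, od = _check_curve(time_h, od600)
    mask = (od >= RATE_WINDOW[0]) & (od <= RATE_WINDOW[1])
    if mask.sum() < 2 or od.max() < RATE_WINDOW[1] or od.min() > RATE_WINDOW[0]:
        raise ValueError(
            "curve does not traverse the OD600 window "
            f"[{RATE_WINDOW[0]:.4g}, {RATE_WINDOW[1]:.4g}]"
        )
    slope = np.polyfit(t[mask], np.log2(od[mask]), 1)[0]
    return float(slope)


def _smooth(x: np.ndarray, window: int = 5) -> np.ndarray:
    return (
        pd.Series(x).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


def diauxic_lag_length(
    time_h: np.ndarray, od600: np.ndarray, alpha: float = 0.3
) -> Optional[float]:
    """Length of the low-growth interval between the two growth phases.

    Returns None (not an error) for single-phase curves where growth never
    re-accelerates after the first-phase slowdown.
    """
    t, od = _check_curve(time_h, od600)
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    log2od = _smooth(np.log2(od))
    rate = np.gradient(log2od, t)

    # detect entry: first drop below alpha x running first-phase max
    peak = rate[0]
    i_enter = None
    first_max = None
    for i in range(1, rate.size):
        peak = max(peak, rate[i])
        if peak > 0 and rate[i] < alpha * peak:
            i_enter = i
            first_max = peak
            break
    if i_enter is None:
        return None

    # detect exit: re-acceleration above alpha x second-phase max, after the
    # rate has actually entered the trough
    tail = rate[i_enter:]
    second_max = float(tail.max())
    if second_max < alpha * first_max:
        return None  # no second growth phase
    below = np.flatnonzero(tail < alpha * second_max)
    if below.size == 0:
        return 0.0  # never dipped below the exit threshold: no lag
    after = np.flatnonzero(tail[below[0]:] > alpha * second_max)
    if after.size == 0:
        return None
    i_exit = i_enter + int(below[0]) + int(after[0])

    # endpoints: half-max crossings, interpolated.  The alpha thresholds sit
    # asymmetrically on the deceleration/re-acceleration ramps that smoothing
    # widens, which would bias the lag by ~(1 - 2*alpha) x ramp width; the
    # 50% crossings are symmetric around the true phase transitions.
    t_enter = _cross_down(t, rate, i_enter, 0.5 * first_max)
    t_exit = _cross_up(t, rate, i_exit, 0.5 * second_max)
    return float(max(t_exit - t_enter, 0.0))


def _cross_down(t: np.ndarray, rate: np.ndarray, i_at: int, thr: float) -> float:
    """Interpolated time of the last downward crossing of thr at/before i_at."""
    i = i_at
    while i > 0 and rate[i] < thr:
        i -= 1
    if i == i_at or rate[i] == rate[i + 1]:
        return float(t[i_at])
    w = (rate[i] - thr) / (rate[i] - rate[i + 1])
    return float(t[i] + w * (t[i + 1] - t[i]))


def _cross_up(t: np.ndarray, rate: np.ndarray, i_at: int, thr: float) -> float:
    """Interpolated time of the first upward crossing of thr at/after i_at."""
    i = i_at
    while i < rate.size - 1 and rate[i] < thr:
        i += 1
    if i == 0 or rate[i] == rate[i - 1]:
        return float(t[i])
    w = (thr - rate[i - 1]) / (rate[i] - rate[i - 1])
    return float(t[i - 1] + w * (t[i] - t[i - 1]))


def threshold_lag_correlation(
    log2_f50: np.ndarray, lag_hours: np.ndarray
) -> dict:
    """Pearson correlation of decision threshold versus diauxic lag.

    Reports r, r^2, the p-value and whether the expected negative sign was
    observed.  Zero variance in either variable gives an undefined, flagged
    result.
    """
    x = np.asarray(log2_f50, float)
    y = np.asarray(lag_hours, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 5:
        raise ValueError(f"need >= 5 paired strains, got {x.size}")
    if np.std(x) == 0 or np.std(y) == 0:
        return {"r": None, "r2": None, "p": None, "negative": None, "flag": "undefined"}
    r, p = pearsonr(x, y)
    return {
        "r": float(r),
        "r2": float(r * r),
        "p": float(p),
        "negative": bool(r < 0),
        "flag": None,
    }


def summarize_curves(curves: pd.DataFrame, alpha: float = 0.3) -> pd.DataFrame:
    """Per-(strain, condition) growth summary over a tidy curve table."""
    rows = []
    for (strain, cond), sub in curves.groupby(["strain_id", "condition"]):
        sub = sub.sort_values("time_h")
        t = sub["time_h"].to_numpy()
        od = sub["od600"].to_numpy()
        flags = []
        try:
            rate = exponential_growth_rate(t, od)
        except ValueError as exc:
            rate = None
            flags.append(f"rate: {exc}")
        try:
            lag = diauxic_lag_length(t, od, alpha)
        except ValueError as exc:
            lag = None
            flags.append(f"lag: {exc}")
        rows.append(
            {
                "strain_id": strain,
                "condition": cond,
                "rate": rate,
                "lag_hours": lag,
                "flags": ";".join(flags),
            }
        )
    return pd.DataFrame(rows)
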
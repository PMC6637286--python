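"""Echocardiographic indices.

TPV/RVET — the ratio of time-to-peak velocity to right-ventricular
ejection time measured on a pulmonary-artery Doppler envelope — is an
inverse surrogate of pulmonary vascular resistance; fractional
shortening is the standard M-mode index of left-ventricular systolic
function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VelocityTrace", "LVMeasures", "compute_tpv_rvet", "fractional_shortening"]


@dataclass
class VelocityTrace:
    times: np.ndarray                 # ms, strictly increasing
    velocity: np.ndarray              # arbitrary units, >= 0 in the window
    window: tuple[float, float] | None = None   # (start, end) ms, optional

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.velocity = np.asarray(self.velocity, float)
        if self.times.ndim != 1 or len(self.times) != len(self.velocity):
            raise ValueError("times and velocity must be equal-length 1D arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class LVMeasures:
    lvidd: float        # mm, end-diastolic internal diameter
    lvids: float        # mm, end-systolic internal diameter

    @property
    def fractional_shortening(self) -> float:
        return fractional_shortening(self.lvidd, self.lvids)


def _interp_crossing(t0, t1, v0, v1, level):
    """Time where the linear segment (t0,v0)-(t1,v1) crosses *level*."""
    if v1 == v0:
        return t0
    return t0 + (level - v0) * (t1 - t0) / (v1 - v0)


def _flank_fit_peak(t: np.ndarray, v: np.ndarray, lo_frac=0.3, hi_frac=0.9) -> float:
    """Peak time as the intersection of lines fitted to the two flanks.

    Samples between ``lo_frac`` and ``hi_frac`` of the peak velocity on
    the rising and falling flanks are fitted by least squares; for a
    piecewise-linear envelope the intersection recovers the true peak
    time exactly, independent of where samples fall relative to it.
    Falls back to the discrete argmax when either flank is too short.
    """
    k = int(np.argmax(v))
    vmax = v[k]
    lo, hi = lo_frac * vmax, hi_frac * vmax
    rise = np.flatnonzero((v[: k + 1] >= lo) & (v[: k + 1] <= hi))
    fall = k + np.flatnonzero((v[k:] >= lo) & (v[k:] <= hi))
    if len(rise) < 2 or len(fall) < 2:
        return float(t[k])
    a1, b1 = np.polyfit(t[rise], v[rise], 1)
    a2, b2 = np.polyfit(t[fall], v[fall], 1)
    if a1 <= 0 or a2 >= 0 or abs(a1 - a2) < 1e-12:
        return float(t[k])
    tp = (b2 - b1) / (a1 - a2)
    # guard against ill-conditioned flanks
    if not (t[rise[0]] <= tp <= t[fall[-1]]):
        return float(t[k])
    return float(tp)


def compute_tpv_rvet(
    trace: VelocityTrace,
    *,
    window_threshold: float = 0.05,
    peak_method: str = "flank",
) -> float:
    """TPV/RVET from a velocity envelope.

    When no ejection window is supplied it is detected as the first and
    last crossings of ``window_threshold`` x peak velocity, located with
    linear interpolation between samples.  TPV is the peak time minus
    the window start (peak located by flank-line intersection, or the
    discrete argmax with ``peak_method="argmax"``); RVET is the window
    duration.  The ratio lies in (0, 1).
    """
    t, v = trace.times, trace.velocity
    vmax = float(v.max())
    if vmax <= 0 or np.ptp(v) == 0:
        raise ValueError("flat trace: no unique velocity peak")
    if int(np.sum(v == vmax)) > 2:
        raise ValueError("no unique velocity peak (flat plateau)")

    if trace.window is not None:
        t_start, t_end = trace.window
    else:
        level = window_threshold * vmax
        above = v >= level
        if not above.any():
            raise ValueError("trace never exceeds the window threshold")
        i0 = int(np.argmax(above))
        i1 = len(v) - 1 - int(np.argmax(above[::-1]))
        t_start = (
            _interp_crossing(t[i0 - 1], t[i0], v[i0 - 1], v[i0], level) if i0 > 0 else t[i0]
        )
        t_end = (
            _interp_crossing(t[i1], t[i1 + 1], v[i1], v[i1 + 1], level)
            if i1 < len(v) - 1
            else t[i1]
        )
    rvet = t_end - t_start
    if rvet <= 0:
        raise ValueError("degenerate ejection window")

    if peak_method == "flank":
        t_peak = _flank_fit_peak(t, v)
    elif peak_method == "argmax":
        t_peak = float(t[np.argmax(v)])
    else:
        raise ValueError(f"unknown peak_method {peak_method!r}")
    tpv = t_peak - t_start
    if not (0 < tpv < rvet):
        raise ValueError("peak lies outside the ejection window")
    return float(tpv / rvet)


def fractional_shortening(lvidd: float, lvids: float) -> float:
    """FS = 100 x (LVIDd - LVIDs) / LVIDd, in percent."""
    if lvidd <= 0:
        raise ValueError("LVIDd must be positive")
    if lvids > lvidd:
        raise ValueError("LVIDs exceeding LVIDd is not a plausible measurement")
    if lvids < 0:
        raise ValueError("LVIDs must be nonnegative")
    return 100.0 * (lvidd - lvids) / lvidd
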
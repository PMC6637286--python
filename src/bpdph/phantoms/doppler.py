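"""Deterministic pulmonary-artery Doppler velocity envelopes.

The envelope is a single-peaked, piecewise-smooth curve that is zero
outside the ejection window [0, RVET] and peaks exactly at TPV.  The
default shape is triangular (linear acceleration and deceleration
flanks), a stylization of the systolic flow envelope whose
threshold-crossing window and flank-fit peak are both recovered exactly
by the downstream estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DopplerProfile", "generate_doppler_trace"]


@dataclass
class DopplerProfile:
    """Timing profile of one ejection: all times in ms."""

    tpv: float
    rvet: float
    peak_velocity: float = 1.0
    sample_rate: float = 1000.0       # Hz
    heart_period: float = 120.0       # ms

    def __post_init__(self) -> None:
        if not (0 < self.tpv < self.rvet < self.heart_period):
            raise ValueError("need 0 < tpv < rvet < heart_period")
        if self.peak_velocity <= 0 or self.sample_rate <= 0:
            raise ValueError("peak_velocity and sample_rate must be positive")

    @classmethod
    def from_config(cls, config: dict, group: str) -> "DopplerProfile":
        p = config["profiles"][group]
        return cls(
            tpv=p["tpv_ms"],
            rvet=p["rvet_ms"],
            peak_velocity=p.get("peak_velocity", 1.0),
            sample_rate=config.get("default_sample_rate_hz", 1000.0),
            heart_period=p.get("heart_period_ms", 120.0),
        )


def generate_doppler_trace(
    profile: DopplerProfile,
    shape: str = "triangle",
) -> tuple[np.ndarray, np.ndarray]:
    """Sample one heart period of the velocity envelope.

    Returns ``(times_ms, velocity)``.  ``shape`` may be ``"triangle"``
    (default) or ``"smooth"`` (a power-skewed arch with continuous
    derivative, still peaking exactly at TPV).

    Raises if the sampling leaves fewer than 10 samples before the
    peak, which would make TPV estimation unreliable.
    """
    dt = 1000.0 / profile.sample_rate           # ms per sample
    if profile.tpv / dt < 10:
        raise ValueError(
            f"sample rate {profile.sample_rate} Hz resolves only "
            f"{profile.tpv / dt:.1f} samples before the peak (need >= 10)"
        )
    t = np.arange(0.0, profile.heart_period, dt)
    v = np.zeros_like(t)
    inside = (t >= 0) & (t <= profile.rvet)
    ti = t[inside]
    if shape == "triangle":
        rise = ti / profile.tpv
        fall = (profile.rvet - ti) / (profile.rvet - profile.tpv)
        v[inside] = profile.peak_velocity * np.minimum(rise, fall)
    elif shape == "smooth":
        # arch u^p (1-u)^q with p/q chosen so the maximum sits at tpv
        u = ti / profile.rvet
        um = profile.tpv / profile.rvet
        p = 2.0 * um
        q = 2.0 * (1 - um)
        arch = u**p * (1 - u) ** q
        v[inside] = profile.peak_velocity * arch / (um**p * (1 - um) ** q)
    else:
        raise ValueError(f"unknown envelope shape {shape!r}")
    return t, v
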
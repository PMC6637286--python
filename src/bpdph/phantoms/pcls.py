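"""Synthetic PCLS artery time-lapses.

Each frame shows a dark lumen ellipse inside brighter tissue, imaged in
phase contrast during stepped agonist perfusion.  The lumen area at
each concentration follows a four-parameter logistic (4PL) law in
percent-of-initial-area units, multiplied by ``1 + N(0, noise_sd)``
frame noise; the exact rasterized lumen pixel count of every frame is
recorded as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..pcls import FourPLParams, four_pl_area_percent

__all__ = ["PCLSGroundTruth", "generate_pcls_timelapse"]


@dataclass
class PCLSGroundTruth:
    concentrations: np.ndarray          # molar, per step (step 0 = no drug)
    step_of_frame: np.ndarray           # step index per frame
    target_area_px: np.ndarray          # noiseless 4PL area per frame
    drawn_area_px: np.ndarray           # after multiplicative noise
    mask_area_px: np.ndarray            # exact rasterized pixel count
    lumen_masks: np.ndarray | None = None  # (T, H, W) boolean, optional
    times_s: np.ndarray | None = None


def _ellipse_mask(shape, center, area_px, axis_ratio=1.3, angle=0.3):
    """Boolean ellipse whose rasterized pixel count matches *area_px*.

    The analytic ellipse of the requested area can rasterize a dozen
    pixels away from it; the scale is bisected until the pixel count is
    as close as the integer grid allows (typically within 1-2 pixels).
    """
    H, W = shape
    b = np.sqrt(area_px / (np.pi * axis_ratio))
    a = axis_ratio * b
    yy, xx = np.mgrid[0:H, 0:W]
    y = yy - center[0]
    x = xx - center[1]
    c, s = np.cos(angle), np.sin(angle)
    u = c * x + s * y
    v = -s * x + c * y
    q = (u / a) ** 2 + (v / b) ** 2    # quadratic form; mask = q <= scale²

    target = int(round(area_px))
    lo, hi = 0.9, 1.1
    best = None
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        n = int(np.count_nonzero(q <= mid * mid))
        if best is None or abs(n - target) < best[0]:
            best = (abs(n - target), mid)
        if n < target:
            lo = mid
        elif n > target:
            hi = mid
        else:
            break
    return q <= best[1] ** 2


def generate_pcls_timelapse(
    params: FourPLParams,
    concentrations,
    frames_per_step: int = 60,
    noise_sd: float = 0.05,
    seed: int = 0,
    *,
    shape: tuple[int, int] = (160, 160),
    initial_area_px: float = 1500.0,
    tissue_level: float = 180.0,
    lumen_level: float = 60.0,
    frame_interval_s: float = 60.0,
    keep_masks: bool = False,
) -> tuple[np.ndarray, PCLSGroundTruth]:
    """Render a stepped concentration time-lapse of one artery.

    A no-drug baseline step is prepended automatically when the first
    listed concentration is nonzero, so the % -of-initial reference is
    always part of the sequence.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    conc = np.asarray(concentrations, float)
    if np.any(np.diff(conc) <= 0):
        raise ValueError("concentrations must be strictly ascending")
    if frames_per_step < 1:
        raise ValueError("frames_per_step must be >= 1")
    if conc[0] > 0:
        conc = np.concatenate([[0.0], conc])

    rng = np.random.default_rng(seed)
    n_steps = len(conc)
    n_frames = n_steps * frames_per_step
    step_of_frame = np.repeat(np.arange(n_steps), frames_per_step)

    area_pct = four_pl_area_percent(conc, params)          # % of initial
    target = initial_area_px * area_pct / 100.0
    target_of_frame = target[step_of_frame]
    noise = rng.normal(0.0, noise_sd, n_frames) if noise_sd > 0 else np.zeros(n_frames)
    drawn = np.clip(target_of_frame * (1.0 + noise), 1.0, None)

    center = (shape[0] / 2, shape[1] / 2)
    frames = np.empty((n_frames,) + tuple(shape), float)
    mask_area = np.empty(n_frames)
    masks = np.empty((n_frames,) + tuple(shape), bool) if keep_masks else None
    for k in range(n_frames):
        m = _ellipse_mask(shape, center, drawn[k])
        frames[k] = np.where(m, lumen_level, tissue_level)
        mask_area[k] = int(m.sum())
        if keep_masks:
            masks[k] = m

    gt = PCLSGroundTruth(
        concentrations=conc,
        step_of_frame=step_of_frame,
        target_area_px=target_of_frame,
        drawn_area_px=drawn,
        mask_area_px=mask_area,
        lumen_masks=masks,
        times_s=np.arange(n_frames) * frame_interval_s,
    )
    return frames, gt
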
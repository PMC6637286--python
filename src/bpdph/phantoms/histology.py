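"""Synthetic Sirius-Red-style cardiac histology images.

Two colour classes on a myocardial background: red collagen patches
occupying an exact, known fraction of the non-vessel tissue area, and
bright vessel lumina recorded in an exclusion mask.  Collagen patches
are spatially correlated (thresholded smooth noise), emulating
interstitial and perivascular fibrosis rather than salt-and-pepper
pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["HistologyGroundTruth", "generate_histology_image"]

_MYOCARDIUM_RGB = np.array([205.0, 175.0, 95.0])
_COLLAGEN_RGB = np.array([175.0, 35.0, 45.0])
_VESSEL_RGB = np.array([235.0, 235.0, 235.0])


@dataclass
class HistologyGroundTruth:
    collagen_mask: np.ndarray     # boolean, collagen pixels (non-vessel)
    vessel_mask: np.ndarray       # boolean, excluded vessel regions
    collagen_fraction: float      # realized fraction of non-vessel tissue


def generate_histology_image(
    collagen_fraction: float,
    vessel_mask_fraction: float = 0.0,
    shape: tuple[int, int] = (256, 256),
    seed: int = 0,
    *,
    color_jitter_sd: float = 3.0,
    correlation_px: float = 6.0,
    paint_vessel_rims_red: bool = False,
) -> tuple[np.ndarray, HistologyGroundTruth]:
    """Render an RGB section with an exact collagen area fraction.

    The red class occupies ``round(collagen_fraction * n_non_vessel)``
    pixels of the non-vessel tissue (exact up to that rounding); vessel
    regions are elliptical lumina whose pixels are recorded in the
    exclusion mask.  ``paint_vessel_rims_red`` adds perivascular red
    INSIDE the vessel mask, which a correct quantification must ignore.
    """
    if not (0 <= collagen_fraction <= 1 and 0 <= vessel_mask_fraction <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    if collagen_fraction + vessel_mask_fraction > 1:
        raise ValueError("collagen and vessel fractions must sum to <= 1")
    rng = np.random.default_rng(seed)
    H, W = shape
    n_px = H * W

    vessel = np.zeros(shape, bool)
    target_vessel = int(round(vessel_mask_fraction * n_px))
    yy, xx = np.mgrid[0:H, 0:W]
    while vessel.sum() < target_vessel:
        cy, cx = rng.uniform(0, H), rng.uniform(0, W)
        a = rng.uniform(6, 14)
        b = a * rng.uniform(0.5, 1.0)
        vessel |= ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0

    non_vessel = ~vessel
    n_tissue = int(non_vessel.sum())
    n_red = int(round(collagen_fraction * n_tissue))

    field = ndimage.gaussian_filter(rng.normal(size=shape), correlation_px)
    field[vessel] = -np.inf
    if n_red > 0:
        flat = field.ravel()
        order = np.argpartition(flat, -n_red)[-n_red:]
        collagen = np.zeros(n_px, bool)
        collagen[order] = True
        collagen = collagen.reshape(shape)
    else:
        collagen = np.zeros(shape, bool)

    img = np.empty((H, W, 3), float)
    img[:] = _MYOCARDIUM_RGB
    img[collagen] = _COLLAGEN_RGB
    img[vessel] = _VESSEL_RGB
    if paint_vessel_rims_red and vessel.any():
        rim = vessel & ~ndimage.binary_erosion(vessel, iterations=2)
        img[rim] = _COLLAGEN_RGB
    if color_jitter_sd > 0:
        img += rng.normal(0.0, color_jitter_sd, img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    realized = collagen.sum() / max(n_tissue, 1)
    gt = HistologyGroundTruth(
        collagen_mask=collagen, vessel_mask=vessel, collagen_fraction=float(realized)
    )
    return img, gt
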
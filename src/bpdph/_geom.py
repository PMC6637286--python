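"""Geometric primitives shared by the phantom generators.

Capsules (cylinders with spherical caps, optionally tapered) stand in for
vessel segments in both the 3D micro-CT phantoms and the 2D angiogram
phantoms.  Rendering uses sub-voxel supersampling so that voxel values
approximate the volume fraction occupied by the tube (partial-volume
behaviour of a real scanner at finite pixel pitch).
"""

from __future__ import annotations

import numpy as np

__all__ = ["render_capsule", "segment_segment_distance", "polyline_length"]


def render_capsule(
    canvas: np.ndarray,
    p0,
    p1,
    r0: float,
    r1: float | None = None,
    amplitude: float = 1.0,
    supersample: int = 3,
) -> None:
    """Draw a (possibly tapered) capsule into *canvas* in place.

    Parameters
    ----------
    canvas:
        Float array of any dimensionality (2D frames or 3D volumes).
    p0, p1:
        End points in index coordinates (same axis order as *canvas*).
    r0, r1:
        Radii in voxels at ``p0`` and ``p1``; ``r1 is None`` means a
        straight (untapered) tube.
    amplitude:
        Value of a fully covered voxel.  Voxel values are
        ``amplitude * fill_fraction`` combined with the existing canvas
        by maximum, so overlapping tubes do not add up.
    supersample:
        Linear subdivision per voxel edge used to estimate the fill
        fraction (``supersample**ndim`` sample points per voxel).  Each
        sample contributes through a linear ramp one subcell wide
        rather than a hard inside/outside test, so the integrated
        opacity of a tube varies smoothly with sub-voxel radius instead
        of quantizing at the subcell lattice.
    """
    if r1 is None:
        r1 = r0
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    nd = canvas.ndim
    if p0.shape != (nd,) or p1.shape != (nd,):
        raise ValueError("end points must match canvas dimensionality")
    if min(r0, r1) <= 0:
        raise ValueError("capsule radii must be positive")
    ss = int(supersample)
    rmax = max(r0, r1)

    lo = np.floor(np.minimum(p0, p1) - rmax - 1).astype(int)
    hi = np.ceil(np.maximum(p0, p1) + rmax + 2).astype(int)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.asarray(canvas.shape))
    if np.any(hi <= lo):
        return

    # Sub-voxel sample coordinates: voxel i covers [i-0.5, i+0.5).
    axes = [
        (np.arange(lo[d] * ss, hi[d] * ss) + 0.5) / ss - 0.5
        for d in range(nd)
    ]
    grid = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([g.ravel() for g in grid], axis=-1)

    ab = p1 - p0
    denom = float(ab @ ab)
    if denom == 0.0:
        t = np.zeros(len(pts))
    else:
        t = np.clip((pts - p0) @ ab / denom, 0.0, 1.0)
    closest = p0 + t[:, None] * ab
    dist = np.linalg.norm(pts - closest, axis=1)
    w = 1.0 / ss
    cover = np.clip((r0 + (r1 - r0) * t + w / 2 - dist) / w, 0.0, 1.0)

    shape_fine = tuple((hi - lo) * ss)
    cover = cover.reshape(shape_fine)
    # Average the ss**nd samples of each voxel.
    for d in range(nd):
        new_shape = cover.shape[:d] + (cover.shape[d] // ss, ss) + cover.shape[d + 1 :]
        cover = cover.reshape(new_shape).mean(axis=d + 1)
    frac = cover

    region = canvas[tuple(slice(lo[d], hi[d]) for d in range(nd))]
    np.maximum(region, amplitude * frac, out=region)


def segment_segment_distance(p0, p1, q0, q1) -> np.ndarray:
    """Minimum distance between segment (p0, p1) and segments (q0, q1).

    ``q0``/``q1`` may be arrays of shape (n, d); a vector of n distances
    is returned.  Uses the clamped closest-point construction; exact for
    all degenerate cases relevant here (short or parallel segments).
    """
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    q0 = np.atleast_2d(np.asarray(q0, float))
    q1 = np.atleast_2d(np.asarray(q1, float))

    d1 = p1 - p0                       # (d,)
    d2 = q1 - q0                       # (n, d)
    r = p0 - q0                        # (n, d)
    a = float(d1 @ d1)
    e = np.einsum("nd,nd->n", d2, d2)
    f = np.einsum("nd,d->n", d2, d1)
    c = np.einsum("nd,d->n", r, d1)
    b = np.einsum("nd,nd->n", r, d2)

    denom = a * e - f * f
    safe_denom = np.where(denom > 1e-12, denom, 1.0)
    s = np.where(denom > 1e-12, np.clip((b * f - c * e) / safe_denom, 0.0, 1.0), 0.0)

    safe_e = np.where(e > 1e-12, e, 1.0)
    t_raw = np.where(e > 1e-12, (b + s * f) / safe_e, 0.0)
    t = np.clip(t_raw, 0.0, 1.0)
    # Where t had to be clamped (or the joint solve was degenerate),
    # re-optimise s for the fixed t.
    clamped = (t_raw < 0.0) | (t_raw > 1.0) | (denom <= 1e-12)
    if a > 1e-12:
        s = np.where(clamped, np.clip((t * f - c) / a, 0.0, 1.0), s)

    cp_p = p0 + np.outer(s, d1)
    cp_q = q0 + t[:, None] * d2
    return np.linalg.norm(cp_p - cp_q, axis=1)


def polyline_length(points: np.ndarray) -> float:
    """Arc length of a polyline given as an (n, d) coordinate array."""
    pts = np.asarray(points, float)
    if len(pts) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
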
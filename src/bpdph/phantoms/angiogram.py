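"""Synthetic cine-angiogram sequences with per-generation ground truth.

Emulates digital-subtraction pulmonary angiography: a static chest
background (low-frequency smoothed noise plus high-contrast rib-like
bars), followed by iodine contrast arriving in a branching arterial
tree whose opacity ramps up over a few frames.  Because the background
is strictly static, subtracting the last pre-injection frame isolates
the vessel tree exactly.

Trees are laid out as ``n1`` disjoint fans growing rightwards from the
left image edge; every parent spawns 0, 2 or 3 children at its distal
tip, so branch points are unambiguous in the projected skeleton and the
per-generation segment counts are exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .._geom import render_capsule, segment_segment_distance

__all__ = ["AngiogramGroundTruth", "layout_branching_tree", "generate_angiogram_sequence"]

_GEN_LENGTH_PX = {1: 90.0, 2: 52.0, 3: 30.0}
_GEN_RADIUS_PX = {1: 4.0, 2: 2.5, 3: 1.5}


@dataclass
class TreeSegment2D:
    p0: np.ndarray
    p1: np.ndarray
    radius_px: float
    generation: int
    tree_id: int
    wedge: tuple[float, float] | None = None   # owned angular sector (rad)


@dataclass
class AngiogramGroundTruth:
    segments: list[TreeSegment2D]
    counts: dict[int, int]                 # vessels per generation
    vessel_opacity: np.ndarray             # fully-arrived contrast image
    arrival_index: int                     # first frame with contrast
    contrast_ramp: np.ndarray              # per-frame opacity scaling in [0, 1]
    salt_pixels: list[tuple[int, int, int]] = field(default_factory=list)  # (frame, row, col)


def _children_per_parent(n_children: int, n_parents: int) -> list[int]:
    """Split *n_children* over *n_parents* using only 0/2/3 per parent."""
    if n_children == 0:
        return [0] * n_parents
    for threes in range(n_children // 3, -1, -1):
        rem = n_children - 3 * threes
        if rem % 2 == 0 and rem // 2 + threes <= n_parents:
            twos = rem // 2
            return [3] * threes + [2] * twos + [0] * (n_parents - threes - twos)
    raise ValueError(
        f"cannot express {n_children} children over {n_parents} parents "
        "with 0/2/3 children each"
    )


def layout_branching_tree(
    counts: tuple[int, int, int],
    shape: tuple[int, int] = (960, 640),
    seed: int = 0,
    *,
    clearance_px: float = 3.0,
    max_tries: int = 60,
) -> list[TreeSegment2D]:
    """Place a forest realizing exactly *counts* segments per generation.

    ``counts[0]`` root vessels enter from the left edge, each confined
    to its own horizontal band so trees cannot collide; within a tree,
    child directions are re-drawn until no two non-adjacent segments
    come closer than ``clearance_px`` beyond their radii.
    """
    n1, n2, n3 = (int(c) for c in counts)
    if n1 < 1:
        raise ValueError("at least one first-generation vessel is required")
    rng = np.random.default_rng(seed)
    H, W = shape
    band = H / n1

    plan2 = _children_per_parent(n2, n1)
    rng.shuffle(plan2)

    segments: list[TreeSegment2D] = []

    def fits(p0, p1, r, band_lo, band_hi, exclude_pts) -> bool:
        m = r + 2
        if not (band_lo + m <= p0[0] <= band_hi - m and band_lo + m <= p1[0] <= band_hi - m):
            return False
        if not (0 + m <= p1[1] <= W - m):
            return False
        if segments:
            q0 = np.asarray([s.p0 for s in segments])
            q1 = np.asarray([s.p1 for s in segments])
            d = segment_segment_distance(p0, p1, q0, q1)
            req = r + np.asarray([s.radius_px for s in segments]) + clearance_px
            shares = np.array(
                [
                    any(np.allclose(pt, s.p0) or np.allclose(pt, s.p1) for pt in exclude_pts)
                    for s in segments
                ]
            )
            if np.any((d < req) & ~shares):
                return False
        return True

    for t in range(n1):
        band_lo, band_hi = t * band, (t + 1) * band
        y0 = (band_lo + band_hi) / 2 + rng.uniform(-4, 4)
        p0 = np.array([y0, 8.0])
        angle = np.deg2rad(rng.uniform(-6, 6))
        L1 = _GEN_LENGTH_PX[1] * rng.uniform(0.9, 1.1)
        p1 = p0 + L1 * np.array([np.sin(angle), np.cos(angle)])
        root = TreeSegment2D(p0, p1, _GEN_RADIUS_PX[1], 1, t)
        segments.append(root)

        if plan2[t]:
            _spawn_children(root, plan2[t], 2, rng, fits, (band_lo, band_hi), segments)

    gen2_all = [s for s in segments if s.generation == 2]
    if n2 != len(gen2_all):  # pragma: no cover - layout accounting guard
        raise RuntimeError("generation-2 layout accounting failed")
    plan3 = _children_per_parent(n3, len(gen2_all)) if gen2_all or n3 else []
    rng.shuffle(plan3)
    for parent, k in zip(gen2_all, plan3):
        if not k:
            continue
        band_lo = parent.tree_id * band
        _spawn_children(parent, k, 3, rng, fits, (band_lo, band_lo + band), segments)

    realized = {g: sum(1 for s in segments if s.generation == g) for g in (1, 2, 3)}
    if realized != {1: n1, 2: n2, 3: n3}:  # pragma: no cover
        raise RuntimeError(f"layout produced {realized}, wanted {(n1, n2, n3)}")
    return segments


_BRANCH_ANGLE_DEG = {2: 33.0, 3: 28.0}


def _spawn_children(parent, k, generation, rng, fits, band, segments, max_tries=80):
    """Attach *k* children at the distal tip of *parent*.

    Children leave at wide, fixed nominal angles (±33° in generation 2,
    ±28° in generation 3, plus a straight continuation when k = 3) so
    that sibling vessels separate within a few pixels of the branch
    point — narrower angles would fuse at the imaging resolution.
    Jitter shrinks over retries; residual collisions and band overruns
    are handled by rejection.
    """
    band_lo, band_hi = band
    origin = parent.p1
    pdir = (parent.p1 - parent.p0) / np.linalg.norm(parent.p1 - parent.p0)
    base = np.arctan2(pdir[0], pdir[1])
    spread = np.deg2rad(_BRANCH_ANGLE_DEG[generation])
    r = _GEN_RADIUS_PX[generation]
    L = _GEN_LENGTH_PX[generation]
    offsets = [-1.0, 1.0] if k == 2 else [-1.0, 0.0, 1.0]
    made: list[TreeSegment2D] = []
    for off in offsets:
        for attempt in range(max_tries):
            damp = max(0.15, 1.0 - attempt / 25.0)
            ang = base + off * spread * rng.uniform(0.9, 1.15) + damp * np.deg2rad(rng.uniform(-5, 5))
            if attempt > max_tries // 3:
                # steer toward the band centre when room runs out
                pull = np.clip((0.5 * (band_lo + band_hi) - origin[0]) / (band_hi - band_lo), -1, 1)
                ang += np.deg2rad(15.0 * pull)
            length = L * rng.uniform(0.85, 1.1) * (0.8 if attempt > max_tries // 2 else 1.0)
            p1 = origin + length * np.array([np.sin(ang), np.cos(ang)])
            seg = TreeSegment2D(origin.copy(), p1, r, generation, parent.tree_id)
            exclude = [origin] + [c.p1 for c in made]
            if fits(origin, p1, r, band_lo, band_hi, exclude):
                segments.append(seg)
                made.append(seg)
                break
        else:
            raise RuntimeError(
                f"could not place a generation-{generation} child without overlap; "
                "enlarge the frame or reduce counts"
            )
    return made


def generate_angiogram_sequence(
    tree: tuple[int, int, int] | list[TreeSegment2D],
    n_frames: int = 40,
    pre_injection_frames: int = 5,
    pixel_size: float = 9.9,
    seed: int = 0,
    *,
    shape: tuple[int, int] = (960, 640),
    background: bool = True,
    base_level: float = 100.0,
    vessel_amplitude: float = 120.0,
    ramp_time_constant: float = 3.0,
    salt_noise_rate: float = 0.0,
    frame_interval_ms: float = 30.0,
) -> tuple[np.ndarray, AngiogramGroundTruth]:
    """Render a contrast-arrival frame sequence.

    *tree* is either a ``(g1, g2, g3)`` count tuple (laid out with the
    given seed) or a pre-built segment list.  Frames ``0 ..
    pre_injection_frames - 1`` contain only the static background;
    later frames add the vessel opacity scaled by a saturating arrival
    curve ``1 - exp(-(k + 1) / ramp_time_constant)``.  Optional salt
    noise (value 255, rate per pixel per post-arrival frame) is
    recorded pixel by pixel in the ground truth.
    """
    if isinstance(tree, (tuple, list)) and len(tree) and not isinstance(tree[0], TreeSegment2D):
        counts3 = tuple(int(c) for c in tree)
        if len(counts3) != 3 or sum(counts3) == 0 or counts3[0] == 0:
            raise ValueError("tree counts must provide at least one generation-1 vessel")
        segments = layout_branching_tree(counts3, shape=shape, seed=seed)
    elif isinstance(tree, list) and tree:
        segments = tree
    else:
        raise ValueError("zero generations requested")
    if not (n_frames > pre_injection_frames >= 1):
        raise ValueError("need n_frames > pre_injection_frames >= 1")
    if salt_noise_rate < 0:
        raise ValueError("salt_noise_rate must be nonnegative")

    rng = np.random.default_rng(seed + 1)

    opacity = np.zeros(shape, float)
    for s in segments:
        render_capsule(opacity, s.p0, s.p1, s.radius_px, amplitude=vessel_amplitude)

    if background:
        texture = ndimage.gaussian_filter(rng.normal(size=shape), 14.0)
        texture *= 25.0 / max(texture.std(), 1e-9)
        rows = np.arange(shape[0])[:, None]
        ribs = 30.0 * (np.sin(2 * np.pi * rows / 72.0) > 0.55).astype(float)
        bg = base_level + texture + ribs * np.ones((1, shape[1]))
    else:
        bg = np.zeros(shape)

    ramp = np.zeros(n_frames)
    post = np.arange(n_frames - pre_injection_frames)
    ramp[pre_injection_frames:] = 1.0 - np.exp(-(post + 1) / ramp_time_constant)

    frames = np.empty((n_frames,) + tuple(shape), float)
    salt_pixels: list[tuple[int, int, int]] = []
    for k in range(n_frames):
        f = bg + ramp[k] * opacity
        if salt_noise_rate > 0 and k >= pre_injection_frames:
            n_salt = rng.binomial(shape[0] * shape[1], salt_noise_rate)
            rr = rng.integers(0, shape[0], n_salt)
            cc = rng.integers(0, shape[1], n_salt)
            f[rr, cc] = 255.0
            salt_pixels += [(k, int(r), int(c)) for r, c in zip(rr, cc)]
        frames[k] = f

    counts = {g: sum(1 for s in segments if s.generation == g) for g in (1, 2, 3)}
    gt = AngiogramGroundTruth(
        segments=segments,
        counts=counts,
        vessel_opacity=opacity,
        arrival_index=pre_injection_frames,
        contrast_ramp=ramp,
        salt_pixels=salt_pixels,
    )
    return frames, gt
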
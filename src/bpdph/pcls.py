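"""PCLS intrapulmonary-artery reactivity analysis.

Lumen areas are measured per frame by grayscale thresholding and pixel
summation; per-concentration responses are expressed as % reduction of
the initial artery area; and the concentration-response relation is
fitted with a four-parameter logistic (4PL) on log10 concentration,
yielding pEC50 and the maximal reduction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

__all__ = [
    "FourPLParams",
    "LumenTrace",
    "ConcentrationResponse",
    "FourPLFit",
    "four_pl_area_percent",
    "four_pl_response",
    "segment_lumen",
    "build_concentration_response",
    "fit_four_pl",
]


@dataclass
class FourPLParams:
    """Four-parameter logistic on log10 molar concentration.

    In area units (phantom profiles) ``bottom`` is the % initial area
    with no drug (100) and ``top`` the % area at saturation, so
    ``bottom >= top`` for a constrictor; in response units (fits)
    bottom ~ 0 and top is the maximal % reduction.  ``hill > 0``.
    """

    bottom: float
    top: float
    logec50: float
    hill: float = 1.0

    def __post_init__(self) -> None:
        if self.hill <= 0:
            raise ValueError("hill slope must be positive")

    @property
    def pec50(self) -> float:
        return -self.logec50

    @classmethod
    def from_config(cls, config: dict, agonist: str) -> "FourPLParams":
        p = config["profiles"][agonist]
        return cls(
            bottom=p["bottom_pct"], top=p["top_pct"], logec50=p["log_ec50"], hill=p["hill"]
        )


def four_pl_area_percent(conc_molar, params: FourPLParams) -> np.ndarray:
    """Evaluate the 4PL in %-of-initial-area units; exact at c = 0."""
    c = np.asarray(conc_molar, float)
    out = np.full(c.shape, params.bottom)
    pos = c > 0
    occ = 1.0 / (1.0 + 10.0 ** ((params.logec50 - np.log10(c[pos])) * params.hill))
    out[pos] = params.bottom + (params.top - params.bottom) * occ
    return out


def four_pl_response(logc, bottom, top, logec50, hill):
    """4PL in response (% reduction) units, used as the fit model."""
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((logec50 - logc) * hill))


@dataclass
class LumenTrace:
    times: np.ndarray            # s
    areas: np.ndarray            # pixel counts
    pixel_size: float = 1.0      # um
    initial_area: float | None = None  # baseline mean, pixels

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.areas = np.asarray(self.areas, float)
        if np.any(self.areas < 0):
            raise ValueError("areas must be nonnegative")
        if self.initial_area is not None and self.initial_area <= 0:
            raise ValueError("initial_area must be positive")


@dataclass
class FourPLFit:
    params: FourPLParams
    pec50: float
    max_reduction: float
    se: dict[str, float]
    degenerate: bool = False
    hill_fixed: bool = False   # plateau was ill-determined; refit with h = 1


@dataclass
class ConcentrationResponse:
    concentrations: np.ndarray   # molar, ascending
    response: np.ndarray         # % reduction of initial area
    n: int = 1
    fitted: FourPLFit | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, float)
        self.response = np.asarray(self.response, float)
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly ascending")
        if np.any(self.response > 100.0 + 1e-9):
            raise ValueError("a reduction cannot exceed 100% of the initial area")


def segment_lumen(
    image: np.ndarray,
    threshold: float | str = "auto",
    seed_point: tuple[int, int] | None = None,
) -> int:
    """Lumen area in pixels: dark pixels below threshold, restricted to
    the connected component holding the seed (default: the largest dark
    component).  Returns 0 with a warning when nothing lies below the
    threshold."""
    img = np.asarray(image, float)
    if img.size == 0:
        raise ValueError("image is empty")
    if threshold == "auto":
        if img.max() == img.min():
            logger.warning("segment_lumen: uniform image, zero lumen area")
            return 0
        threshold = threshold_otsu(img)
    dark = img < float(threshold)
    if not dark.any():
        logger.warning("segment_lumen: no pixels below threshold, zero lumen area")
        return 0
    labels, n = ndimage.label(dark)
    if seed_point is not None:
        lab = labels[tuple(int(v) for v in seed_point)]
        if lab == 0:
            logger.warning("segment_lumen: seed not in a dark component, zero area")
            return 0
    else:
        sizes = ndimage.sum_labels(dark, labels, index=np.arange(1, n + 1))
        lab = int(np.argmax(sizes)) + 1
    return int(np.sum(labels == lab))


def build_concentration_response(
    trace: LumenTrace,
    step_times: np.ndarray,
    concentrations: np.ndarray,
    *,
    plateau_fraction: float = 0.2,
) -> ConcentrationResponse:
    """Reduce an area trace over stepped perfusion to response points.

    ``step_times[i]`` is the onset (s) of ``concentrations[i]``; each
    step's plateau is the mean area over the final ``plateau_fraction``
    of its window.  The initial area is the trace's ``initial_area`` if
    set, else the mean over any frames before the first step (or the
    plateau of a leading zero-concentration step).
    ``response = 100 * (1 - plateau / initial)``.
    """
    step_times = np.asarray(step_times, float)
    conc = np.asarray(concentrations, float)
    if len(step_times) != len(conc):
        raise ValueError("step_times and concentrations must align")
    if np.any(np.diff(step_times) <= 0):
        raise ValueError("step windows must be ordered and non-overlapping")
    if not 0 < plateau_fraction <= 1:
        raise ValueError("plateau_fraction must lie in (0, 1]")

    t = trace.times
    bounds = np.concatenate([step_times, [t[-1] + 1e-9]])
    plateaus = np.empty(len(conc))
    for i in range(len(conc)):
        w = (t >= bounds[i]) & (t < bounds[i + 1])
        if not w.any():
            raise ValueError(f"step {i} window contains no frames")
        idx = np.flatnonzero(w)
        k = max(1, int(round(plateau_fraction * len(idx))))
        plateaus[i] = trace.areas[idx[-k:]].mean()

    if trace.initial_area is not None:
        initial = trace.initial_area
    else:
        pre = t < step_times[0]
        if pre.any():
            initial = trace.areas[pre].mean()
        elif conc[0] == 0:
            initial = plateaus[0]
        else:
            raise ValueError("no baseline frames and no zero-concentration step")
    if initial <= 0:
        raise ValueError("initial area must be positive")

    response = 100.0 * (1.0 - plateaus / initial)
    keep = conc > 0
    return ConcentrationResponse(concentrations=conc[keep], response=response[keep])


def fit_four_pl(
    cr: ConcentrationResponse,
    *,
    max_top: float = 100.0,
    stabilize: bool = True,
) -> FourPLFit:
    """Least-squares 4PL fit of % reduction against log10 concentration.

    The bottom is allowed a small band around zero (no reduction at no
    drug), the top is bounded by ``max_top`` (an artery cannot lose
    more than its whole lumen), and the Hill slope is constrained
    positive for a constrictor.  Degenerate (flat) data are flagged
    rather than fitted.

    With few concentrations, noise can flatten the slope and let the
    plateau run away (a shallow-hill/high-top trade-off that leaves the
    maximum unidentified).  When ``stabilize`` is on and the free fit
    returns an ill-determined plateau (SE of the top > 8 points, or a
    Hill slope at/below 0.5), the curve is refit with the Hill slope
    fixed at 1 — the standard single-receptor reduction — and flagged
    via ``hill_fixed``.
    """
    if len(cr.concentrations) < 4:
        raise ValueError("need at least 4 distinct concentrations")
    logc = np.log10(cr.concentrations)
    y = cr.response

    if np.ptp(y) < 1e-9:
        params = FourPLParams(bottom=float(y[0]), top=float(y[0]) if y[0] > 0 else 1e-6, logec50=float(logc.mean()), hill=1.0)
        return FourPLFit(params=params, pec50=params.pec50, max_reduction=float(y[0]), se={}, degenerate=True)

    def solve(fixed_hill: float | None):
        if fixed_hill is None:
            p0 = [0.0, max(y.max(), 1.0), float(logc[np.argmin(np.abs(y - y.max() / 2))]), 1.0]
            bounds = ([-10.0, 0.0, logc.min() - 2.0, 0.2], [10.0, max_top, logc.max() + 2.0, 5.0])
            model = four_pl_response
        else:
            p0 = [0.0, max(y.max(), 1.0), float(logc[np.argmin(np.abs(y - y.max() / 2))])]
            bounds = ([-10.0, 0.0, logc.min() - 2.0], [10.0, max_top, logc.max() + 2.0])

            def model(lc, bottom, top, logec50):
                return four_pl_response(lc, bottom, top, logec50, fixed_hill)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(model, logc, y, p0=p0, bounds=bounds, maxfev=20000)
        perr = (
            np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(len(popt), np.nan)
        )
        return popt, perr

    try:
        popt, perr = solve(None)
    except RuntimeError as err:
        raise RuntimeError(f"4PL fit failed to converge: {err}") from err

    hill_fixed = False
    if stabilize and (not np.isfinite(perr[1]) or perr[1] > 8.0 or popt[3] <= 0.5):
        try:
            popt3, perr3 = solve(1.0)
            popt = np.array([popt3[0], popt3[1], popt3[2], 1.0])
            perr = np.array([perr3[0], perr3[1], perr3[2], 0.0])
            hill_fixed = True
        except RuntimeError:
            pass  # keep the free fit

    params = FourPLParams(bottom=popt[0], top=popt[1], logec50=popt[2], hill=popt[3])
    se = dict(zip(("bottom", "top", "logec50", "hill"), (float(v) for v in perr)))
    return FourPLFit(
        params=params,
        pec50=float(-popt[2]),
        max_reduction=float(popt[1]),
        se=se,
        hill_fixed=hill_fixed,
    )
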
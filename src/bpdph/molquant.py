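"""Molecular and histological quantification with group statistics.

Covers the downstream read-outs of the study: ΔΔCT relative gene
expression normalized to the most stable housekeeping gene,
total-protein normalization of ELISA analytes, the positive-pixel
immunostain score (strong-staining intensity per tissue area), the
Sirius-Red collagen area fraction with vessel exclusion, and the group
comparison protocol (normality and equal-variance checks, Student's
t-test or one-way ANOVA with Tukey's HSD).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage.color import rgb2hsv
from statsmodels.stats.multicomp import pairwise_tukeyhsd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionTable",
    "StainScore",
    "DdctResult",
    "GroupComparison",
    "select_housekeeping",
    "ddct_fold_change",
    "normalize_to_total_protein",
    "positive_pixel_score",
    "collagen_fraction",
    "group_compare",
]


# --------------------------------------------------------------------------
# qPCR


@dataclass
class ExpressionTable:
    """Samples x genes CT values with group labels."""

    ct: pd.DataFrame              # index = sample, columns = genes
    groups: pd.Series             # sample -> group label
    housekeeping: str = "Actb"

    def __post_init__(self) -> None:
        if not np.isfinite(self.ct.to_numpy(float)).all():
            raise ValueError("CT values must be finite")
        if self.housekeeping not in self.ct.columns:
            raise ValueError(f"housekeeping gene {self.housekeeping!r} absent from table")
        if not self.ct.index.equals(self.groups.index):
            raise ValueError("groups must be indexed by the same samples")

    @property
    def genes(self) -> list[str]:
        return list(self.ct.columns)


def select_housekeeping(table: ExpressionTable, candidates: list[str]) -> str:
    """The most stably expressed candidate: minimal CT standard deviation
    across all samples; ties broken alphabetically (logged)."""
    present = [g for g in candidates if g in table.ct.columns]
    if not present:
        raise ValueError("no housekeeping candidate present in the table")
    sds = {g: float(table.ct[g].std(ddof=1)) for g in present}
    best = min(sorted(sds), key=lambda g: sds[g])
    ties = [g for g in present if np.isclose(sds[g], sds[best]) and g != best]
    if ties:
        logger.info("housekeeping tie between %s; choosing %s alphabetically", [best] + ties, best)
    return best


@dataclass
class DdctResult:
    fold_change: float                      # 2^-ΔΔCT, comparison vs reference
    ddct: float
    per_sample_relative: pd.Series          # 2^-(ΔCT - mean ΔCT_ref), all samples
    sem: dict[str, float]                   # per group SEM of relative values
    display_scaled: pd.Series               # relative to the lowest-expressed level


def ddct_fold_change(
    table: ExpressionTable,
    target: str,
    reference_group: str,
    comparison_group: str,
) -> DdctResult:
    """Relative expression by the ΔΔCT method.

    ΔCT = CT_target - CT_housekeeping per sample; ΔΔCT is the group-mean
    difference (comparison - reference); fold change = 2^-ΔΔCT.
    Per-sample relative values 2^-(ΔCT - mean ΔCT_ref) are returned for
    SEM reporting, together with a display scaling of the group means
    relative to the lowest-expressed level (an alternative presentation
    convention for multi-gene panels).
    """
    if target not in table.ct.columns:
        raise ValueError(f"target gene {target!r} absent from table")
    for g in (reference_group, comparison_group):
        if not (table.groups == g).any():
            raise ValueError(f"group {g!r} is empty")

    dct = table.ct[target] - table.ct[table.housekeeping]
    ref_mean = dct[table.groups == reference_group].mean()
    comp_mean = dct[table.groups == comparison_group].mean()
    ddct = float(comp_mean - ref_mean)
    fold = float(2.0 ** (-ddct))

    rel = 2.0 ** (-(dct - ref_mean))
    sem = {
        g: float(rel[table.groups == g].sem())
        for g in table.groups.unique()
    }
    group_means = rel.groupby(table.groups).mean()
    display = group_means / group_means.min()
    return DdctResult(
        fold_change=fold, ddct=ddct, per_sample_relative=rel, sem=sem, display_scaled=display
    )


# --------------------------------------------------------------------------
# protein


def normalize_to_total_protein(analyte, total_protein, groups=None) -> pd.DataFrame:
    """Per-sample analyte / total protein, with group mean ± SEM if labels
    are provided.  Analyte in pg/ml, protein in mg/ml (units preserved
    as a ratio)."""
    analyte = np.asarray(analyte, float)
    protein = np.asarray(total_protein, float)
    if analyte.shape != protein.shape:
        raise ValueError("analyte and total_protein must align")
    if np.any(protein <= 0):
        raise ValueError("total protein concentrations must be positive")
    ratio = analyte / protein
    df = pd.DataFrame({"normalized": ratio})
    if groups is not None:
        df["group"] = np.asarray(groups)
    return df


# --------------------------------------------------------------------------
# histology


@dataclass
class StainScore:
    strong_positive_intensity_sum: float
    tissue_area_um2: float
    n_strong: int = 0

    def __post_init__(self) -> None:
        if self.tissue_area_um2 <= 0:
            raise ValueError("tissue area must be positive")

    @property
    def score(self) -> float:
        return self.strong_positive_intensity_sum / self.tissue_area_um2


def positive_pixel_score(
    image: np.ndarray,
    tissue_mask: np.ndarray,
    *,
    pixel_size_um: float = 1.0,
    hue_window: tuple[float, float] = (0.02, 0.12),
    min_saturation: float = 0.15,
    strong_value_max: float = 0.55,
) -> StainScore:
    """Positive-pixel immunostain score within a tissue mask.

    Pixels are classified by HSV hue window (default: the brown of a
    peroxidase/DAB product) and saturation; positive pixels whose value
    (brightness) falls below ``strong_value_max`` count as strong.  The
    score is the summed staining intensity of strong pixels — intensity
    taken as ``255 - mean RGB`` (darker stain = more chromogen) —
    divided by the masked tissue area in um².
    """
    tissue_mask = np.asarray(tissue_mask, bool)
    if not tissue_mask.any():
        raise ValueError("tissue mask is empty")
    img = np.asarray(image, float)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError("expected an RGB image")
    hsv = rgb2hsv(img / 255.0)
    hue, sat, val = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    lo, hi = hue_window
    in_hue = (hue >= lo) & (hue <= hi) if lo <= hi else (hue >= lo) | (hue <= hi)
    positive = in_hue & (sat >= min_saturation) & tissue_mask
    strong = positive & (val <= strong_value_max)
    intensity = 255.0 - img.mean(axis=-1)
    area_um2 = float(tissue_mask.sum()) * pixel_size_um**2
    return StainScore(
        strong_positive_intensity_sum=float(intensity[strong].sum()),
        tissue_area_um2=area_um2,
        n_strong=int(strong.sum()),
    )


def collagen_fraction(
    image: np.ndarray,
    vessel_mask: np.ndarray | None = None,
    *,
    red_hue_window: tuple[float, float] = (0.92, 0.08),
    min_saturation: float = 0.3,
) -> float:
    """Sirius-Red collagen content as % of non-vessel tissue area.

    Red-class pixels (hue in a wrap-around window about 0, saturated)
    are counted over all non-vessel pixels; vessel regions are excluded
    from numerator and denominator alike.
    """
    img = np.asarray(image, float)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError("expected an RGB image")
    if vessel_mask is None:
        vessel_mask = np.zeros(img.shape[:2], bool)
    vessel_mask = np.asarray(vessel_mask, bool)
    if vessel_mask.shape != img.shape[:2]:
        raise ValueError("vessel mask must match the image shape")
    tissue = ~vessel_mask
    n_tissue = int(tissue.sum())
    if n_tissue == 0:
        raise ValueError("no tissue pixels outside the vessel mask")
    hsv = rgb2hsv(img / 255.0)
    hue, sat = hsv[..., 0], hsv[..., 1]
    lo, hi = red_hue_window
    in_hue = (hue >= lo) | (hue <= hi) if lo > hi else (hue >= lo) & (hue <= hi)
    red = in_hue & (sat >= min_saturation) & tissue
    return 100.0 * float(red.sum()) / n_tissue


# --------------------------------------------------------------------------
# statistics


@dataclass
class GroupComparison:
    design: str                            # "two_group" | "multi_group"
    statistic: float                       # t or F
    p_value: float
    normality_p: dict[str, float]
    equal_variance_p: float
    assumptions_ok: bool
    means: dict[str, float]
    sems: dict[str, float]
    pairwise: pd.DataFrame | None = None   # Tukey table for multi_group
    significant: bool = False


def group_compare(values: dict[str, np.ndarray], design: str | None = None, *, alpha: float = 0.05) -> GroupComparison:
    """Compare group means per the study's statistical protocol.

    Normality (Shapiro-Wilk per group) and equal variance
    (Brown-Forsythe) are checked at the 0.05 rejection level and
    reported; two groups are compared by two-sided Student's t-test,
    three or more by one-way ANOVA with Tukey's HSD pairwise
    comparisons.  Significance is declared at P < 0.05.
    """
    groups = {g: np.asarray(v, float) for g, v in values.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    if design is None:
        design = "two_group" if len(groups) == 2 else "multi_group"
    if design == "two_group" and len(groups) != 2:
        raise ValueError("two_group design requires exactly two groups")

    normality = {}
    for g, v in groups.items():
        if np.ptp(v) == 0:
            normality[g] = np.nan   # Shapiro undefined on constant data
        else:
            normality[g] = float(stats.shapiro(v).pvalue)
    arrays = list(groups.values())
    if all(np.ptp(v) == 0 for v in arrays):
        levene_p = np.nan
    else:
        levene_p = float(stats.levene(*arrays, center="median").pvalue)
    assumptions_ok = all(
        (np.isnan(p) or p >= alpha) for p in normality.values()
    ) and (np.isnan(levene_p) or levene_p >= alpha)

    means = {g: float(v.mean()) for g, v in groups.items()}
    sems = {g: float(stats.sem(v)) for g, v in groups.items()}

    pairwise = None
    if design == "two_group":
        a, b = arrays
        res = stats.ttest_ind(a, b)
        statistic, p = float(res.statistic), float(res.pvalue)
        if np.isnan(statistic) and np.allclose(a, b):
            statistic, p = 0.0, 1.0
    else:
        res = stats.f_oneway(*arrays)
        statistic, p = float(res.statistic), float(res.pvalue)
        flat = np.concatenate(arrays)
        labels = np.concatenate([[g] * len(v) for g, v in groups.items()])
        tk = pairwise_tukeyhsd(flat, labels, alpha=alpha)
        pairwise = pd.DataFrame(
            tk.summary().data[1:], columns=tk.summary().data[0]
        )
    return GroupComparison(
        design=design,
        statistic=statistic,
        p_value=p,
        normality_p=normality,
        equal_variance_p=levene_p,
        assumptions_ok=assumptions_ok,
        means=means,
        sems=sems,
        pairwise=pairwise,
        significant=bool(p < alpha),
    )
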
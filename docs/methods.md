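# Methods

This note documents the models, estimators and numerical choices behind
each pipeline, what the synthetic phantoms do and do not emulate, and
the known limitations.

## Micro-CT vessel census (`bpdph.microct`)

**Model of the data.** An iodine-stained lung lobe imaged at 6.0 µm
isotropic voxel pitch: vessels are bright tubes on a darker parenchymal
background, stored as 8-bit stacks. Vessels of interest span 4–30 µm —
from two-thirds of a voxel to five voxels in diameter — so partial
volume dominates the smallest classes: a 4.5 µm capillary appears as a
dim one-voxel-wide trace whose brightness, not width, carries its size.

**Chain.**
1. *Edge detection* — two per-plane difference-of-Gaussian band-passes
   of increasing scale (σ = 2 then 5 px, inner/outer σ ratio 1.6), each
   thresholded (global Otsu by default; per-plane Otsu and fixed levels
   available) and median-despeckled; the final mask is their
   intersection, so a voxel must respond at both scales. Wide vessels
   respond only at their walls (the band-pass suppresses flat
   interiors), producing the edge mask the filling step needs.
   Per-plane Otsu is not the default because on planes containing no
   vessel Otsu bisects noise and floods the mask.
2. *Filling* — per plane: despeckle (median, preserving pixels with ≥3
   set neighbours so convex boundaries survive), skeletonize the walls,
   drop fragments < 5 px, bridge each skeleton tip to its nearest other
   tip within 5 px, flood-fill enclosed regions. Idempotent on solid
   input; on closed contours it equals the border-flood-fill complement
   (tested against that oracle).
3. *Tracing* — two passes. Large vessels: 3D thinning of the filled
   mask, after discarding filled components whose bright intensity core
   never reaches 1.5 voxels of half-width (these are fill artefacts of
   capillary-scale vessels, which remain available to the small-vessel
   pass — the analogue of cleaning the filled channel with a smoothed
   surface). Small vessels: intensity threshold at background + 10% of
   the dynamic range (low enough to keep partial-volume capillaries), a
   2-voxel guard zone around retained large vessels, gap closing, 3D
   thinning. Skeleton paths between tips/branch points become segments.
   The thinning wrapper re-derives a principal-axis centreline for
   components the library thinning deletes outright (it erases
   even-width bars).
4. *Diameters* — per-point radius is the Euclidean distance transform
   of the class mask at the centreline minus half a voxel (a one-voxel
   line reads exactly one voxel, 6 µm); segment diameter is twice the
   median. Because a binary EDT cannot resolve below the voxel pitch,
   segments with EDT radius ≤ 6 voxels are refined by an
   integrated-opacity estimator: shell voxels are assigned to their
   nearest centreline point, per-point sums are boxcar-smoothed (the
   voxel-to-point assignment is lattice-uneven along oblique paths) and
   divided by the local arc length of the 5-point-smoothed polyline
   (the raw 26-connected chain overstates length by its staircase), and
   `d = 2·voxel_size·sqrt(area/π)` from the median per-point area.
   Opacity conservation makes this estimator unbiased well below the
   pitch. Signed residuals are summed (clipping at zero would rectify
   noise into a positive bias); background and full-fill amplitude are
   estimated from the volume itself (median; 99th percentile of
   foreground). Segments outside both masks are excluded with a logged
   warning.
5. *Binning and normalization* — half-open [lo, hi) bins with first
   edge fixed at the 4 µm resolution cutoff; diameters below it and
   beyond the last edge are tallied separately so counts are conserved.
   Percent-of-total is per lobe; normalized values multiply the percent
   by the lobe's total over the reference-group mean total, making the
   normalized bin proportional to absolute per-bin abundance. Percent
   is computed before normalization, following the order in which the
   two steps are described.

**Phantoms.** Tubes are rendered as capsules with anti-aliased
partial-volume weighting (4× supersampling with a one-subcell linear
coverage ramp; hard-threshold supersampling quantizes sub-voxel areas).
Per-bin counts are Poisson draws around the profile expectations;
larger (≥ 7 µm) vessels may attach in sibling pairs to an existing
vessel's endpoint, forming shallow trees; capillaries are isolated, as
they effectively are at this resolution. Minimum surface clearance is
3 voxels. Default noise: additive Gaussian, σ = 2 grey levels on a
200-level amplitude (~1% of dynamic range, consistent with averaged
synchrotron reconstructions).

**Bundled profiles.** Small-bin depletions (0.16/0.17/0.24) encode the
reported −84/−83/−76% losses; medium-bin depletions (0.50–0.80) follow
the reported monotone easing of the loss with diameter, and absolute
air-group counts fill a 128³ volume at realistic density — both free
parameters, chosen once. At 6 µm pitch a 1-µm-wide bin cannot be
recovered per-vessel without error: diameter scatter of ±0.3–0.5 µm
moves borderline vessels between adjacent bins, so recovered per-bin
reductions carry a few points of cross-talk bias (larger where
neighbouring bins differ strongly in depletion). The 5+5-volume
comparison recovers the three small-bin reductions to well within ±10
percentage points.

## Cine-angiography (`bpdph.angiography`)

Subtraction uses the last pre-injection frame, clipped at zero (vessel
opacity only increases with contrast); a 2-px-radius disk median
filter cleans speckle. Automated counting thresholds the peak-opacity
frame (Otsu), skeletonizes, builds the branch graph, roots each
connected tree at its tip nearest the inflow edge, and assigns each
segment the topological depth from the root (root = generation 1) up
to generation 3. Two skeleton artefacts are handled explicitly: spur
segments shorter than 6 px are pruned, and junction-to-junction
segments shorter than 18 px are contracted — where daughters leave a
branch point at a small angle their proximal portions blur into one
ridge and the skeleton splits a few pixels downstream, which would
otherwise shift every distal vessel one generation deeper. 18 px is
far below any real segment (generation-3 vessels are ~30 px).
Depth-from-root was chosen over Strahler order because the study's
1st/2nd/3rd naming is proximal→distal.

**Phantoms.** A static background (smoothed noise + high-contrast
bars) plus a branching forest whose opacity follows a saturating
arrival curve; background staticity makes subtraction exact. Each of
the n₁ root vessels owns a horizontal band; every parent spawns 0, 2
or 3 children at its distal tip at wide nominal angles (±33°/±28°), so
counts per generation are exact by construction and trees cannot
collide. The bundled profiles encode the reported −18% (generation 2)
and −21% (generation 3) losses; automated counts match ground truth
exactly in all tested seeds, so group comparisons recover the
configured reductions.

## PCLS reactivity (`bpdph.pcls`)

Lumen area = pixel count of the connected dark component under a
grayscale threshold (Otsu by default), seeded or largest. Responses:
plateau = mean of the final 20% of each 10-min step window; response =
100·(1 − plateau/initial), with the initial area from the baseline
(zero-drug) window mean. The 4PL is fitted on log10 concentration by
bounded least squares (bottom ∈ [−10, 10] %, top ∈ [0, 100] %, Hill ∈
[0.2, 5]); zero-concentration points anchor the baseline but are
excluded from the log-domain fit; flat data are flagged degenerate
rather than fitted. With only six concentrations, noise can flatten
the slope and let the plateau run away (a shallow-Hill/high-top
trade-off that leaves the maximum unidentified); when the free fit
returns a top with SE > 8 points or a Hill slope ≤ 0.5, the curve is
refit with the Hill slope fixed at 1 — the standard single-receptor
reduction — and flagged. This keeps replicate-mean maxima unbiased
without constraining well-identified fits.

**Phantoms.** A dark lumen ellipse in bright tissue whose area follows
the 4PL times (1 + Gaussian noise) per frame; the ellipse scale is
bisected so the rasterized pixel count matches the drawn area to 1–2
px. Defaults: 60 frames per concentration step — a desk-scale stand-in
for the 0.5 Hz × 10 min acquisition (300 frames/step) that keeps
plateau noise realistic. Bundled profiles: maxima 43% (ET-1) and 38%
(U46619); logEC50 −8.0 and −7.0 (one log unit apart, matching the
~10-fold potency difference, with ET-1's EC50 inside its 1–100 nM
range); Hill 1. With 8 replicates at 5% noise the mean fitted maxima
recover the generating values within one SEM; the highest tested dose
reaches only ~91% of plateau, so individual fitted maxima scatter by a
few percent.

## Echocardiography (`bpdph.echo`)

The ejection window is detected at 5% of peak velocity with linear
interpolation between samples; the peak is located by intersecting
least-squares lines fitted to the rising and falling flanks (30–90% of
peak). For a triangular envelope both constructions are exact at any
sampling rate, and the 5% threshold scales TPV and RVET by the same
0.95 factor, so the ratio is recovered exactly; `peak_method="argmax"`
is available for irregular envelopes. Fractional shortening is the
standard `100·(LVIDd − LVIDs)/LVIDd`.

**Profiles.** Only the group ratios are reported (0.32/0.27/0.31);
the bundled profiles use RVET = 50 ms (typical for an anaesthetised
mouse) with TPV scaled to the ratios, sampled at 1 kHz. The triangular
envelope is a stylization: it has the correct single-peak topology and
exact recovery properties but not the rounded systolic contour of real
Doppler traces.

## Molecular quantification (`bpdph.molquant`)

- Housekeeping selection: minimal CT standard deviation across all
  samples (simplest defensible reading of "most stably expressed");
  ties break alphabetically with a log note.
- ΔΔCT uses group-mean ΔCT (unpaired design); per-sample relative
  values 2^−(ΔCT − mean ΔCT_ref) feed SEM reporting, and a display
  scaling relative to the lowest-expressed level is returned alongside
  (two presentation conventions exist for multi-gene panels; both are
  produced rather than reconciled).
- Positive-pixel score: HSV hue window (default DAB brown) with
  saturation gate; strong = value ≤ 0.55; score = Σ(255 − mean RGB)
  over strong pixels / tissue area (µm²).
- Collagen fraction: red-class pixels (wrap-around hue window about 0,
  saturation ≥ 0.3) over non-vessel tissue, ×100.
- Group statistics: Shapiro-Wilk normality per group and
  Brown-Forsythe equal variance (rejection at 0.05, reported, not
  gating), two-sided t-test for two groups, one-way ANOVA + Tukey HSD
  otherwise; significance at P < 0.05; means ± SEM throughout.

**Phantoms.** CT tables are group means + Gaussian cycles. Histology
sections place an exact red-pixel count (thresholded smooth noise →
spatially correlated patches) on a myocardial background with
elliptical vessel lumina; between-specimen biology is simulated by a
6% CV on the group-mean collagen fraction (chosen once as typical
section-to-section scatter). The qPCR fixture encodes the reported
folds (Lgals3 2.9×, Ccl2 1.8×, Nppb 1.0×, with the reported IL-1Ra
reversals); absolute CT levels are free parameters.

## What the phantoms do not emulate

Reconstruction physics (beam hardening, ring artefacts, phase
retrieval), anatomy (real branching geometry, vessel curvature and
taper, cardiac/respiratory motion), staining chemistry and
illumination variation in histology, and amplification-efficiency
differences in qPCR. Passing recovery tests therefore demonstrates
correctness of the measurement chains under controlled image
formation, not robustness to every artefact of the instruments.

## Problem sizes

The shipped comparisons run at desk scale, chosen once: 5+5 micro-CT
volumes of 128³ voxels, 10 seeded angiograms of 960×640 px per group,
8 PCLS replicates × 7 steps × 60 frames of 160² px, 8+8 histology
sections of 256² px. These sizes put Poisson and fit uncertainty
comfortably inside each stated tolerance while keeping the full suite
in minutes on one CPU core.
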
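"""Parameter-recovery experiments over the bundled condition profiles.

Each function simulates one arm of the study at desk scale — generating
phantoms from the bundled profiles, running the corresponding analysis
chain end to end, and reducing the result to the group-level quantity
the study reports.  The analysis drivers, the test suite and the
reproduction script all call these entry points, so the numbers they
print are always produced by the same computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import profiles
from .angiography import (
    AngiogramSequence,
    count_generations,
    median_filter_frames,
    peak_frame,
    subtract_background,
)
from .echo import VelocityTrace, compute_tpv_rvet
from .microct import normalize_to_reference, run_microct_pipeline
from .molquant import collagen_fraction, ddct_fold_change, select_housekeeping
from .pcls import FourPLParams, LumenTrace, build_concentration_response, fit_four_pl, segment_lumen
from .phantoms import (
    ConditionProfile,
    DopplerProfile,
    generate_angiogram_sequence,
    generate_ct_table,
    generate_doppler_trace,
    generate_histology_image,
    generate_pcls_timelapse,
)

__all__ = [
    "microct_condition_comparison",
    "echo_group_ratio",
    "pcls_replicate_fits",
    "pcls_potency_ratio",
    "angiography_generation_counts",
    "collagen_group_fractions",
    "heart_qpcr_fold_changes",
]


def microct_condition_comparison(
    groups: dict[str, list[int]] | None = None,
    shape: tuple[int, int, int] = (128, 128, 128),
    reference_group: str = "air_vehicle",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full vessel census on seeded phantom volumes per group.

    ``groups`` maps condition name -> list of seeds (default: the study
    comparison, 5 air and 5 hyperoxia volumes).  Returns the per-bin
    group summary (mean ± SEM of normalized values) and a per-bin
    percent-change table of every group against the reference.
    """
    if groups is None:
        groups = {"air_vehicle": [1, 2, 3, 4, 5], "hyperoxia_vehicle": [6, 7, 8, 9, 10]}
    cfg = profiles.microct_conditions()
    hists = []
    for group, seeds in groups.items():
        prof = ConditionProfile.from_config(cfg, group)
        for seed in seeds:
            vol, _ = generate_vascular_volume_cached(prof, shape, seed)
            _, hist = run_microct_pipeline(
                vol, specimen_id=f"{group}_{seed}", group=group
            )
            hists.append(hist)
    _, summary = normalize_to_reference(hists, reference_group)

    piv = summary.pivot_table(index=["bin_lo_um", "bin_hi_um"], columns="group", values="mean")
    changes = []
    for group in groups:
        if group == reference_group:
            continue
        pct = 100.0 * (1.0 - piv[group] / piv[reference_group])
        for (lo, hi), v in pct.items():
            changes.append(
                {"group": group, "bin_lo_um": lo, "bin_hi_um": hi, "reduction_pct": v}
            )
    return summary, pd.DataFrame(changes)


def generate_vascular_volume_cached(prof, shape, seed):
    # thin indirection kept for monkeypatching in tests
    from .phantoms import generate_vascular_volume

    return generate_vascular_volume(prof, shape=shape, seed=seed)


def echo_group_ratio(group: str, sample_rate_hz: float = 1000.0) -> float:
    """TPV/RVET of the deterministic envelope built from a bundled profile."""
    cfg = profiles.doppler_profiles()
    prof = DopplerProfile.from_config(cfg, group)
    prof.sample_rate = sample_rate_hz
    t, v = generate_doppler_trace(prof)
    return compute_tpv_rvet(VelocityTrace(t, v))


def _fit_one_replicate(params: FourPLParams, conc_molar: np.ndarray, noise_sd: float, seed: int):
    frames, gt = generate_pcls_timelapse(params, conc_molar, noise_sd=noise_sd, seed=seed)
    areas = np.array([segment_lumen(f) for f in frames])
    trace = LumenTrace(times=gt.times_s, areas=areas)
    steps = np.array(
        [gt.times_s[gt.step_of_frame == i].min() for i in range(len(gt.concentrations))]
    )
    cr = build_concentration_response(trace, steps, gt.concentrations)
    return fit_four_pl(cr)


def pcls_replicate_fits(
    agonist: str,
    seeds: list[int] | None = None,
    noise_sd: float = 0.05,
) -> pd.DataFrame:
    """Image-based 4PL fits for n seeded replicate arteries of one agonist."""
    if seeds is None:
        seeds = list(range(1, 9))
    cfg = profiles.pcls_agonists()
    params = FourPLParams.from_config(cfg, agonist)
    conc = np.asarray(cfg["profiles"][agonist]["concentrations_nm"], float) * 1e-9
    rows = []
    for seed in seeds:
        fit = _fit_one_replicate(params, conc, noise_sd, seed)
        rows.append(
            {
                "agonist": agonist,
                "seed": seed,
                "max_reduction_pct": fit.max_reduction,
                "pec50": fit.pec50,
                "hill": fit.params.hill,
            }
        )
    return pd.DataFrame(rows)


def pcls_potency_ratio() -> float:
    """EC50 ratio (U46619 / ET-1) from noise-free image-based fits."""
    cfg = profiles.pcls_agonists()
    fits = {}
    for agonist in ("et1", "u46619"):
        params = FourPLParams.from_config(cfg, agonist)
        conc = np.asarray(cfg["profiles"][agonist]["concentrations_nm"], float) * 1e-9
        fits[agonist] = _fit_one_replicate(params, conc, 0.0, 0)
    return 10.0 ** (-fits["u46619"].pec50) / 10.0 ** (-fits["et1"].pec50)


def angiography_generation_counts(group: str, seeds: list[int] | None = None) -> pd.DataFrame:
    """Automated per-generation counts on seeded phantom angiograms."""
    if seeds is None:
        seeds = list(range(1, 11))
    cfg = profiles.angiogram_trees()
    counts = tuple(cfg["conditions"][group]["counts"])
    rows = []
    for seed in seeds:
        frames, gt = generate_angiogram_sequence(counts, seed=seed)
        seq = AngiogramSequence(frames, pre_injection_index=gt.arrival_index - 1)
        frame = median_filter_frames(peak_frame(subtract_background(seq)))
        gc = count_generations(frame)
        g1, g2, g3 = gc.as_tuple()
        rows.append(
            {"group": group, "seed": seed, "gen1": g1, "gen2": g2, "gen3": g3,
             "true1": counts[0], "true2": counts[1], "true3": counts[2]}
        )
    return pd.DataFrame(rows)


def collagen_group_fractions(
    groups: dict[str, list[int]] | None = None,
    shape: tuple[int, int] = (256, 256),
) -> pd.DataFrame:
    """Collagen fraction per phantom section, with vessel exclusion.

    Per-specimen collagen fractions are drawn around the group mean with
    the profile's between-animal CV, then measured back from the
    rendered image by the quantification operation.
    """
    if groups is None:
        groups = {"air_vehicle": list(range(1, 9)), "hyperoxia_vehicle": list(range(9, 17))}
    cfg = profiles.histology_collagen()
    cv = float(cfg.get("specimen_cv", 0.06))
    vessel_fraction = float(cfg.get("vessel_fraction", 0.05))
    rows = []
    for group, seeds in groups.items():
        mean_f = float(cfg["conditions"][group]["collagen_fraction"])
        for seed in seeds:
            rng = np.random.default_rng(seed)
            f = max(1e-4, mean_f * (1.0 + cv * rng.standard_normal()))
            img, gt = generate_histology_image(f, vessel_fraction, shape=shape, seed=seed)
            measured = collagen_fraction(img, gt.vessel_mask)
            rows.append(
                {"group": group, "seed": seed, "true_fraction_pct": 100 * gt.collagen_fraction,
                 "measured_fraction_pct": measured}
            )
    return pd.DataFrame(rows)


def heart_qpcr_fold_changes(
    noise_sd: float = 0.0,
    n_per_group: int = 8,
    seed: int = 0,
    targets: tuple[str, ...] = ("Lgals3", "Ccl2", "Nppb"),
) -> pd.DataFrame:
    """ΔΔCT fold changes of the cardiac panel vs the air-vehicle group."""
    cfg = profiles.heart_qpcr()
    table = generate_ct_table(
        cfg["group_means_ct"], noise_sd=noise_sd, n_per_group=n_per_group,
        seed=seed, housekeeping=cfg["housekeeping"],
    )
    hk = select_housekeeping(table, cfg["housekeeping_candidates"])
    table.housekeeping = hk
    rows = []
    for target in targets:
        for group in cfg["group_means_ct"]:
            if group == "air_vehicle":
                continue
            r = ddct_fold_change(table, target, "air_vehicle", group)
            rows.append(
                {"gene": target, "group": group, "fold_change": r.fold_change,
                 "housekeeping": hk}
            )
    return pd.DataFrame(rows)
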
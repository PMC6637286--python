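"""ΔΔCT, protein normalization, stain scores and group statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bpdph.molquant import (
    ExpressionTable,
    collagen_fraction,
    ddct_fold_change,
    group_compare,
    normalize_to_total_protein,
    positive_pixel_score,
    select_housekeeping,
)
from bpdph.phantoms import generate_ct_table, generate_histology_image


def make_table(data, groups, housekeeping="Actb"):
    ct = pd.DataFrame(data)
    ct.index = [f"s{i}" for i in range(len(ct))]
    return ExpressionTable(ct=ct, groups=pd.Series(groups, index=ct.index), housekeeping=housekeeping)


class TestHousekeeping:
    def test_single_candidate(self):
        t = make_table({"Actb": [18, 18.1, 17.9, 18]}, ["a"] * 4)
        assert select_housekeeping(t, ["Actb"]) == "Actb"

    def test_lowest_sd_wins(self):
        t = make_table(
            {"A": [18.0, 18.1, 18.0, 17.9], "B": [20.0, 21.0, 19.0, 20.5]},
            ["a", "a", "b", "b"],
            housekeeping="A",
        )
        assert select_housekeeping(t, ["A", "B"]) == "A"

    def test_sd_matches_hand_value(self):
        vals = [18.0, 18.4, 17.6, 18.0]
        t = make_table({"A": vals}, ["a"] * 4, housekeeping="A")
        hand_sd = np.std(vals, ddof=1)
        assert t.ct["A"].std(ddof=1) == pytest.approx(hand_sd)

    def test_no_candidate_present(self):
        t = make_table({"Actb": [18] * 3}, ["a"] * 3)
        with pytest.raises(ValueError):
            select_housekeeping(t, ["Gapdh"])


class TestDdct:
    def test_equal_groups_fold_one(self):
        t = make_table(
            {"Actb": [18.0] * 4, "X": [25.0] * 4}, ["ref", "ref", "cmp", "cmp"]
        )
        r = ddct_fold_change(t, "X", "ref", "cmp")
        assert r.fold_change == pytest.approx(1.0)

    def test_one_cycle_doubling(self):
        t = make_table(
            {"Actb": [18.0] * 4, "X": [25.0, 25.0, 24.0, 24.0]},
            ["ref", "ref", "cmp", "cmp"],
        )
        r = ddct_fold_change(t, "X", "ref", "cmp")
        assert r.fold_change == pytest.approx(2.0)

    @given(st.floats(-5, 5))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_shift_invariance(self, shift):
        t = make_table(
            {"Actb": [18.0, 18.2, 17.8, 18.1], "X": [25.0, 24.8, 23.9, 24.2]},
            ["ref", "ref", "cmp", "cmp"],
        )
        r1 = ddct_fold_change(t, "X", "ref", "cmp")
        t2 = make_table(
            {"Actb": np.array([18.0, 18.2, 17.8, 18.1]) + shift,
             "X": np.array([25.0, 24.8, 23.9, 24.2]) + shift},
            ["ref", "ref", "cmp", "cmp"],
        )
        r2 = ddct_fold_change(t2, "X", "ref", "cmp")
        assert r1.fold_change == pytest.approx(r2.fold_change, rel=1e-9)

    def test_reference_against_itself_is_one(self):
        t = make_table(
            {"Actb": [18.0, 18.3, 17.7], "X": [25.0, 24.5, 25.5]}, ["ref"] * 3
        )
        r = ddct_fold_change(t, "X", "ref", "ref")
        assert r.fold_change == pytest.approx(1.0)

    def test_missing_gene_rejected(self):
        t = make_table({"Actb": [18.0] * 2}, ["a", "b"])
        with pytest.raises(ValueError):
            ddct_fold_change(t, "Nope", "a", "b")


class TestProteinNormalization:
    def test_simple_ratio(self):
        df = normalize_to_total_protein([100.0], [2.0])
        assert df["normalized"].iloc[0] == pytest.approx(50.0)

    def test_scale_invariance(self):
        a = normalize_to_total_protein([100.0, 60.0], [2.0, 1.5])
        b = normalize_to_total_protein([200.0, 120.0], [4.0, 3.0])
        np.testing.assert_allclose(a["normalized"], b["normalized"])

    def test_group_ratio_reproduced(self):
        analyte = np.array([10.0, 12, 11, 14.0, 16.8, 15.4])
        protein = np.array([1.0, 1, 1, 1, 1, 1])
        df = normalize_to_total_protein(analyte, protein, groups=["air"] * 3 + ["hyp"] * 3)
        means = df.groupby("group")["normalized"].mean()
        assert means["hyp"] / means["air"] == pytest.approx(1.4)

    def test_nonpositive_protein_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_total_protein([1.0], [0.0])


class TestStainScore:
    def test_blank_image_scores_zero(self):
        img = np.full((32, 32, 3), 255, np.uint8)
        s = positive_pixel_score(img, np.ones((32, 32), bool))
        assert s.score == 0.0

    def test_known_strong_pixels_hand_computed(self):
        img = np.full((20, 20, 3), 255, np.uint8)
        img[5:8, 5:8] = (120, 70, 30)          # dark brown: strong positive
        mask = np.ones((20, 20), bool)
        s = positive_pixel_score(img, mask, pixel_size_um=2.0)
        intensity = 255.0 - np.mean([120, 70, 30])
        assert s.n_strong == 9
        assert s.score == pytest.approx(9 * intensity / (400 * 4.0))

    def test_doubling_area_halves_score(self):
        img = np.full((20, 40, 3), 255, np.uint8)
        img[5:8, 5:8] = (120, 70, 30)
        half = np.zeros((20, 40), bool)
        half[:, :20] = True
        s_half = positive_pixel_score(img, half)
        s_full = positive_pixel_score(img, np.ones((20, 40), bool))
        assert s_full.score == pytest.approx(s_half.score / 2.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            positive_pixel_score(np.zeros((4, 4, 3)), np.zeros((4, 4), bool))


class TestCollagenFraction:
    def test_no_red_is_zero(self):
        img, gt = generate_histology_image(0.0, 0.0, shape=(64, 64), seed=0)
        assert collagen_fraction(img, gt.vessel_mask) == pytest.approx(0.0, abs=0.2)

    def test_quarter_fraction_recovered(self):
        img, gt = generate_histology_image(0.25, 0.0, shape=(128, 128), seed=1)
        assert collagen_fraction(img, gt.vessel_mask) == pytest.approx(25.0, abs=0.5)

    def test_red_inside_vessels_excluded(self):
        img, gt = generate_histology_image(
            0.0, 0.15, shape=(128, 128), seed=2, paint_vessel_rims_red=True
        )
        assert collagen_fraction(img, gt.vessel_mask) == pytest.approx(0.0, abs=0.2)

    def test_fraction_complement_sums_to_tissue(self):
        img, gt = generate_histology_image(0.12, 0.05, shape=(96, 96), seed=3)
        f = collagen_fraction(img, gt.vessel_mask)
        assert 0.0 <= f <= 100.0
        true = 100.0 * gt.collagen_fraction
        assert f == pytest.approx(true, abs=0.6)

    def test_zero_tissue_rejected(self):
        img = np.zeros((8, 8, 3), np.uint8)
        with pytest.raises(ValueError):
            collagen_fraction(img, np.ones((8, 8), bool))


class TestGroupCompare:
    def test_identical_groups_t_zero_p_one(self):
        r = group_compare({"a": [1.0, 2, 3], "b": [1.0, 2, 3]})
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_three_group_anova_matches_hand_f(self):
        groups = {"g1": [1.0, 2, 3], "g2": [2.0, 3, 4], "g3": [5.0, 6, 7]}
        r = group_compare(groups, design="multi_group")
        data = [np.asarray(v) for v in groups.values()]
        grand = np.concatenate(data).mean()
        ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in data)
        ss_within = sum(((v - v.mean()) ** 2).sum() for v in data)
        f_hand = (ss_between / 2) / (ss_within / 6)
        assert r.statistic == pytest.approx(f_hand)
        assert r.pairwise is not None

    def test_two_group_f_equals_t_squared(self):
        from scipy import stats

        a = np.array([1.0, 2.2, 3.1, 2.5])
        b = np.array([2.0, 3.4, 4.1, 3.3])
        t = stats.ttest_ind(a, b).statistic
        f = stats.f_oneway(a, b).statistic
        assert f == pytest.approx(t**2)
        r = group_compare({"a": a, "b": b})
        assert r.statistic == pytest.approx(t)

    def test_p_values_in_unit_interval_and_report_fields(self):
        rng = np.random.default_rng(2)
        groups = {g: rng.normal(size=6) for g in ("a", "b", "c")}
        r = group_compare(groups)
        assert 0 <= r.p_value <= 1
        assert set(r.means) == {"a", "b", "c"}
        assert all(0 <= p <= 1 for p in r.normality_p.values())

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare({"a": [1.0], "b": [1.0, 2.0]})


class TestEndToEndFixture:
    def test_bundled_fixture_reproduces_configured_folds(self):
        from bpdph.profiles import heart_qpcr

        cfg = heart_qpcr()
        t = generate_ct_table(
            cfg["group_means_ct"], noise_sd=0.0, n_per_group=3, housekeeping=cfg["housekeeping"]
        )
        hk = select_housekeeping(t, cfg["housekeeping_candidates"])
        assert hk == "Actb"
        r = ddct_fold_change(t, "Lgals3", "air_vehicle", "hyperoxia_vehicle")
        assert r.fold_change == pytest.approx(2.9, abs=1e-4)
        r2 = ddct_fold_change(t, "Ccl2", "air_vehicle", "hyperoxia_vehicle")
        assert r2.fold_change == pytest.approx(1.8, abs=1e-4)
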
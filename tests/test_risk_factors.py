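import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from doubleread.risk_factors import (
    BINARY_FEATURES,
    baseline_features,
    delta_burden,
    infrequent_location,
    optimize_threshold,
    organ_frequency_table,
    organ_overlap_flags,
    sprop_sod,
    univariate_screen,
)
from conftest import make_lesion_row


class TestDeltaBurden:
    def test_equal_sods_zero(self):
        assert delta_burden(50, 50) == 0.0

    def test_formula(self):
        assert delta_burden(60, 40) == pytest.approx(0.2)

    def test_one_sided_boundary(self):
        assert delta_burden(35.0, 0.0) == 1.0

    def test_both_zero_missing(self):
        assert math.isnan(delta_burden(0, 0))

    @given(
        a=st.floats(0.1, 500.0),
        b=st.floats(0.1, 500.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_bounds_and_symmetry_property(self, a, b):
        v = delta_burden(a, b)
        assert 0.0 <= v <= 1.0
        assert v == pytest.approx(delta_burden(b, a))
        if a == b:
            assert v == 0.0

    def test_symmetric_and_scale_invariant(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b = rng.uniform(1, 100, 2)
            k = rng.uniform(0.1, 10)
            assert delta_burden(a, b) == pytest.approx(delta_burden(b, a))
            assert delta_burden(k * a, k * b) == pytest.approx(
                delta_burden(a, b)
            )
            assert 0 <= delta_burden(a, b) <= 1


class TestOrganOverlap:
    def test_partial_overlap(self):
        flags = organ_overlap_flags({"LUNG", "LIVER"}, {"LUNG", "ADRENAL"})
        assert flags["tl_not_all_same_organs"]
        assert not flags["all_tls_different_organs"]

    def test_disjoint(self):
        flags = organ_overlap_flags({"LIVER"}, {"ADRENAL"})
        assert flags["tl_not_all_same_organs"]
        assert flags["all_tls_different_organs"]

    def test_identical(self):
        flags = organ_overlap_flags({"LUNG"}, {"LUNG"}, {"BONE"}, {"BONE"})
        assert not flags["tl_not_all_same_organs"]
        assert not flags["all_tls_different_organs"]
        assert not flags["ntl_not_all_same_organs"]

    def test_implication_property(self):
        organs = ["LUNG", "LIVER", "ADRENAL", "BONE"]
        rng = np.random.default_rng(1)
        for _ in range(100):
            s1 = {o for o in organs if rng.random() < 0.5}
            s2 = {o for o in organs if rng.random() < 0.5}
            flags = organ_overlap_flags(s1, s2)
            if flags["all_tls_different_organs"]:
                assert flags["tl_not_all_same_organs"]


class TestSpropSod:
    def test_identical_maps_zero(self):
        assert sprop_sod({"LUNG": 50.0}, {"LUNG": 50.0}) == 0.0

    def test_disjoint_organs_one(self):
        assert sprop_sod({"LUNG": 50.0}, {"LIVER": 50.0}) == 1.0

    def test_partial(self):
        assert sprop_sod({"LUNG": 50.0}, {"LUNG": 30.0, "LIVER": 20.0}) == (
            pytest.approx(0.2)
        )

    def test_zero_total_missing(self):
        assert math.isnan(sprop_sod({}, {}))


class TestInfrequentLocation:
    TABLE = {"LUNG": 0.9, "LIVER": 0.3, "OTHER": 0.02}

    def test_all_frequent(self):
        assert not infrequent_location({"LUNG", "LIVER"}, self.TABLE)

    def test_unknown_organ_infrequent(self):
        assert infrequent_location({"LUNG", "SPLEEN"}, self.TABLE)

    def test_below_cutoff(self):
        assert infrequent_location({"OTHER"}, self.TABLE, cutoff=0.05)

    def test_exactly_at_cutoff_not_flagged(self):
        assert not infrequent_location({"LIVER"}, self.TABLE, cutoff=0.3)


def _baseline_table(rows):
    return pd.DataFrame([make_lesion_row(**r) for r in rows])


class TestBaselineFeatures:
    def test_two_reader_features(self):
        rows = [
            dict(reader_id="R1", lesion_id="L1", organ="LUNG", diameter_mm=30.0),
            dict(reader_id="R1", lesion_id="L2", organ="LIVER", diameter_mm=20.0),
            dict(reader_id="R2", lesion_id="L1", organ="LUNG", diameter_mm=40.0),
            dict(
                reader_id="R1",
                lesion_id="L3",
                organ="BONE",
                category="NTL",
                diameter_mm=np.nan,
                ntl_status="PRESENT",
            ),
            dict(
                reader_id="R2",
                lesion_id="L3",
                organ="BONE",
                category="NTL",
                diameter_mm=np.nan,
                ntl_status="PRESENT",
            ),
        ]
        feats = baseline_features(_baseline_table(rows)).iloc[0]
        assert feats["tl_not_all_same_organs"]
        assert not feats["all_tls_different_organs"]
        assert not feats["ntl_not_all_same_organs"]
        assert feats["delta_burden"] == pytest.approx(abs(50 - 40) / 90)
        # reader-specific LIVER burden / combined SOD
        assert feats["sprop_sod"] == pytest.approx(20 / 90)
        assert not feats["non_measurable_one_reader"]

    def test_ntl_only_reader_flagged(self):
        rows = [
            dict(reader_id="R1", lesion_id="L1", diameter_mm=30.0),
            dict(
                reader_id="R2",
                lesion_id="L1",
                category="NTL",
                diameter_mm=np.nan,
                ntl_status="PRESENT",
            ),
        ]
        feats = baseline_features(_baseline_table(rows)).iloc[0]
        assert feats["non_measurable_one_reader"]
        assert feats["delta_burden"] == 1.0

    def test_organ_frequency_table(self):
        rows = [
            dict(patient_id="P1", reader_id="R1", organ="LUNG"),
            dict(patient_id="P1", reader_id="R2", organ="LUNG"),
            dict(patient_id="P2", reader_id="R1", organ="LIVER"),
            dict(patient_id="P2", reader_id="R2", organ="LUNG"),
        ]
        table = organ_frequency_table(_baseline_table(rows))
        assert table["LUNG"] == 1.0
        assert table["LIVER"] == 0.5


def _screen_tables(n, rng, assoc=False):
    feature = rng.random(n) < 0.5
    flag = rng.random(n) < (0.55 * feature + 0.15 if assoc else 0.3)
    features = pd.DataFrame(
        {
            "patient_id": range(n),
            **{name: feature for name in BINARY_FEATURES},
            "delta_burden": rng.random(n),
            "sprop_sod": rng.random(n),
        }
    )
    kods = pd.DataFrame(
        {
            "patient_id": range(n),
            "included": True,
            "bor": flag,
        }
    )
    return features, kods


class TestUnivariateScreen:
    def test_hand_computed_or(self):
        # 2x2 (a,b,c,d) = (20,10,5,10) -> OR 4
        features = pd.DataFrame(
            {
                "patient_id": range(45),
                "tl_not_all_same_organs": [True] * 30 + [False] * 15,
            }
        )
        kods = pd.DataFrame(
            {
                "patient_id": range(45),
                "included": True,
                "bor": [True] * 20 + [False] * 10 + [True] * 5 + [False] * 10,
            }
        )
        out = univariate_screen(
            features,
            kods,
            "bor",
            binary_features=["tl_not_all_same_organs"],
            continuous_features=[],
        )
        assert out["oddsratio"].iloc[0] == pytest.approx(4.0)

    def test_degenerate_feature_rejected(self):
        rng = np.random.default_rng(2)
        features, kods = _screen_tables(50, rng)
        features["no_disease_one_reader"] = False
        with pytest.raises(ValueError, match="degenerate"):
            univariate_screen(features, kods, "bor")

    def test_continuous_features_get_p(self):
        rng = np.random.default_rng(3)
        features, kods = _screen_tables(80, rng)
        out = univariate_screen(features, kods, "bor")
        cont = out[out["kind"] == "continuous"]
        assert cont["p"].notna().all()

    def test_type_one_error_calibration(self):
        # independent feature/flag: ~5% of screens significant at 0.05
        rng = np.random.default_rng(4)
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            features, kods = _screen_tables(200, rng)
            out = univariate_screen(
                features,
                kods,
                "bor",
                binary_features=["tl_not_all_same_organs"],
                continuous_features=[],
            )
            hits += out["p"].iloc[0] < 0.05
        assert 0.03 <= hits / n_rep <= 0.07

    def test_association_detected(self):
        rng = np.random.default_rng(5)
        features, kods = _screen_tables(400, rng, assoc=True)
        out = univariate_screen(
            features,
            kods,
            "bor",
            binary_features=["tl_not_all_same_organs"],
            continuous_features=[],
        )
        assert out["oddsratio"].iloc[0] > 2
        assert out["p"].iloc[0] < 0.01


class TestOptimizeThreshold:
    def test_recovers_construction_threshold(self):
        rng = np.random.default_rng(6)
        x = rng.random(400)
        flip = rng.random(400) < 0.1
        y = (x > 0.3) ^ flip
        thr, orr = optimize_threshold(x, y)
        assert thr == pytest.approx(0.3, abs=0.05)
        assert orr > 10

    def test_perfect_separation_capped(self):
        x = np.array([0.1, 0.2, 0.8, 0.9])
        y = np.array([False, False, True, True])
        thr, orr = optimize_threshold(x, y)
        assert orr == 1e6
        assert 0.2 <= thr <= 0.8

    def test_independent_feature_or_near_one(self):
        # permutation oracle: no threshold should give a large OR
        rng = np.random.default_rng(7)
        x = rng.random(500)
        y = rng.random(500) < 0.4
        grid = np.linspace(0.1, 0.9, 17)
        _, best = optimize_threshold(x, y, grid=grid)
        assert best < 2.0  # best-case selection bounded under independence

    def test_needs_two_levels(self):
        with pytest.raises(ValueError):
            optimize_threshold([1.0, 1.0], [True, False])


class TestOnSimulatedCohort:
    def test_features_computed_for_cohort(self, default_trial):
        _, lesions, _ = default_trial
        feats = baseline_features(lesions)
        assert len(feats) > 400
        assert feats["delta_burden"].dropna().between(0, 1).all()
        assert feats["sprop_sod"].dropna().between(0, 1).all()
        implied = feats["all_tls_different_organs"] <= feats["tl_not_all_same_organs"]
        assert implied.all()

    def test_screen_runs_on_cohort(self, default_trial, default_kods):
        _, lesions, _ = default_trial
        feats = baseline_features(lesions)
        out = univariate_screen(feats, default_kods, "bor", on_degenerate="skip")
        assert {"tl_not_all_same_organs", "ntl_not_all_same_organs"} <= set(
            out["feature"]
        )
        assert {"delta_burden", "sprop_sod"} <= set(out["feature"])
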
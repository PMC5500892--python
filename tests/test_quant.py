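import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from apms import quant
from apms import synthdata as sd
from apms.io_model import CalibrationTable, DatasetMeta, ValidationError
from conftest import make_pv


class TestNormalizePeptideProfiles:
    def test_divides_by_row_maximum_keeping_missing(self, simple_matrix):
        prof = quant.normalize_peptide_profiles(simple_matrix)
        assert prof.loc["AAAA"].tolist()[:2] == [1.0, 0.5]
        assert math.isnan(prof.loc["AAAA", "d3"])
        assert prof.loc["DDDD"].tolist() == [1.0, 1.0, 1.0]

    def test_all_missing_peptide_dropped_with_warning(self, caplog):
        pv = make_pv(
            {"P1": {"AAAA": [np.nan, np.nan], "CCCC": [1.0, 2.0]}}, ["d1", "d2"]
        )
        with caplog.at_level("WARNING", logger="apms"):
            prof = quant.normalize_peptide_profiles(pv)
        assert list(prof.index) == ["CCCC"]
        assert any("no observed PV" in r.message for r in caplog.records)

    @settings(max_examples=30, deadline=None)
    @given(c=st.floats(min_value=1e-6, max_value=1e6, allow_nan=False))
    def test_scale_invariance_per_peptide(self, c):
        """Multiplying one peptide's PVs by c > 0 leaves its profile unchanged."""
        base = make_pv({"P": {"AAAA": [8.0, 4.0, 2.0]}}, ["d1", "d2", "d3"])
        scaled = make_pv(
            {"P": {"AAAA": [8.0 * c, 4.0 * c, 2.0 * c]}}, ["d1", "d2", "d3"]
        )
        a = quant.normalize_peptide_profiles(base)
        b = quant.normalize_peptide_profiles(scaled)
        assert np.allclose(a.to_numpy(), b.to_numpy(), rtol=1e-9)


class TestRankAndSelect:
    def test_anticorrelated_outlier_excluded(self):
        """Five concordant profiles + one anti-correlated peptide: the
        outlier must not enter peptides_used (brute-force expectation:
        any concordant subset ranks above it)."""
        datasets = [f"d{i}" for i in range(6)]
        good = [1.0, 0.8, 0.6, 0.4, 0.2, 0.1]
        bad = [0.1, 0.2, 0.4, 0.6, 0.8, 1.0]
        rows = {
            "AAAAAAAA": good,
            "CCCCCCCC": good,
            "DDDDDDDD": good,
            "EEEEEEEE": good,
            "FFFFFFFF": good,
            "WWWWWWWW": bad,
        }
        prof = pd.DataFrame.from_dict(rows, orient="index", columns=datasets)
        sel = quant.rank_and_select_peptides(prof)
        assert "WWWWWWWW" not in sel.selected
        assert "WWWWWWWW" in sel.excluded_outliers

    def test_single_peptide_is_low_confidence(self):
        prof = pd.DataFrame({"d1": [1.0], "d2": [0.5]}, index=["AAAA"])
        sel = quant.rank_and_select_peptides(prof)
        assert sel.selected == ("AAAA",)
        assert sel.low_confidence

    def test_fraction_rule_arithmetic(self):
        """20 peptides at fraction 0.5 select exactly 10."""
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACDEFGHIKL"), 8)) for _ in range(20)]
        base = np.linspace(1.0, 0.1, 6)
        prof = pd.DataFrame(
            [base * (1 + 0.01 * i) for i in range(20)],
            index=seqs,
            columns=[f"d{i}" for i in range(6)],
        )
        prof = prof.div(prof.max(axis=1), axis=0)
        sel = quant.rank_and_select_peptides(prof, fraction=0.5)
        assert len(sel.selected) == 10

    def test_insufficient_shared_data_falls_back_to_all(self):
        prof = pd.DataFrame(
            {
                "d1": [1.0, np.nan],
                "d2": [np.nan, 1.0],
                "d3": [0.5, np.nan],
            },
            index=["AAAA", "CCCC"],
        )
        sel = quant.rank_and_select_peptides(prof)
        assert set(sel.selected) == {"AAAA", "CCCC"}
        assert sel.low_confidence


class TestProteinProfile:
    def test_median_of_two(self):
        prof = pd.DataFrame(
            {"d1": [1.0, 1.0], "d2": [0.4, 0.6]}, index=["AAAA", "CCCC"]
        )
        result = quant.protein_profile(prof)
        assert result.tolist() == [1.0, 0.5]

    def test_median_ignores_missing_per_dataset(self):
        prof = pd.DataFrame(
            {"d1": [1.0, np.nan, 0.2], "d2": [np.nan, np.nan, np.nan]},
            index=["AAAA", "CCCC", "DDDD"],
        )
        result = quant.protein_profile(prof)
        assert result["d1"] == pytest.approx(0.6)
        assert math.isnan(result["d2"])

    def test_noiseless_simulation_recovered_exactly(self):
        """Oracle: on noiseless data the protein profile equals the true
        relative abundance (true abundance over its maximum)."""
        model = sd.random_abundance_model(6, 7, seed=11)
        pv, truth = sd.simulate_apms(model, sd.NOISELESS, 5, seed=12)
        qr = quant.protein_profiles(pv)
        expected = truth.relative_profiles().loc[qr.profiles.index]
        assert np.allclose(
            qr.profiles.to_numpy(), expected.to_numpy(), atol=1e-12
        )

    def test_one_gross_outlier_among_six_is_absorbed(self):
        """Selection + median leave the profile unchanged when a single
        peptide is grossly distorted."""
        model = sd.random_abundance_model(4, 8, seed=21)
        pv, truth = sd.simulate_apms(model, sd.NOISELESS, 6, seed=22)
        clean = quant.protein_profiles(pv).profiles
        rng = np.random.default_rng(23)
        corrupted = pv.values.copy()
        for pid in model.true_abundance.index:
            seqs = truth.protein_of.index[truth.protein_of == pid]
            corrupted.loc[seqs[0]] *= np.exp(
                math.log(10) * rng.standard_normal(corrupted.shape[1])
            )
        pv2 = type(pv)(pv.peptides, corrupted, pv.datasets)
        dirty = quant.protein_profiles(pv2).profiles
        assert np.allclose(clean.to_numpy(), dirty.to_numpy(), atol=1e-9)


class TestCalibration:
    def test_single_point_fit(self):
        res = quant.calibrate_qconcat(
            pd.Series({"d1": 1.0, "d2": 0.5}), pd.Series({"d1": 10.0})
        )
        assert res.abundance.tolist() == [10.0, 5.0]

    def test_two_point_least_squares_matches_grid_search(self):
        """Closed form s = sum(p*c)/sum(p^2) = 9.6 for profile (1, 0.5)
        against anchors (10, 4); verified against a dense scan."""
        profile = pd.Series({"d1": 1.0, "d2": 0.5})
        cal = pd.Series({"d1": 10.0, "d2": 4.0})
        res = quant.calibrate_qconcat(profile, cal)
        assert res.scale == pytest.approx(9.6)
        grid = np.linspace(0, 20, 200001)
        sse = [((s * profile - cal) ** 2).sum() for s in grid]
        assert grid[int(np.argmin(sse))] == pytest.approx(9.6, abs=1e-3)
        assert res.abundance.tolist() == pytest.approx([9.6, 4.8])

    def test_all_zero_anchors_give_zero_abundance(self):
        res = quant.calibrate_qconcat(
            pd.Series({"d1": 1.0, "d2": 0.5}), pd.Series({"d1": 0.0, "d2": 0.0})
        )
        assert res.abundance.tolist() == [0.0, 0.0]

    def test_no_overlap_flags_uncalibrated(self):
        res = quant.calibrate_qconcat(
            pd.Series({"d1": 1.0}), pd.Series({"d9": 5.0})
        )
        assert not res.calibrated


class TestAbundanceSpec:
    def test_summed_pv_per_accessible_residue(self):
        pv = make_pv({"P1": {"AAAA": [100.0], "CCCC": [300.0]}}, ["d1"])
        out = quant.abundance_spec(pv, {"P1": 40})
        assert out.loc["P1", "d1"] == pytest.approx(10.0)

    def test_linear_in_total_signal(self):
        pv = make_pv({"P1": {"AAAA": [100.0], "CCCC": [300.0]}}, ["d1"])
        pv2 = make_pv({"P1": {"AAAA": [200.0], "CCCC": [600.0]}}, ["d1"])
        a = quant.abundance_spec(pv, {"P1": 40})
        b = quant.abundance_spec(pv2, {"P1": 40})
        assert (b / a).loc["P1", "d1"] == pytest.approx(2.0)

    def test_rank_order_recovered_under_noise(self):
        """Spearman rank of abundance_spec vs truth > 0.9 at CV 0.2."""
        from scipy.stats import spearmanr

        model = sd.random_abundance_model(15, 1, seed=31)
        pv, truth = sd.simulate_apms(
            model, sd.NoiseModel(cv=0.2, sigma_response=0.3), 5, seed=32
        )
        est = quant.abundance_spec(
            pv, {p: 50 for p in model.true_abundance.index}
        )
        rho = spearmanr(
            est.iloc[:, 0], truth.true_abundance.loc[est.index].iloc[:, 0]
        ).statistic
        assert rho > 0.9


class TestNormalizeToTarget:
    def test_target_column_is_identically_one(self):
        ab = pd.DataFrame(
            {"AP_1": [8.0, 2.0], "AP_2": [4.0, 1.0]}, index=["GluA1", "PREY"]
        )
        meta = [
            DatasetMeta("AP_1", frozenset({"GluA1"})),
            DatasetMeta("AP_2", frozenset({"GluA1"})),
        ]
        norm, _ = quant.normalize_to_target(ab, meta)
        assert norm.loc["GluA1"].tolist() == [1.0, 1.0]
        assert norm.loc["PREY", "AP_1"] == pytest.approx(0.25)

    def test_ampar_amount_is_sum_over_four(self):
        ab = pd.DataFrame(
            {"AP_1": [4.0, 4.0, 2.0, 2.0]},
            index=["GluA1", "GluA2", "GluA3", "GluA4"],
        )
        assert quant.ampar_amount(ab)["AP_1"] == pytest.approx(3.0)

    def test_zero_target_dataset_excluded(self, caplog):
        ab = pd.DataFrame(
            {"AP_1": [0.0, 2.0], "AP_2": [4.0, 1.0]}, index=["GluA1", "PREY"]
        )
        meta = [
            DatasetMeta("AP_1", frozenset({"GluA1"})),
            DatasetMeta("AP_2", frozenset({"GluA1"})),
        ]
        with caplog.at_level("WARNING", logger="apms"):
            norm, _ = quant.normalize_to_target(ab, meta)
        assert list(norm.columns) == ["AP_2"]
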
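import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from apms import interactomics as ia
from apms import quant
from apms import synthdata as sd
from apms.io_model import ValidationError


def _ab(rows, cols):
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


class TestComputeRPV:
    def test_simple_ratio_and_null_case(self):
        ab = _ab({"P1": [2.0, 1.0], "P2": [3.0, 3.0]}, ["a1", "b1"])
        out = ia.compute_rpv(ab, ["a1"], ["b1"])
        assert out.loc["P1", "rpv"] == pytest.approx(2.0)
        assert out.loc["P2", "rpv"] == pytest.approx(1.0)

    def test_mean_of_per_replicate_ratios_with_sem(self):
        ab = _ab({"P1": [2.0, 4.0, 1.0, 1.0]}, ["a1", "a2", "b1", "b2"])
        out = ia.compute_rpv(ab, ["a1", "a2"], ["b1", "b2"])
        assert out.loc["P1", "rpv"] == pytest.approx(3.0)
        # ratios 2 and 4 -> sd sqrt(2), sem 1
        assert out.loc["P1", "sem"] == pytest.approx(1.0)

    def test_undetected_in_control_imputed_at_half_minimum(self):
        ab = _ab(
            {"P1": [10.0, np.nan], "P2": [1.0, 4.0]}, ["a1", "b1"]
        )
        out = ia.compute_rpv(ab, ["a1"], ["b1"])
        # floor in b1 = 0.5 * 4 = 2 -> rPV = 10 / 2 = 5
        assert out.loc["P1", "rpv"] == pytest.approx(5.0)
        assert out.loc["P1", "n_imputed"] == 1

    def test_protein_absent_everywhere_excluded(self):
        ab = _ab({"P1": [np.nan, np.nan], "P2": [1.0, 1.0]}, ["a1", "b1"])
        out = ia.compute_rpv(ab, ["a1"], ["b1"])
        assert "P1" not in out.index

    def test_threefold_enrichment_recovered(self):
        """Simulated 3x enrichment, CV 0.15, 4 replicates: mean rPV within
        [2.5, 3.6] over seeds."""
        rng_means = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            a = 3.0 * np.exp(0.15 * rng.standard_normal(4))
            b = 1.0 * np.exp(0.15 * rng.standard_normal(4))
            ab = _ab(
                {"P1": list(a) + list(b)},
                [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)],
            )
            out = ia.compute_rpv(
                ab, [f"a{i}" for i in range(4)], [f"b{i}" for i in range(4)]
            )
            rng_means.append(out.loc["P1", "rpv"])
        assert 2.5 <= float(np.mean(rng_means)) <= 3.6


class TestEstimateThreshold:
    def test_needs_twenty_proteins(self):
        with pytest.raises(ValidationError, match="manual threshold"):
            ia.estimate_threshold(np.ones(10))

    def test_degenerate_identical_rpvs(self, caplog):
        with caplog.at_level("WARNING", logger="apms"):
            thr = ia.estimate_threshold(np.ones(50))
        assert thr == pytest.approx(1.0)

    def test_lognormal_background_matches_analytic_quantile(self):
        """Background log-normal(0, 0.2^2): threshold ~ exp(3 * 0.2)."""
        thresholds = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            rpvs = np.exp(0.2 * rng.standard_normal(400))
            thresholds.append(ia.estimate_threshold(rpvs))
        mean = float(np.mean(thresholds))
        assert 1.6 <= mean <= 2.1

    def test_enriched_minority_all_pass_background_threshold(self):
        """95% background + 5% enriched at 50x: the threshold stays at the
        background mode and every enriched protein passes (checked
        against the explicitly constructed pass set)."""
        rng = np.random.default_rng(7)
        background = np.exp(0.2 * rng.standard_normal(380))
        enriched = 50.0 * np.exp(0.2 * rng.standard_normal(20))
        rpvs = np.concatenate([background, enriched])
        thr = ia.estimate_threshold(rpvs)
        assert thr < 5.0
        assert (enriched > thr).all()

    def test_high_rpv_tail_does_not_lower_threshold(self):
        """Adding truly enriched proteins to a realistic background never
        lowers the background-mode threshold (robust estimator)."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            background = np.exp(0.25 * rng.standard_normal(300))
            base = ia.estimate_threshold(background)
            extended = np.concatenate(
                [background, 40.0 * np.exp(0.2 * rng.standard_normal(15))]
            )
            assert ia.estimate_threshold(extended) >= base * 0.999


class TestCallSpecific:
    def _comparison(self, name, antibody, kind, values):
        rpv = pd.DataFrame({"rpv": pd.Series(values)})
        rpv.index.name = "protein_id"
        return ia.Comparison(name, antibody, kind, rpv, threshold=2.0)

    def test_two_antibodies_plus_depletion_required(self):
        comps = [
            self._comparison("ab1_igg", "AB1", "igg", {"P1": 5.0, "P2": 5.0}),
            self._comparison("ab2_igg", "AB2", "igg", {"P1": 5.0, "P2": 1.0}),
            self._comparison("ab1_depl", "AB1", "depletion", {"P1": 5.0, "P2": 5.0}),
        ]
        calls = ia.call_specific(comps)
        assert bool(calls.loc["P1", "is_specific"])
        assert not bool(calls.loc["P2", "is_specific"])  # only one antibody

    def test_failing_depletion_control_vetoes(self):
        comps = [
            self._comparison("ab1_igg", "AB1", "igg", {"P1": 5.0}),
            self._comparison("ab2_igg", "AB2", "igg", {"P1": 5.0}),
            self._comparison("ab1_depl", "AB1", "depletion", {"P1": 1.0}),
        ]
        calls = ia.call_specific(comps)
        assert not bool(calls.loc["P1", "is_specific"])


class TestFractionFirst:
    @pytest.mark.parametrize(
        "rpv,expected", [(1.0, 0.5), (0.0, 0.0), (3.0, 0.75), (math.inf, 1.0)]
    )
    def test_closed_forms(self, rpv, expected):
        assert ia.fraction_first(rpv) == pytest.approx(expected)

    def test_negative_rpv_rejected(self):
        with pytest.raises(ValidationError):
            ia.fraction_first(-0.5)

    @settings(max_examples=50, deadline=None)
    @given(x=st.floats(min_value=1e-6, max_value=1e6, allow_nan=False))
    def test_reciprocal_symmetry(self, x):
        """F(1/x) = 1 - F(x): swapping the two APs flips the fraction."""
        assert ia.fraction_first(1.0 / x) == pytest.approx(
            1.0 - ia.fraction_first(x), abs=1e-12
        )


class TestTwostepPartition:
    def test_fraction_from_abundances(self):
        ab = _ab({"P1": [0.2, 0.8]}, ["first_1", "second_1"])
        out = ia.twostep_partition(ab, ["first_1"], ["second_1"])
        assert out.loc["P1", "fraction_first"] == pytest.approx(0.2)
        assert out.loc["P1", "fraction_second"] == pytest.approx(0.8)

    def test_partition_conserves_unity_exactly(self):
        rng = np.random.default_rng(3)
        ab = _ab(
            {f"P{i}": list(rng.random(4) + 0.1) for i in range(10)},
            ["first_1", "first_2", "second_1", "second_2"],
        )
        out = ia.twostep_partition(
            ab, ["first_1", "first_2"], ["second_1", "second_2"]
        )
        assert np.allclose(
            out["fraction_first"] + out["fraction_second"], 1.0, atol=0
        )

    def test_missing_in_second_ap_is_boundary_f_of_one(self):
        ab = _ab({"P1": [0.5, np.nan]}, ["first_1", "second_1"])
        out = ia.twostep_partition(ab, ["first_1"], ["second_1"])
        assert out.loc["P1", "fraction_first"] == 1.0
        assert bool(out.loc["P1", "boundary_imputed"])

    def test_recovery_of_simulated_fraction(self):
        """simulate_twostep truth F = 0.175, 3 replicates, CV 0.15:
        recovered mean F lands in [0.125, 0.225]."""
        recovered = []
        for seed in range(20):
            pv, truth, firsts, seconds = sd.simulate_twostep(
                {f"P{i}": 100.0 for i in range(5)},
                {f"P{i}": 0.175 for i in range(5)},
                sd.NoiseModel(cv=0.15),
                seed=seed,
            )
            profiles = quant.protein_profiles(pv).profiles
            out = ia.twostep_partition(profiles, firsts, seconds)
            recovered.append(out["fraction_first"].mean())
        assert 0.125 <= float(np.mean(recovered)) <= 0.225


class TestCompareGroups:
    def test_identical_groups_ratio_one_p_one(self):
        ab = _ab({"P1": [2.0, 2.0, 2.0, 2.0]}, ["a1", "a2", "b1", "b2"])
        out = ia.compare_groups(ab, ["a1", "a2"], ["b1", "b2"])
        assert out.loc["P1", "ratio"] == pytest.approx(1.0)
        assert out.loc["P1", "p_value"] == pytest.approx(1.0)

    def test_zero_reference_mean_flagged_infinite(self):
        ab = _ab({"P1": [2.0, 2.0, 0.0, 0.0]}, ["a1", "a2", "b1", "b2"])
        out = ia.compare_groups(ab, ["a1", "a2"], ["b1", "b2"])
        assert bool(out.loc["P1", "ratio_infinite"])
        assert math.isnan(out.loc["P1", "p_value"])

    def test_single_replicate_gives_ratio_without_p(self):
        ab = _ab({"P1": [2.0, 1.0]}, ["a1", "b1"])
        out = ia.compare_groups(ab, ["a1"], ["b1"])
        assert out.loc["P1", "ratio"] == pytest.approx(2.0)
        assert math.isnan(out.loc["P1", "p_value"])

    def test_stars_follow_p_value_bands(self):
        assert ia.significance_stars(0.5) == ""
        assert ia.significance_stars(0.005) == "**"
        assert ia.significance_stars(0.0005) == "***"


class TestCrossDatasetCorrelation:
    def test_identical_and_anticorrelated_vectors(self):
        ab = _ab(
            {
                "FOCAL": [1.0, 2.0, 3.0, 4.0],
                "SAME": [1.0, 2.0, 3.0, 4.0],
                "ANTI": [4.0, 3.0, 2.0, 1.0],
            },
            ["d1", "d2", "d3", "d4"],
        )
        out = ia.cross_dataset_correlation(
            ab, "FOCAL", {"core": ["SAME", "ANTI"]}
        )
        assert out.loc["SAME", "r"] == pytest.approx(1.0)
        assert out.loc["ANTI", "r"] == pytest.approx(-1.0)

    def test_zero_variance_vector_flagged(self):
        ab = _ab(
            {"FOCAL": [1.0, 2.0, 3.0, 4.0], "FLAT": [5.0, 5.0, 5.0, 5.0]},
            ["d1", "d2", "d3", "d4"],
        )
        out = ia.cross_dataset_correlation(ab, "FOCAL", {"s": ["FLAT"]})
        assert bool(out.loc["FLAT", "undefined"])

    def test_sum_of_independent_drivers_beats_each_member(self):
        """When the focal protein tracks the sum of independent core
        subunits, r(focal, sum) exceeds every individual r in most
        seeds."""
        wins = 0
        n_seeds = 30
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            cols = [f"d{i}" for i in range(12)]
            core = {f"CORE{j}": rng.random(12) + 0.2 for j in range(3)}
            total = np.sum(list(core.values()), axis=0)
            focal = total * np.exp(0.1 * rng.standard_normal(12))
            ab = _ab({"FOCAL": list(focal), **{k: list(v) for k, v in core.items()}}, cols)
            out = ia.cross_dataset_correlation(
                ab, "FOCAL", {"core": list(core)}
            )
            r_sum = out.loc["sum(core)", "r"]
            r_each = out.loc[list(core), "r"].max()
            wins += int(r_sum > r_each)
        assert wins / n_seeds >= 0.9
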
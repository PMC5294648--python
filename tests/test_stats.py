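import itertools
import math

import numpy as np
import pytest
from scipy import optimize, stats as sps

from bgfilt.core_network import SubjectData, TrialPowerTable
from bgfilt.filtration import BettiCurve
from bgfilt.stats import (
    BehavioralRecord,
    barcode_condition_permutation,
    behavior_correlation,
    bonferroni,
    diff_max,
    dprime,
    group_permutation,
    network_type_contrast,
    slm_condition_permutation,
    slm_paired_t,
    subject_slm_difference,
)
from bgfilt.synthetic import PlantedPair, SimulationConfig, generate_cohort, null_cohort


def curve(breakpoints, size, partition="cue_alpha"):
    return BettiCurve(partition=partition, size=size, breakpoints=np.asarray(breakpoints))


class TestDiffMax:
    def test_identical_curves(self):
        a = curve([0.2, 0.5], 3)
        assert diff_max(a, curve([0.2, 0.5], 3)).value == 0.0

    def test_two_step_curves_dense_grid_oracle(self):
        # A: 3 on [0,0.5), 1 after; B: 3 on [0,0.3), 2 on [0.3,0.7), 1 after
        a = curve([0.5, 0.5], 3)
        b = curve([0.3, 0.7], 3)
        dm = diff_max(a, b)
        assert dm.value == 1.0
        assert dm.epsilon_at_max == pytest.approx(0.3)
        # independent dense-grid evaluation
        grid = np.linspace(0, 1, 100001, endpoint=False)
        d = a.value(grid) - b.value(grid)
        k = int(np.argmax(np.abs(d)))
        assert dm.value == d[k]
        assert abs(dm.epsilon_at_max - grid[k]) <= 1e-5

    @pytest.mark.parametrize("seed", range(10))
    def test_random_curves_against_dense_grid(self, seed):
        rng = np.random.default_rng(seed)
        p = 6
        a = curve(np.sort(rng.random(rng.integers(0, p))) * 0.99, p)
        b = curve(np.sort(rng.random(rng.integers(0, p))) * 0.99, p)
        dm = diff_max(a, b)
        grid = np.linspace(0, 1, 200001, endpoint=False)
        d = a.value(grid) - b.value(grid)
        assert abs(dm.value) == np.max(np.abs(d))
        assert dm.value == d[int(np.argmax(np.abs(d)))]

    def test_antisymmetry(self):
        a = curve([0.1, 0.4], 3)
        b = curve([0.2], 3)
        assert diff_max(a, b).value == -diff_max(b, a).value

    def test_size_mismatch_raises(self):
        with pytest.raises(ValueError, match="equal size"):
            diff_max(curve([], 3), curve([], 4))


class TestNetworkTypeContrast:
    def test_six_same_sign_exact_p(self):
        # oracle: enumerate all 2^6 sign patterns of ranks 1..6
        values = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        _, p = network_type_contrast(values)
        ranks = np.arange(1, 7)
        w_obs = 0.0  # all positive: min(W+, W-) = 0
        count = 0
        for signs in itertools.product([1, -1], repeat=6):
            w_plus = sum(r for r, s in zip(ranks, signs) if s > 0)
            w_minus = sum(r for r, s in zip(ranks, signs) if s < 0)
            if min(w_plus, w_minus) <= w_obs:
                count += 1
        assert p == pytest.approx(count / 64)
        assert p == pytest.approx(0.03125)

    def test_symmetric_values_large_p(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal(12)
        v = np.concatenate([v, -v])  # exactly symmetric about 0
        _, p = network_type_contrast(v)
        assert p > 0.5

    def test_all_zero_convention(self):
        assert network_type_contrast([0.0] * 6) == (0.0, 1.0)

    def test_too_few_subjects(self):
        with pytest.raises(ValueError, match="n >= 5"):
            network_type_contrast([1.0] * 4)


class TestDprime:
    def test_equal_rates_zero(self):
        assert dprime(30, 100, 30, 100) == pytest.approx(0.0)

    def test_reference_rates_against_quantile_oracle(self):
        # independent quantile oracle: invert the normal CDF by root finding
        def z(q):
            return optimize.brentq(lambda x: sps.norm.cdf(x) - q, -10, 10, xtol=1e-12)

        expected = z(0.57) - z(0.24)
        assert dprime(57, 100, 24, 100) == pytest.approx(expected, abs=1e-9)

    def test_extreme_rate_guard(self):
        n = 50
        guarded = dprime(n, n, 10, n)
        expected = sps.norm.ppf(1 - 1 / (2 * n)) - sps.norm.ppf(10 / n)
        assert guarded == pytest.approx(expected)
        assert math.isfinite(dprime(0, n, n, n))

    @pytest.mark.parametrize("h1,h2", [(40, 41), (80, 81)])
    def test_strictly_increasing_in_hits(self, h1, h2):
        assert dprime(h2, 100, 20, 100) > dprime(h1, 100, 20, 100)

    def test_strictly_decreasing_in_fa(self):
        assert dprime(60, 100, 30, 100) < dprime(60, 100, 20, 100)


class TestBehavioralRecord:
    def test_performer_group_threshold(self):
        good = BehavioralRecord("s1", 160, 200, 60, 200, 30, 200)
        assert good.memory_performance > 1.0
        assert good.performer_group == "good"
        poor = BehavioralRecord("s2", 90, 200, 60, 200, 70, 200)
        assert poor.memory_performance < 1.0
        assert poor.performer_group == "poor"

    def test_count_validation(self):
        with pytest.raises(ValueError):
            BehavioralRecord("s", 300, 200, 0, 200, 0, 200)


class TestBehaviorCorrelation:
    def test_bonferroni_seven_tests(self):
        assert bonferroni(0.004, 7) == pytest.approx(0.028)
        assert bonferroni(0.04, 7) == pytest.approx(0.28)
        assert bonferroni(0.2, 7) == 1.0

    def test_full_pipeline_values(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(10)
        y = -x + 0.3 * rng.standard_normal(10)
        r, p, pb = behavior_correlation(x, y, 7)
        assert r < -0.8
        assert pb == min(1.0, p * 7)
        # p from the t distribution with n - 2 dof
        t = r * math.sqrt(8 / (1 - r * r))
        assert p == pytest.approx(2 * sps.t.sf(abs(t), 8), rel=1e-9)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="zero-variance"):
            behavior_correlation([1.0] * 5, [1, 2, 3, 4, 5], 1)


# ---------------------------------------------------------------------------
# permutation engines
# ---------------------------------------------------------------------------

def tiny_cohort(seed=0, n_subjects=5, n_rois=5, trials=(20, 18), pairs=()):
    cfg = SimulationConfig(n_subjects=n_subjects, n_rois=n_rois,
                           trials_per_condition=trials, planted_pairs=pairs,
                           seed=seed)
    return generate_cohort(cfg)


def identical_condition_cohort(seed=0, n_subjects=4):
    """R and NR tables byte-identical per subject."""
    rng = np.random.default_rng(seed)
    labels = tuple(f"roi{k}.L" for k in range(4))
    subjects = []
    for s in range(n_subjects):
        cue = 1 + 0.1 * rng.standard_normal((12, 4))
        item = 1 + 0.1 * rng.standard_normal((12, 4))
        tables = {}
        for cond in ("R", "NR"):
            tables[(cond, "cue_alpha")] = TrialPowerTable(f"s{s}", cond, "cue_alpha", labels, cue)
            tables[(cond, "item_gamma")] = TrialPowerTable(f"s{s}", cond, "item_gamma", labels, item)
        subjects.append(SubjectData(subject_id=f"s{s}", tables=tables))
    return subjects


class TestBarcodePermutation:
    def test_reproducible_under_seed(self):
        cohort = tiny_cohort().subjects
        a = barcode_condition_permutation(cohort, "item_gamma", n_perm=30, seed=5)
        b = barcode_condition_permutation(cohort, "item_gamma", n_perm=30, seed=5)
        assert a.p_value == b.p_value
        np.testing.assert_array_equal(a.null_stats, b.null_stats)
        assert len(a.null_stats) == 30

    def test_identical_conditions_p_one(self):
        res = barcode_condition_permutation(identical_condition_cohort(), "cue_alpha",
                                            n_perm=20, seed=0)
        assert res.observed_stat == 0.0
        assert res.p_value == 1.0

    def test_p_floor(self):
        cohort = tiny_cohort(seed=3).subjects
        res = barcode_condition_permutation(cohort, "cue_alpha", n_perm=19, seed=1)
        assert res.p_value >= 1 / 20

    def test_planted_effect_detected(self):
        # pairs sharing a cue ROI connect item-partition nodes early under R,
        # shifting the item Betti curve
        pairs = (PlantedPair("Precentral.L", "Frontal_Sup.L", -0.85, 0.0),
                 PlantedPair("Precentral.L", "Frontal_Mid.L", -0.85, 0.0),
                 PlantedPair("Precentral.R", "Frontal_Sup.R", -0.85, 0.0),
                 PlantedPair("Precentral.R", "Frontal_Mid.R", -0.85, 0.0))
        cohort = tiny_cohort(seed=11, n_subjects=10, n_rois=8, trials=(60, 60),
                             pairs=pairs)
        res = barcode_condition_permutation(cohort.subjects, "item_gamma",
                                            n_perm=100, seed=2)
        assert res.observed_stat < 0  # earlier item merges under R
        assert res.p_value <= 0.05

    def test_unknown_partition_raises(self):
        with pytest.raises(ValueError, match="partition"):
            barcode_condition_permutation(tiny_cohort().subjects, "beta", n_perm=5, seed=0)

    def test_too_few_subjects_raises(self):
        cohort = tiny_cohort(n_subjects=2).subjects
        with pytest.raises(ValueError, match="3 subjects"):
            barcode_condition_permutation(cohort, "cue_alpha", n_perm=5, seed=0)


class TestSlmPermutation:
    def test_identical_conditions_no_flags(self):
        res = slm_condition_permutation(identical_condition_cohort(), n_perm=20,
                                        alpha=0.05, seed=0)
        assert (res.observed_t == 0.0).all()
        assert (res.p == 1.0).all()
        assert res.flagged == []

    def test_reproducible_and_p_floor(self):
        cohort = tiny_cohort(seed=7).subjects
        a = slm_condition_permutation(cohort, n_perm=25, alpha=0.05, seed=9)
        b = slm_condition_permutation(cohort, n_perm=25, alpha=0.05, seed=9)
        np.testing.assert_array_equal(a.p, b.p)
        assert (a.p >= 1 / 26).all()

    def test_planted_pair_flagged_with_sign(self):
        pair = PlantedPair("Precentral.L", "Frontal_Sup.L", -0.85, -0.05)
        cohort = tiny_cohort(seed=13, n_subjects=12, n_rois=6, trials=(80, 80),
                             pairs=(pair,))
        res = slm_condition_permutation(cohort.subjects, n_perm=200, alpha=0.01,
                                        seed=3)
        hits = [(f.cue_roi, f.item_roi, f.sign) for f in res.flagged]
        assert ("Precentral.L", "Frontal_Sup.L", "R < NR") in hits

    def test_observed_matches_standalone_paired_t(self):
        cohort = tiny_cohort(seed=21).subjects
        res = slm_condition_permutation(cohort, n_perm=5, seed=17)
        t, diffs = slm_paired_t(cohort, seed=17)
        np.testing.assert_array_equal(res.observed_t, t)
        np.testing.assert_array_equal(res.subject_diffs, diffs)


class TestGroupPermutation:
    def test_identical_groups_p_one(self):
        rng = np.random.default_rng(0)
        block = rng.random((3, 4, 4))
        diffs = np.concatenate([block, block])  # same subjects duplicated
        groups = ["good"] * 3 + ["poor"] * 3
        res = group_permutation(diffs, groups, [f"r{k}" for k in range(4)],
                                [f"c{k}" for k in range(4)], n_perm=50, seed=1)
        assert (res.mean_diff == 0.0).all()
        assert (res.p == 1.0).all()
        assert res.flagged == []

    def test_planted_interaction_recovered(self):
        rng = np.random.default_rng(5)
        diffs = 0.05 * rng.standard_normal((14, 5, 5))
        diffs[:7, 2, 3] -= 0.6  # strong good-group effect at one pair
        groups = ["good"] * 7 + ["poor"] * 7
        res = group_permutation(diffs, groups, [f"r{k}" for k in range(5)],
                                [f"c{k}" for k in range(5)], n_perm=400,
                                alpha=0.01, seed=2)
        assert any(f.cue_roi == "r2" and f.item_roi == "c3" and f.sign == "good < poor"
                   for f in res.flagged)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError, match="non-empty"):
            group_permutation(np.zeros((3, 2, 2)), ["good"] * 3, ["a", "b"],
                              ["a", "b"], n_perm=5, seed=0)

    def test_reproducible(self):
        rng = np.random.default_rng(9)
        diffs = rng.standard_normal((8, 3, 3))
        groups = ["good"] * 4 + ["poor"] * 4
        kw = dict(n_perm=60, seed=4)
        a = group_permutation(diffs, groups, "abc", "abc", **kw)
        b = group_permutation(diffs, groups, "abc", "abc", **kw)
        np.testing.assert_array_equal(a.p, b.p)


class TestCalibrationSmoke:
    """Scaled-down null-calibration sanity; the full battery lives in the
    acceptance suite."""

    def test_null_p_values_roughly_uniform(self):
        cfg = SimulationConfig(n_subjects=6, n_rois=6, trials_per_condition=(20, 20),
                               seed=0)
        ps = []
        for c in range(40):
            cohort = null_cohort(SimulationConfig(
                n_subjects=6, n_rois=6, trials_per_condition=(20, 20), seed=c))
            res = barcode_condition_permutation(cohort.subjects, "item_gamma",
                                                n_perm=60, seed=5000 + c)
            ps.append(res.p_value)
        ps = np.asarray(ps)
        # no pile-up at either tail
        assert 0.02 <= np.mean(ps < 0.5) <= 0.8
        assert np.mean(ps <= 0.1) <= 0.35
        ks = sps.kstest(ps, "uniform")
        assert ks.pvalue > 0.005
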
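"""Evaluation harness: folds, statistics oracles, ERP contrasts, end-to-end run."""

import itertools

import numpy as np
import pytest

from hbci.evaluate import (
    compare_methods,
    distribution_contrast,
    erp_contrast,
    estimate_cv_weights,
    latency_to_sample,
    make_folds,
    moving_average_error,
    run_pipeline_cv,
)
from hbci.exceptions import InputError

from conftest import STUDY_METHODS


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------

class TestMakeFolds:
    def test_320_trials_gives_288_32_splits(self):
        folds = make_folds(320, 10, seed=0)
        assert len(folds) == 10
        for f in folds:
            assert f.train_indices.size == 288
            assert f.test_indices.size == 32

    def test_partition_property(self):
        folds = make_folds(97, 10, seed=1)
        test_union = np.concatenate([f.test_indices for f in folds])
        assert np.array_equal(np.sort(test_union), np.arange(97))
        for f in folds:
            assert np.intersect1d(f.train_indices, f.test_indices).size == 0

    def test_leave_one_out(self):
        folds = make_folds(10, 10, seed=2)
        assert all(f.test_indices.size == 1 for f in folds)

    def test_stratified_folds_keep_target_prevalence(self):
        is_target = np.zeros(320, dtype=bool)
        is_target[:80] = True
        folds = make_folds(320, 10, seed=3, stratify_by=is_target)
        for f in folds:
            assert is_target[f.test_indices].sum() == 8  # 25% of 32

    def test_too_many_folds_raises(self):
        with pytest.raises(InputError):
            make_folds(5, 10)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def _exact_signed_rank_p(diffs):
    """Enumerate all sign assignments of the ranked |differences| (one-sided:
    alternative 'first sample smaller', i.e. negative differences)."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = np.empty(d.size)
    order = np.argsort(np.abs(d), kind="stable")
    # midranks for ties in |d|
    abs_sorted = np.abs(d)[order]
    r = np.arange(1, d.size + 1, dtype=float)
    for v in np.unique(abs_sorted):
        mask = abs_sorted == v
        r[mask] = r[mask].mean()
    ranks[order] = r
    w_pos = ranks[d > 0].sum()
    count = 0
    total = 0
    for signs in itertools.product([0, 1], repeat=d.size):
        w = sum(rk for rk, s in zip(ranks, signs) if s)
        total += 1
        if w <= w_pos:
            count += 1
    return count / total


class TestCompareMethods:
    def test_identical_vectors_give_p_one(self):
        res = compare_methods([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert res.pvalue == 1.0

    def test_n5_matches_published_table(self):
        # five pairs, a strictly below b: one-sided exact p = 1/32
        a = [0.1, 0.2, 0.3, 0.4, 0.5]
        b = [0.2, 0.3, 0.4, 0.5, 0.6]
        res = compare_methods(a, b, sided="one")
        assert res.pvalue == pytest.approx(1 / 32)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_exact_enumeration_small_n(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random(8)
        b = rng.random(8)
        res = compare_methods(a, b, sided="one")
        assert res.pvalue == pytest.approx(_exact_signed_rank_p(a - b), abs=1e-12)

    def test_strict_dominance_45_pairs(self):
        rng = np.random.default_rng(4)
        b = rng.random(45) + 1.0
        a = b - rng.uniform(0.5, 1.0, 45)
        res = compare_methods(a, b, sided="one")
        assert res.pvalue < 1e-8  # approximation regime; overwhelming evidence

    def test_two_sided_symmetry(self):
        rng = np.random.default_rng(5)
        a, b = rng.random(12), rng.random(12)
        ab = compare_methods(a, b, sided="two").pvalue
        ba = compare_methods(b, a, sided="two").pvalue
        assert ab == pytest.approx(ba)


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

class TestDistributionContrast:
    def test_identical_samples(self):
        res = distribution_contrast([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_separated_normals(self, rng):
        res = distribution_contrast(rng.normal(0, 1, 100), rng.normal(3, 1, 100))
        assert res.pvalue < 1e-10

    def test_tie_corrected_hand_example(self):
        # c = [1,1,2], i = [2,3,3]: midranks 1.5,1.5,3.5 | 3.5,5.5,5.5
        # H_uncorr = 12/(6*7) * (6.5^2/3 + 14.5^2/3) - 3*7 = 64/21
        # ties: three pairs -> correction 1 - 18/210; H = (64/21)/(32/35) = 10/3
        res = distribution_contrast([1.0, 1.0, 2.0], [2.0, 3.0, 3.0])
        assert res.statistic == pytest.approx(10.0 / 3.0, abs=1e-12)

    def test_empty_set_raises(self):
        with pytest.raises(InputError):
            distribution_contrast([], [1.0])


# ---------------------------------------------------------------------------
# ERP contrast
# ---------------------------------------------------------------------------

class TestErpContrast:
    def test_identical_sets(self, rng):
        ep = rng.standard_normal((10, 3, 48))
        res = erp_contrast(ep, ep.copy())
        assert np.allclose(res.grand_average_correct, res.grand_average_incorrect)
        assert np.all(res.pvalue == 1.0)

    def test_constant_epochs_average(self):
        c = np.full((5, 2, 48), 4.2)
        i = np.full((6, 2, 48), 4.2)
        res = erp_contrast(c, i)
        assert np.allclose(res.grand_average_correct, 4.2)
        assert np.all(res.pvalue == 1.0)

    def test_detects_attenuated_incorrect_erp(self, study_run, cohort):
        """With 0.5 attenuation on incorrect trials the contrast is
        significant near the injected template peak on an ERP channel."""
        es = study_run.epoch_sets[0]
        correct = study_run.correct[0]
        cz = es.channel_names.index("Cz")
        res = erp_contrast(es.stimulus[correct], es.stimulus[~correct],
                           channel_names=es.channel_names)
        peak = latency_to_sample(350.0, "stimulus")
        window = res.pvalue[cz, peak - 2 : peak + 3]
        assert window.min() < 0.05

    def test_mismatched_channels_raise(self, rng):
        with pytest.raises(InputError):
            erp_contrast(rng.standard_normal((4, 3, 48)), rng.standard_normal((4, 2, 48)))


class TestLatencyMap:
    @pytest.mark.parametrize(
        "ms,lock,idx",
        [
            (0.0, "stimulus", 0),
            (600.0, "stimulus", 19),
            (900.0, "stimulus", 28),
            (-200.0, "response", 25),
            (200.0, "response", 38),
        ],
    )
    def test_named_latencies(self, ms, lock, idx):
        assert latency_to_sample(ms, lock) == idx

    def test_out_of_range_raises(self):
        with pytest.raises(InputError):
            latency_to_sample(1600.0, "stimulus")


# ---------------------------------------------------------------------------
# Moving-average dynamics
# ---------------------------------------------------------------------------

class TestMovingAverage:
    def test_constant_input_flat(self):
        res = moving_average_error(np.full(100, 0.3), window=40)
        assert np.allclose(res.series, 0.3)
        assert res.slope == 0.0

    def test_full_window_single_point(self):
        flags = np.array([1, 0, 0, 1, 0], dtype=float)
        res = moving_average_error(flags, window=5)
        assert res.series.shape == (1,)
        assert res.series[0] == pytest.approx(0.4)

    def test_alternating_window_two(self):
        res = moving_average_error(np.resize([0.0, 1.0], 50), window=2)
        assert np.allclose(res.series, 0.5)

    def test_window_too_large_raises(self):
        with pytest.raises(InputError):
            moving_average_error(np.zeros(10), window=11)

    def test_improving_observers_show_declining_tie_rate(self):
        """Off-line pairs of improving observers disagree less over time:
        the fitted slope of the smoothed tie rate is negative."""
        rng = np.random.default_rng(8)
        n = 320
        err = np.linspace(0.45, 0.05, n)
        slopes = []
        for _ in range(5):
            d1 = np.where(rng.random(n) < err, -1, 1)
            d2 = np.where(rng.random(n) < err, -1, 1)
            ties = (d1 != d2).astype(float)
            slopes.append(moving_average_error(ties, window=40).slope)
        assert np.mean(slopes) < 0
        assert sum(s < 0 for s in slopes) >= 4


# ---------------------------------------------------------------------------
# End-to-end cross-validated run
# ---------------------------------------------------------------------------

class TestRunPipeline:
    def test_table_contains_all_methods_and_sizes(self, study_run):
        t = study_run.table
        assert set(t["method"]) == set(STUDY_METHODS)
        for m in STUDY_METHODS:
            counts = t[t["method"] == m].groupby("size").size()
            assert counts[1] == 10 and counts[2] == 45
            assert counts[3] == 120 and counts[4] == 210
        assert t["error_rate"].between(0, 1).all()

    def test_cross_fold_conservation(self, study_run):
        test_union = np.concatenate([f.test_indices for f in study_run.folds])
        assert np.array_equal(np.sort(test_union), np.arange(320))

    def test_unit_weights_reduce_to_majority_table(self, study_run):
        from hbci.groups import enumerate_groups, evaluate_group_method

        groups = enumerate_groups(10, 2)
        ones = np.ones_like(study_run.decisions, dtype=float)
        a = evaluate_group_method(groups, study_run.decisions, ones,
                                  study_run.truth, np.random.default_rng(11))
        b = evaluate_group_method(groups, study_run.decisions, ones * 2.0,
                                  study_run.truth, np.random.default_rng(11))
        assert np.array_equal(a.error_rates, b.error_rates)

    def test_hbci_beats_majority_on_pairs(self, study_run):
        t = study_run.table
        a = t[(t["method"] == "hbci") & (t["size"] == 2)]["error_rate"].to_numpy()
        b = t[(t["method"] == "majority") & (t["size"] == 2)]["error_rate"].to_numpy()
        assert compare_methods(a, b, sided="one").pvalue < 0.05
        assert a.mean() < b.mean()

    def test_singleton_errors_match_individual_rates(self, study_run):
        t = study_run.table
        maj1 = t[(t["method"] == "majority") & (t["size"] == 1)]
        expected = (study_run.decisions != study_run.truth).mean(axis=1)
        assert np.allclose(np.sort(maj1["error_rate"]), np.sort(expected))

    def test_no_leakage_from_test_epochs(self, study_run, cohort):
        """Perturbing a test-trial epoch never reaches the fold's fitted
        models: every other test weight of that fold is unchanged.  (The
        same trial is training data in the other folds, so only fold-local
        invariance is expected.)"""
        es = study_run.epoch_sets[0]
        rts = cohort[0].trials["rt"].to_numpy()
        correct = study_run.correct[0]
        folds = study_run.folds
        base = estimate_cv_weights(
            es.stimulus, es.response, rts, correct, folds, ["hybrid"]
        )["hybrid"]
        victim = int(folds[0].test_indices[0])
        stim2 = es.stimulus.copy()
        stim2[victim] += 37.0
        perturbed = estimate_cv_weights(
            stim2, es.response, rts, correct, folds, ["hybrid"]
        )["hybrid"]
        fold0_others = np.setdiff1d(folds[0].test_indices, [victim])
        assert np.array_equal(base[fold0_others], perturbed[fold0_others])
        assert base[victim] != perturbed[victim]

    def test_communication_pair_preserving_run(self):
        from hbci.simulate import simulate_cohort
        from conftest import study_config

        cfg = study_config(seed=9, communication_mode=True, n_channels=8)
        sessions = simulate_cohort(cfg)
        res = run_pipeline_cv(
            sessions,
            methods=("majority", "second_response_majority", "hbci"),
            sizes=(2, 4),
            seed=9,
            enumeration="pair_preserving",
        )
        t = res.table
        # 5 pairs -> C(5,1)=5 groups of size 2, C(5,2)=10 of size 4
        assert len(t[(t["method"] == "majority") & (t["size"] == 2)]) == 5
        assert len(t[(t["method"] == "majority") & (t["size"] == 4)]) == 10
        assert set(t["method"]) == {"majority", "second_response_majority", "hbci"}
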
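"""Threshold training, ROC statistics, and specificity validation."""

import numpy as np
import pytest
from scipy import stats

from umiseq import simulate_background, simulate_catalog
from umiseq.calibration import (
    MutationPool,
    fpr_threshold,
    in_silico_negatives,
    prepare_scans,
    roc_stats,
    sample_catalog_size,
    train_threshold,
    validate_specificity,
)


class TestCatalogSize:
    def test_degenerate_distribution(self):
        assert sample_catalog_size({3: 1.0}, np.random.default_rng(0)) == 3

    def test_empirical_frequencies_recovered(self):
        dist = {2: 0.25, 3: 0.5, 4: 0.25}
        rng = np.random.default_rng(1)
        draws = np.array([sample_catalog_size(dist, rng) for _ in range(10_000)])
        for size, p in dist.items():
            sd = np.sqrt(p * (1 - p) / 10_000)
            assert abs((draws == size).mean() - p) < 3 * sd

    def test_default_distribution_median_three(self):
        from umiseq.model import SyntheticCohortSpec, empirical_quantile

        dist = SyntheticCohortSpec(seed=0).catalog_size_dist
        assert empirical_quantile(dist, 0.5) == 3
        assert empirical_quantile(dist, 0.75) - empirical_quantile(dist, 0.25) == 2

    def test_empty_distribution_rejected(self):
        with pytest.raises(ValueError):
            sample_catalog_size({}, np.random.default_rng(0))


class TestMutationPool:
    def test_pool_of_one(self, small_panel, rng):
        cat = simulate_catalog(small_panel, rng, size_dist={1: 1.0},
                               deletion_freq=0, insertion_freq=0, mnv_freq=0)
        pool = MutationPool.from_catalogs([cat])
        assert len(pool) == 1
        drawn = pool.draw(1, rng)
        assert drawn.mutations[0].key == cat.mutations[0].key

    def test_weighted_draws_follow_frequencies(self, small_panel, rng):
        a = simulate_catalog(small_panel, rng, size_dist={1: 1.0},
                             deletion_freq=0, insertion_freq=0, mnv_freq=0)
        b = simulate_catalog(small_panel, rng, size_dist={1: 1.0},
                             deletion_freq=0, insertion_freq=0, mnv_freq=0)
        pool = MutationPool(
            mutations=a.mutations + b.mutations, weights=np.array([0.9, 0.1])
        )
        hits = sum(
            pool.draw(1, rng).mutations[0].key == a.mutations[0].key
            for _ in range(10_000)
        )
        sd = np.sqrt(0.9 * 0.1 / 10_000)
        assert abs(hits / 10_000 - 0.9) < 3 * sd

    def test_oversized_request_rejected(self, small_panel, rng):
        cat = simulate_catalog(small_panel, rng, size_dist={2: 1.0},
                               deletion_freq=0, insertion_freq=0, mnv_freq=0)
        pool = MutationPool.from_catalogs([cat])
        with pytest.raises(ValueError):
            pool.draw(5, rng)


class TestFprThreshold:
    def test_twenty_evenly_spaced_scores(self):
        # rank ceil(21 * 0.95) = 20: the largest score, the empirical
        # 95th-percentile order statistic under the (n+1) convention
        neg = np.arange(20) * 0.05
        assert fpr_threshold(neg, 0.05) == pytest.approx(0.95)

    def test_hundred_scores_pick_96th_order_statistic(self, rng):
        neg = rng.random(100)
        assert fpr_threshold(neg, 0.05) == np.sort(neg)[95]

    def test_perfect_separation_threshold_sits_in_gap(self, rng):
        neg = rng.uniform(0, 0.4, size=100)
        thr = fpr_threshold(neg, 0.05)
        assert thr < 0.5  # every positive above 0.5 is called
        assert (neg > thr).mean() <= 0.05

    def test_unbiased_coverage_expectation(self):
        # P(fresh uniform <= k-th of n) = k/(n+1): for n=100, fpr=0.05 the
        # chosen rank 96 gives 96/101 ~ 0.9505 coverage
        rng = np.random.default_rng(2)
        cover = [
            (rng.random(10_000) <= fpr_threshold(rng.random(100), 0.05)).mean()
            for _ in range(300)
        ]
        assert np.mean(cover) == pytest.approx(96 / 101, abs=0.004)


class TestRocStats:
    def test_perfect_separation(self):
        out = roc_stats(np.array([1, 2, 3, 4]), np.array([0, 0, 1, 1]))
        assert out["auc"] == 1.0

    def test_random_scores_auc_half(self, rng):
        scores = rng.normal(size=4000)
        labels = rng.integers(0, 2, size=4000)
        assert roc_stats(scores, labels)["auc"] == pytest.approx(0.5, abs=0.03)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_stats(np.array([1.0, 2.0]), np.array([1, 1]))


@pytest.fixture(scope="module")
def calib_setup(small_panel, pon_bundle):
    """Healthy scans plus an SNV-heavy pool for fast negative generation."""
    pon, truth, model = pon_bundle
    rng = np.random.default_rng(60)
    healthy = [simulate_background(small_panel, truth, 4000, rng) for _ in range(8)]
    cats = [
        simulate_catalog(small_panel, rng, patient_id=f"p{i}")
        for i in range(40)
    ]
    pool = MutationPool.from_catalogs(cats)
    sizes = [len(c) for c in cats]
    size_dist = {s: sizes.count(s) / len(sizes) for s in set(sizes)}
    scans = prepare_scans(healthy, model)
    return scans, pool, size_dist


class TestNegativesAndValidation:
    def test_null_negatives_center_below_half(self, calib_setup, rng):
        scans, pool, size_dist = calib_setup
        S = in_silico_negatives(scans, pool, size_dist, 120, rng, K=1000)
        # mixed-class catalogs are conservative: mean at or below 0.5
        assert S.mean() < 0.55
        assert (S < 0.9).mean() > 0.7

    def test_all_zero_scores_give_full_specificity(self, calib_setup):
        scans, pool, size_dist = calib_setup
        val = validate_specificity(
            scans, pool, size_dist, alpha=0.5,
            training_specificities=np.full(5, 1.0),
            rng=np.random.default_rng(3), n_reps=2, n_per_rep=10, K=200,
        )
        # specificity bounded by construction
        assert 0.0 <= val.mean_specificity <= 1.0

    def test_alpha_zero_calls_everything_positive(self, calib_setup):
        scans, pool, size_dist = calib_setup
        rng = np.random.default_rng(5)
        S = in_silico_negatives(scans, pool, size_dist, 50, rng, K=500)
        assert ((S <= 0.0).mean()) == pytest.approx((S == 0).mean())
        spec_at_zero = (S <= 0.0).mean()
        assert spec_at_zero < 0.2  # almost every S > 0 is called positive

    def test_specificity_monotone_in_alpha(self, calib_setup):
        scans, pool, size_dist = calib_setup
        rng = np.random.default_rng(6)
        S = in_silico_negatives(scans, pool, size_dist, 150, rng, K=500)
        alphas = np.linspace(0, 0.999, 25)
        spec = [(S <= a).mean() for a in alphas]
        assert all(b >= a for a, b in zip(spec, spec[1:]))

    def test_identical_generators_give_insignificant_t(self, calib_setup):
        scans, pool, size_dist = calib_setup
        rng = np.random.default_rng(7)
        alpha = 0.9
        spec_a = np.array([
            (in_silico_negatives(scans, pool, size_dist, 40, rng, K=500) <= alpha).mean()
            for _ in range(8)
        ])
        val = validate_specificity(
            scans, pool, size_dist, alpha, spec_a,
            rng=rng, n_reps=8, n_per_rep=40, K=500,
        )
        assert val.p_value > 0.05


def test_training_is_reproducible_and_reports_roc(calib_setup):
    scans, pool, size_dist = calib_setup
    pos = np.random.default_rng(1).uniform(0.9, 1.0, size=30)

    def run(seed):
        return train_threshold(
            pos, scans, pool, size_dist, np.random.default_rng(seed),
            n_sims=3, n_pos=20, n_neg=40, K=500,
        )

    with pytest.warns(UserWarning):
        # n_pos defaults exceed the 30 positives when asked for 100
        train_threshold(
            pos, scans, pool, size_dist, np.random.default_rng(0),
            n_sims=1, n_pos=100, n_neg=20, K=200,
        )
    a, b = run(11), run(11)
    assert a.alpha == b.alpha
    np.testing.assert_array_equal(a.per_sim_threshold, b.per_sim_threshold)
    assert (a.per_sim_auc > 0.8).all()  # well-separated synthetic scores
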
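"""The scoring core: Bayes factors, integration, rank score, cAF."""

import numpy as np
import pytest

from umiseq import simulate_background, simulate_catalog, simulate_plasma, umiseq_score
from umiseq.model import CountVector, MutationCatalog, MutationRecord, UncallablePatientError
from umiseq._betabinom import log_bayes_factor, log_bayes_factor_rows
from umiseq.scoring import (
    PanelScan,
    call_sample,
    compute_caf,
    integrated_score,
    mutation_score,
    random_catalogs,
    rank_score,
)

from oracles import quadrature_log_bayes_factor


class TestMutationScore:
    def test_agrees_with_quadrature_oracle_on_random_grid(self, rng):
        for _ in range(25):
            d_f = int(rng.integers(500, 20_000))
            d_r = int(rng.integers(500, 20_000))
            x_f = int(rng.integers(0, 15))
            x_r = int(rng.integers(0, 15))
            mu_f = 10.0 ** rng.uniform(-6.5, -3.2)
            mu_r = 10.0 ** rng.uniform(-6.5, -3.2)
            rho = 10.0 ** rng.uniform(-5, -1.3)
            got = log_bayes_factor(x_f, x_r, d_f, d_r, mu_f, mu_r, rho)
            want = quadrature_log_bayes_factor(x_f, x_r, d_f, d_r, mu_f, mu_r, rho)
            assert got == pytest.approx(want, abs=1e-3)

    def test_no_alt_reads_is_no_evidence(self):
        v = CountVector(0, 0, 10_000, 10_000)
        assert mutation_score(v, 1e-5, 1e-5, 1e-4) <= 0.0

    def test_strand_shared_model_penalizes_one_strand_signal(self):
        # 50 alt reads on one strand only: under the shared-fraction (AND)
        # model this looks like a strand artifact and scores far below a
        # model that allows the variant on a single strand
        v = CountVector(50, 0, 950, 1000)
        m_and = mutation_score(v, 1e-4, 1e-4, 1e-3, model="and")
        m_or = mutation_score(v, 1e-4, 1e-4, 1e-3, model="or")
        assert m_and < m_or - 10.0

    def test_zero_depth_strand_is_uninformative(self):
        assert mutation_score(CountVector(0, 0, 0, 1000), 1e-5, 1e-5, 1e-4) == 0.0

    def test_vectorized_scan_matches_scalar_kernel(self, rng):
        n = 40
        x_f = rng.integers(0, 30, n)
        x_r = rng.integers(0, 30, n)
        d_f = rng.integers(200, 10_000, n)
        d_r = rng.integers(200, 10_000, n)
        mu_f = 10.0 ** rng.uniform(-6, -3.5, n)
        mu_r = 10.0 ** rng.uniform(-6, -3.5, n)
        rho = 10.0 ** rng.uniform(-5, -1.5, n)
        vec = log_bayes_factor_rows(x_f, x_r, d_f, d_r, mu_f, mu_r, rho, grid_size=501)
        for i in range(n):
            scal = log_bayes_factor(
                int(x_f[i]), int(x_r[i]), int(d_f[i]), int(d_r[i]),
                mu_f[i], mu_r[i], rho[i], grid_size=501,
            )
            assert vec[i] == pytest.approx(scal, abs=1e-8)


class TestIntegratedScore:
    def test_single_mutation_passes_through(self):
        assert integrated_score(np.array([3.5])) == 3.5

    def test_two_mutations_sum_in_log_space(self):
        assert integrated_score(np.array([3.0, 4.0])) == 7.0

    def test_permutation_invariance(self, rng):
        vals = rng.normal(size=5)
        assert integrated_score(vals) == pytest.approx(
            integrated_score(vals[rng.permutation(5)])
        )

    def test_empty_catalog_raises(self):
        with pytest.raises(UncallablePatientError):
            integrated_score(np.array([]))

    def test_monotone_in_added_evidence(self):
        base = integrated_score(np.array([2.0, -1.0]))
        assert integrated_score(np.array([2.0, -1.0, 0.5])) > base
        assert integrated_score(np.array([2.0, -1.0, -0.5])) < base


class TestRandomCatalogs:
    def test_seeded_draws_reproduce(self):
        a = random_catalogs(3, 1, 5, np.random.default_rng(9))
        b = random_catalogs(3, 1, 5, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)

    def test_full_pool_returns_everything(self):
        idx = random_catalogs(4, 4, 3, np.random.default_rng(0))
        for row in idx:
            assert sorted(row) == [0, 1, 2, 3]

    def test_oversized_catalog_rejected(self):
        with pytest.raises(ValueError):
            random_catalogs(3, 4, 1, np.random.default_rng(0))

    def test_single_draws_are_uniform(self):
        idx = random_catalogs(4, 1, 10_000, np.random.default_rng(12)).ravel()
        freq = np.bincount(idx, minlength=4) / 10_000
        sd = np.sqrt(0.25 * 0.75 / 10_000)
        assert np.all(np.abs(freq - 0.25) < 3 * sd)

    def test_rows_have_no_duplicates(self):
        idx = random_catalogs(50, 8, 2000, np.random.default_rng(3))
        srt = np.sort(idx, axis=1)
        assert not (srt[:, 1:] == srt[:, :-1]).any()


class TestRankScore:
    def test_observed_above_all_random(self):
        r, S = rank_score(10.0, np.zeros(100_000), 100_000)
        assert r == 0 and S == pytest.approx(1.0 - 1.0 / 100_001)

    def test_observed_below_all_random(self):
        r, S = rank_score(-10.0, np.zeros(100), 100)
        assert r == 100 and S == 0.0

    def test_ties_count_as_not_larger(self):
        r, _ = rank_score(5.0, np.array([5.0, 5.0, 4.0]), 3)
        assert r == 0

    def test_invariant_to_positive_rescaling(self, rng):
        obs = 2.5
        rand = rng.normal(size=1000)
        r1, _ = rank_score(obs, rand, 1000)
        r2, _ = rank_score(3.0 * obs, 3.0 * rand, 1000)
        assert r1 == r2


class TestCallAndCaf:
    @pytest.mark.parametrize(
        "S,alpha,expected",
        [(0.99, 0.9797, True), (0.9797, 0.9797, False), (0.0, 0.0, False)],
    )
    def test_call_threshold_is_strict(self, S, alpha, expected):
        assert call_sample(S, alpha) is expected

    def test_caf_is_pooled_ratio(self, small_panel, pon_bundle):
        _, truth, _ = pon_bundle
        # construct a sample with exact counts at two catalog loci
        rng = np.random.default_rng(4)
        cat = simulate_catalog(
            small_panel, rng, deletion_freq=0, insertion_freq=0, mnv_freq=0,
            size_dist={2: 1.0},
        )
        table = simulate_background(small_panel, truth, 1000, rng)
        for k, rec in enumerate(cat):
            i = small_panel.locus_index(rec.chrom, rec.pos)
            col = small_panel.allele_column(i, rec)
            table.depth_fwd[i], table.depth_rev[i] = 5000, 5000
            table.alt_fwd[i, :] = 0
            table.alt_rev[i, :] = 0
            table.alt_fwd[i, col] = 5 if k == 0 else 15
        assert compute_caf(table, cat) == pytest.approx(20 / 20_000)

    def test_caf_zero_when_no_alt_reads(self, small_panel, pon_bundle):
        rng = np.random.default_rng(4)
        cat = simulate_catalog(
            small_panel, rng, deletion_freq=0, insertion_freq=0, mnv_freq=0
        )
        _, truth, _ = pon_bundle
        table = simulate_background(small_panel, truth, 1000, rng)
        table.alt_fwd[:] = 0
        table.alt_rev[:] = 0
        assert compute_caf(table, cat) == 0.0

    def test_caf_recovers_spiked_fraction(self, small_panel, pon_bundle):
        _, truth, _ = pon_bundle
        rng = np.random.default_rng(8)
        caf = 5e-3
        cat = simulate_catalog(
            small_panel, rng, size_dist={3: 1.0},
            deletion_freq=0, insertion_freq=0, mnv_freq=0,
        )
        est = []
        for _ in range(10):
            table = simulate_plasma(cat, caf, 10_000, truth, small_panel, rng)
            est.append(compute_caf(table, cat))
        pooled_depth = 10 * 3 * 10_000
        sd = np.sqrt(caf * (1 - caf) / pooled_depth)
        assert abs(np.mean(est) - caf) < 3 * sd + 1e-4  # background adds a little


class TestUmiseqScore:
    def test_strong_signal_tops_all_random_catalogs(self, small_panel, pon_bundle):
        _, truth, model = pon_bundle
        rng = np.random.default_rng(15)
        cat = simulate_catalog(
            small_panel, rng, size_dist={3: 1.0},
            deletion_freq=0, insertion_freq=0, mnv_freq=0,
        )
        plasma = simulate_plasma(cat, 0.05, 8000, truth, small_panel, rng)
        K = 2000
        sc = umiseq_score(plasma, cat, model, rng, K=K)
        assert sc.r == 0
        assert sc.S == pytest.approx(1.0 - 1.0 / (K + 1))
        assert sc.call  # alpha default 0.9797 < S

    def test_flagged_mutations_do_not_contribute(self, small_panel, pon_bundle):
        """Adding an inert flagged mutation must not change s or cAF."""
        _, truth, model = pon_bundle
        rng = np.random.default_rng(21)
        base = simulate_catalog(
            small_panel, rng, size_dist={3: 1.0},
            deletion_freq=0, insertion_freq=0, mnv_freq=0,
        )
        plasma = simulate_plasma(base, 0.01, 8000, truth, small_panel, rng)
        # an extra catalog with one flagged mutation at an unused locus
        used = {m.pos for m in base}
        i = next(
            j for j in range(small_panel.size)
            if int(small_panel.pos[j]) not in used
        )
        extra = MutationRecord(
            small_panel.chrom[i], int(small_panel.pos[i]), small_panel.ref[i],
            str(small_panel.alt_bases[i][0]), "SNV",
        )
        augmented = MutationCatalog(
            patient_id=base.patient_id, mutations=base.mutations + [extra]
        )
        augmented.chip.add(len(base.mutations))
        s1 = umiseq_score(plasma, base, model, np.random.default_rng(5), K=500)
        s2 = umiseq_score(plasma, augmented, model, np.random.default_rng(5), K=500)
        assert s1.s == pytest.approx(s2.s)
        assert s1.caf == pytest.approx(s2.caf)
        assert s1.S == pytest.approx(s2.S)
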
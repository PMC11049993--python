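"""Generator fidelity: panel structure, class frequencies, spike-ins,
determinism."""

import numpy as np
import pytest

from umiseq import (
    simulate_background,
    simulate_catalog,
    simulate_cohort,
    simulate_panel,
    simulate_pbmc,
    simulate_plasma,
)
from umiseq.model import SyntheticCohortSpec
from umiseq.scoring import compute_caf


class TestPanel:
    def test_requested_size_is_covered(self):
        panel = simulate_panel(100, np.random.default_rng(0))
        assert panel.size == 100
        assert sum(e - s for _, s, e in panel.regions) == 100

    def test_gc_fraction_matches_request(self):
        panel = simulate_panel(15_465, np.random.default_rng(1), gc_fraction=0.5)
        gc = int(np.isin(panel.ref, ["G", "C"]).sum())
        sd = np.sqrt(15_465 * 0.25)
        assert abs(gc - 15_465 / 2) < 3 * sd

    def test_same_seed_same_panel(self):
        a = simulate_panel(500, np.random.default_rng(5))
        b = simulate_panel(500, np.random.default_rng(5))
        np.testing.assert_array_equal(a.ref, b.ref)
        np.testing.assert_array_equal(a.pos, b.pos)
        assert a.regions == b.regions

    def test_contexts_consistent_with_neighbors(self):
        panel = simulate_panel(300, np.random.default_rng(2))
        # inside a region the 3' context of i equals the reference of i+1
        for i in range(panel.size - 1):
            if (
                panel.chrom[i + 1] == panel.chrom[i]
                and panel.pos[i + 1] == panel.pos[i] + 1
            ):
                assert panel.ctx3[i] == panel.ref[i + 1]
                assert panel.ctx5[i + 1] == panel.ref[i]


class TestCatalogs:
    def test_class_carrier_fractions(self, small_panel):
        rng = np.random.default_rng(10)
        n = 1000
        carriers = {"DEL": 0, "INS": 0, "MNV": 0}
        sizes = []
        for i in range(n):
            cat = simulate_catalog(small_panel, rng, patient_id=f"p{i}")
            sizes.append(len(cat))
            classes = {m.variant_class for m in cat}
            for vc in carriers:
                carriers[vc] += vc in classes
        for vc, target in (("DEL", 0.48), ("INS", 0.22), ("MNV", 0.09)):
            sd = np.sqrt(target * (1 - target) / n)
            # small shortfall possible when a size-1 catalog carries another class
            assert abs(carriers[vc] / n - target) < 3 * sd + 0.03
        assert np.median(sizes) == 3
        assert min(sizes) >= 1

    def test_degenerate_size_distribution(self, small_panel):
        rng = np.random.default_rng(11)
        for _ in range(20):
            cat = simulate_catalog(small_panel, rng, size_dist={2: 1.0})
            assert len(cat) == 2


class TestPlasma:
    def test_zero_caf_is_pure_background(self, small_panel, pon_bundle):
        _, truth, _ = pon_bundle
        rng = np.random.default_rng(20)
        cat = simulate_catalog(small_panel, rng, size_dist={3: 1.0},
                               deletion_freq=0, insertion_freq=0, mnv_freq=0)
        state = rng.bit_generator.state
        bg = simulate_background(small_panel, truth, 5000, rng)
        rng.bit_generator.state = state
        pl = simulate_plasma(cat, 0.0, 5000, truth, small_panel, rng)
        np.testing.assert_array_equal(bg.alt_fwd, pl.alt_fwd)
        np.testing.assert_array_equal(bg.alt_rev, pl.alt_rev)

    def test_caf_half_recovered(self, small_panel, pon_bundle):
        _, truth, _ = pon_bundle
        rng = np.random.default_rng(21)
        cat = simulate_catalog(small_panel, rng, size_dist={2: 1.0},
                               deletion_freq=0, insertion_freq=0, mnv_freq=0)
        pl = simulate_plasma(cat, 0.5, 10_000, truth, small_panel, rng)
        caf = compute_caf(pl, cat)
        sd = np.sqrt(0.5 * 0.5 / (2 * 10_000))
        assert abs(caf - 0.5) < 3 * sd

    def test_signal_split_evenly_across_strands(self, small_panel, pon_bundle):
        _, truth, _ = pon_bundle
        rng = np.random.default_rng(22)
        cat = simulate_catalog(small_panel, rng, size_dist={1: 1.0},
                               deletion_freq=0, insertion_freq=0, mnv_freq=0)
        rec = cat.mutations[0]
        fwd = []
        alt = []
        for _ in range(60):
            pl = simulate_plasma(cat, 0.2, 4000, truth, small_panel, rng)
            v = pl.mutation_counts(rec)
            fwd.append(v.alt_fwd)
            alt.append(v.alt)
        frac = np.sum(fwd) / np.sum(alt)
        sd = np.sqrt(0.25 / np.sum(alt))
        assert abs(frac - 0.5) < 4 * sd


class TestPbmc:
    def test_zero_prevalence_never_spikes(self, small_panel, pon_bundle):
        _, truth, _ = pon_bundle
        rng = np.random.default_rng(30)
        for _ in range(30):
            cat = simulate_catalog(small_panel, rng)
            _, chip = simulate_pbmc(
                cat, truth, small_panel, rng, depth=2000, chip_prevalence=0.0
            )
            assert chip == []

    def test_prevalence_and_af_range(self, small_panel, pon_bundle):
        _, truth, _ = pon_bundle
        rng = np.random.default_rng(31)
        n = 3000
        carriers = 0
        for _ in range(n):
            cat = simulate_catalog(small_panel, rng, size_dist={1: 1.0},
                                   deletion_freq=0, insertion_freq=0, mnv_freq=0)
            table, chip = simulate_pbmc(cat, truth, small_panel, rng, depth=4000)
            carriers += bool(chip)
            if chip:
                af = table.mutation_counts(cat.mutations[chip[0]]).af()
                assert af < 0.02  # below ~1% modulo sampling noise
        p = 0.034
        sd = np.sqrt(p * (1 - p) / n)
        assert abs(carriers / n - p) < 3 * sd


class TestCohort:
    def test_cohort_structure_and_determinism(self, tmp_path):
        from umiseq.io import write_cohort

        spec = SyntheticCohortSpec(
            seed=99, n_pon=4, n_patients=3, n_healthy=2, panel_size=120,
            depth_median=500.0,
        )
        a = simulate_cohort(spec)
        b = simulate_cohort(spec)
        assert len(a.pon) == 4 and len(a.healthy) == 2 and len(a.patients) == 3
        write_cohort(a, tmp_path / "a")
        write_cohort(b, tmp_path / "b")
        for pa in sorted((tmp_path / "a").rglob("*")):
            if pa.is_dir():
                continue
            pb = tmp_path / "b" / pa.relative_to(tmp_path / "a")
            assert pa.read_bytes() == pb.read_bytes(), f"{pa.name} differs"

    def test_high_caf_patients_are_called(self, small_panel):
        """End-to-end: positives at high cAF all round-trip to positive calls."""
        from umiseq import build_error_model, umiseq_score
        from umiseq.synthetic import simulate_pon

        rng = np.random.default_rng(40)
        pon, truth = simulate_pon(small_panel, rng, n_samples=12, depth_median=3000)
        model = build_error_model(pon, small_panel)
        for i in range(5):
            cat = simulate_catalog(small_panel, rng, patient_id=f"p{i}")
            pl = simulate_plasma(cat, 0.02, 5000, truth, small_panel, rng)
            sc = umiseq_score(pl, cat, model, rng, K=1500, alpha=0.9797)
            assert sc.call

    def test_error_count_correlates_with_depth(self, small_panel, pon_bundle):
        pon, _, _ = pon_bundle
        depths = np.array([t.depth_fwd.sum() + t.depth_rev.sum() for t in pon])
        errors = np.array([
            t.alt_fwd[:, :3].sum() + t.alt_rev[:, :3].sum() for t in pon
        ])
        r = np.corrcoef(depths, errors)[0, 1]
        assert r > 0.5
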
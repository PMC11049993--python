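"""Limit-of-detection estimation and in-silico detection studies.

Three layers of sensitivity analysis:

- per-mutation LOD: the smallest allele fraction detectable at a single
  locus at a fixed specificity and power, from the beta-binomial error
  model (closed-form tail computations, no simulation);
- sample-level LOD: the smallest circulating AF at which a whole catalog is
  called positive with the trained threshold, by Monte-Carlo bisection;
- detection-probability tables: Poisson-resampled in-silico patients at a
  grid of cAFs, with and without non-SNV mutations, quantifying how much
  signal integration across mutation classes buys.

A synthetic dilution-series benchmark reproduces the mutation-level
discrimination analysis (foreground mutations spiked at known AFs against
the whole-panel background) with ROC / precision-recall AUC per AF bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .model import CountTable, LODResult, MutationCatalog, MutationRecord, PanelDef
from .error_model import ErrorModel
from .scoring import PanelScan, integrated_score, mutation_score, random_catalogs, rank_score
from .synthetic import TruthRates, _add_signal, simulate_background, simulate_plasma

#: sequencing depths of the sample-LOD study
LOD_DEPTHS = (4_000, 10_000, 20_000, 40_000)
#: circulating AFs of the in-silico detection-probability study
DETECTION_CAFS = (1.667e-3, 5.56e-4, 1.85e-4, 6.2e-5)

_RHO_BINOMIAL = 1e-9  # below this the beta-binomial is numerically binomial


def _tail_ge(c: int, depth: int, p: float, rho: float) -> float:
    """P(X >= c) for beta-binomial (binomial in the small-rho limit)."""
    if c <= 0:
        return 1.0
    if c > depth:
        return 0.0
    if p <= 0:
        return 0.0
    if rho <= _RHO_BINOMIAL:
        return float(stats.binom.sf(c - 1, depth, min(p, 1.0)))
    t = (1.0 - rho) / rho
    p = min(p, 1.0 - 1e-12)
    return float(stats.betabinom.sf(c - 1, depth, p * t, (1.0 - p) * t))


def mutation_lod(
    mu: float,
    rho: float,
    depth: int,
    specificity: float = 0.99,
    power: float = 0.95,
    tol: float = 1e-7,
) -> float | None:
    """Minimal detectable AF at one locus.

    The count threshold c* is the smallest integer whose noise-only tail
    probability P(X >= c* | depth, mu, rho) does not exceed 1 - specificity;
    the LOD is then the smallest allele fraction f (binary search to
    ``tol``) at which P(X >= c* | depth, mu + f, rho) reaches ``power``.
    Returns None when no valid c* exists below the depth (noise too high).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    alpha_tail = 1.0 - specificity
    # smallest c with noise tail <= alpha_tail; the tail is decreasing in c
    lo_c, hi_c = 1, depth + 1
    if _tail_ge(1, depth, mu, rho) <= alpha_tail:
        c_star = 1
    else:
        if _tail_ge(depth, depth, mu, rho) > alpha_tail:
            return None
        while hi_c - lo_c > 1:  # invariant: tail(lo_c) > alpha_tail >= tail(hi_c)
            mid = (lo_c + hi_c) // 2
            if _tail_ge(mid, depth, mu, rho) <= alpha_tail:
                hi_c = mid
            else:
                lo_c = mid
        c_star = hi_c
    if _tail_ge(c_star, depth, mu + 1.0, rho) < power:
        return None
    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if _tail_ge(c_star, depth, mu + mid, rho) >= power:
            hi = mid
        else:
            lo = mid
    return hi


def mutation_lod_table(
    error_model: ErrorModel,
    depth: int,
    specificity: float = 0.99,
    power: float = 0.95,
    allele_cols: tuple[int, ...] = (0, 1, 2, 3, 4),
) -> pd.DataFrame:
    """Per-(position, allele) LOD over the panel; NaN where undefined."""
    rows = []
    mu = (error_model.mu_fwd + error_model.mu_rev) / 2.0
    for i in np.flatnonzero(error_model.modelable):
        for col in allele_cols:
            lod = mutation_lod(
                float(mu[i, col]), float(error_model.rho[i, col]), depth,
                specificity=specificity, power=power,
            )
            rows.append((int(i), col, np.nan if lod is None else lod))
    return pd.DataFrame(rows, columns=["locus_idx", "allele_col", "lod"])


@dataclass
class _NullEnsemble:
    """Recycled background panel profiles with their null rank distributions."""

    tables: list[CountTable]
    scans: list[PanelScan]
    random_s: list[np.ndarray]  # per profile, K random catalog scores


def _build_null_ensemble(
    panel: PanelDef,
    rates,
    error_model: ErrorModel,
    depth: float,
    n_catalog: int,
    K: int,
    n_profiles: int,
    rng: np.random.Generator,
) -> _NullEnsemble:
    tables, scans, rand = [], [], []
    for _ in range(n_profiles):
        t = simulate_background(panel, rates, depth, rng)
        sc = PanelScan(t, error_model)
        idx = random_catalogs(sc.pool_size, n_catalog, K, rng)
        tables.append(t)
        scans.append(sc)
        rand.append(sc.log_m[idx].sum(axis=1))
    return _NullEnsemble(tables=tables, scans=scans, random_s=rand)


def _replicate_scores(
    ensemble: _NullEnsemble,
    catalog: MutationCatalog,
    af,
    n_reps: int,
    K: int,
    rng: np.random.Generator,
    poisson_depth: float | None = None,
    subset: list[int] | None = None,
) -> np.ndarray:
    """Rank scores S of ``n_reps`` signal replicates over recycled profiles.

    Signal is redrawn per replicate on top of a copied background at the
    catalog loci only; the profile's precomputed panel scan and null rank
    distribution are reused (random catalogs essentially never overlap the
    few catalog loci).  ``subset`` restricts the scored catalog (e.g. the
    SNV-only comparison) while the signal is still spiked for all mutations.
    """
    S = np.empty(n_reps)
    n_prof = len(ensemble.tables)
    scored = (
        catalog
        if subset is None
        else MutationCatalog(
            patient_id=catalog.patient_id,
            mutations=[catalog.mutations[j] for j in subset],
        )
    )
    for rep in range(n_reps):
        j = rep % n_prof
        base = ensemble.tables[j]
        work = CountTable(
            base.panel,
            base.depth_fwd,
            base.depth_rev,
            base.alt_fwd.copy(),
            base.alt_rev.copy(),
            sample_id=base.sample_id,
        )
        _add_signal(
            work, catalog, af, rng,
            poisson=poisson_depth is not None, depth_for_poisson=poisson_depth,
        )
        log_m = [
            mutation_score(
                work.mutation_counts(m),
                *ensemble.scans[j].error_model.params_for(m),
                grid_size=ensemble.scans[j].grid_size,
            )
            for m in scored.retained()
        ]
        s = integrated_score(np.asarray(log_m))
        if subset is None:
            rand_s = ensemble.random_s[j]
        else:  # resize the null catalogs to the subset size
            idx = random_catalogs(
                ensemble.scans[j].pool_size, len(scored), K, rng
            )
            rand_s = ensemble.scans[j].log_m[idx].sum(axis=1)
        _, S[rep] = rank_score(s, rand_s, K)
    return S


def sample_lod(
    catalog: MutationCatalog,
    error_model: ErrorModel,
    depth: float,
    alpha: float,
    rng: np.random.Generator,
    rates=None,
    K: int = 10_000,
    power: float = 0.95,
    n_reps: int = 200,
    n_profiles: int = 25,
    caf_bracket: tuple[float, float] = (1e-6, 0.05),
    max_iter: int = 12,
) -> LODResult:
    """Sample-level LOD: minimal cAF called positive with probability ``power``.

    Monte-Carlo bisection over the cAF: at each candidate, ``n_reps`` plasma
    replicates (binomial signal at the candidate cAF over recycled
    beta-binomial background profiles) are scored and the positive-call
    fraction compared to ``power``.  When the bracket cannot be closed
    within ``max_iter`` bisections the widest bracketing interval is
    reported.
    """
    rates = rates if rates is not None else error_model
    panel = error_model.panel
    ensemble = _build_null_ensemble(
        panel, rates, error_model, depth, len(catalog.retained()), K, n_profiles, rng
    )

    def call_rate(caf: float) -> float:
        S = _replicate_scores(ensemble, catalog, caf, n_reps, K, rng)
        return float((S > alpha).mean())

    lo, hi = caf_bracket
    rate_hi = call_rate(hi)
    if rate_hi < power:  # not detectable within the bracket
        return LODResult(
            lod=None, depth=depth, specificity=alpha, power=power,
            interval=(lo, hi), call_rate=rate_hi,
        )
    rate = rate_hi
    for _ in range(max_iter):
        mid = float(np.sqrt(lo * hi))  # geometric bisection: cAF spans decades
        r = call_rate(mid)
        if r >= power:
            hi, rate = mid, r
        else:
            lo = mid
    return LODResult(
        lod=hi, depth=depth, specificity=alpha, power=power,
        interval=(lo, hi), call_rate=rate,
    )


def detection_probability(
    catalogs: list[MutationCatalog],
    error_model: ErrorModel,
    alpha: float,
    rng: np.random.Generator,
    rates=None,
    cafs: tuple[float, ...] = DETECTION_CAFS,
    depth: float = 20_000.0,
    n_reps: int = 40,
    K: int = 10_000,
    n_profiles: int = 10,
) -> pd.DataFrame:
    """In-silico ctDNA detection probabilities with and without non-SNVs.

    Per catalog and cAF, each replicate draws per-mutation alt counts as
    Poisson(depth x cAF) on top of background noise and computes two rank
    scores: the full catalog, and the catalog restricted to its SNVs.
    Columns: catalog_id, caf, n_mutations, n_snv, p_detect_all,
    p_detect_snv (NaN when the catalog has no SNVs).
    """
    rates = rates if rates is not None else error_model
    panel = error_model.panel
    rows = []
    for cat_id, catalog in enumerate(catalogs):
        snv_idx = [
            j for j, m in enumerate(catalog) if m.variant_class == "SNV"
        ]
        ensemble = _build_null_ensemble(
            panel, rates, error_model, depth, len(catalog.retained()), K,
            n_profiles, rng,
        )
        for caf in cafs:
            S_all = _replicate_scores(
                ensemble, catalog, caf, n_reps, K, rng, poisson_depth=depth
            )
            p_all = float((S_all > alpha).mean())
            if snv_idx:
                S_snv = _replicate_scores(
                    ensemble, catalog, caf, n_reps, K, rng,
                    poisson_depth=depth, subset=snv_idx,
                )
                p_snv = float((S_snv > alpha).mean())
            else:
                p_snv = np.nan
            rows.append(
                (cat_id, caf, len(catalog), len(snv_idx), p_all, p_snv)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "catalog_id", "caf", "n_mutations", "n_snv",
            "p_detect_all", "p_detect_snv",
        ],
    )


DEFAULT_AF_BINS = (
    (0.0, 1e-4),
    (1e-4, 5e-4),
    (5e-4, 1e-3),
    (1e-3, 1e-2),
    (1e-2, 1e-1),
    (1e-1, 1.01),
)


def foreground_catalog(
    panel: PanelDef, rng: np.random.Generator, n: int = 95,
    af_range: tuple[float, float] = (1e-3, 1.0),
) -> tuple[MutationCatalog, np.ndarray]:
    """Compound foreground: ``n`` SNVs with log-uniform undiluted AFs."""
    pos = rng.choice(panel.size, size=n, replace=False)
    muts = []
    for i in pos:
        alt = str(rng.choice(panel.alt_bases[int(i)]))
        muts.append(
            MutationRecord(
                panel.chrom[int(i)], int(panel.pos[int(i)]), panel.ref[int(i)],
                alt, "SNV", patient_id="compound",
            )
        )
    afs = np.exp(rng.uniform(np.log(af_range[0]), np.log(af_range[1]), size=n))
    return MutationCatalog(patient_id="compound", mutations=muts), afs


def _mutation_level_auc(
    scan: PanelScan, fg_scores: np.ndarray, keep: np.ndarray
) -> tuple[float, float]:
    """(ROC AUC, PR AUC) of kept foreground scores vs the whole-panel pool."""
    scores = np.concatenate([fg_scores[keep], scan.log_m])
    labels = np.concatenate(
        [np.ones(int(keep.sum())), np.zeros(scan.pool_size)]
    )
    return (
        float(roc_auc_score(labels, scores)),
        float(average_precision_score(labels, scores)),
    )


def dilution_benchmark(
    panel: PanelDef,
    error_model: ErrorModel,
    rng: np.random.Generator,
    rates=None,
    n_foreground: int = 95,
    dilution_factors: tuple[float, ...] = (1.0, 0.25, 0.0625, 0.0156, 0.0039, 0.001),
    depth: float = 10_000.0,
    af_bins: tuple[tuple[float, float], ...] = DEFAULT_AF_BINS,
    n_reps: int = 20,
) -> pd.DataFrame:
    """Synthetic dilution-series benchmark of mutation-level detection.

    A compound foreground catalog is serially diluted; in every diluted
    sample each foreground mutation is spiked at its diluted AF on top of
    the panel background.  Foreground mutations are binned by *observed* AF
    and, per bin, their Bayes factors are discriminated against all other
    panel substitutions of the same samples (ROC and precision-recall AUC,
    mean and normal-theory 95% CI over ``n_reps`` Monte-Carlo repetitions).
    Also reports the Pearson correlation between spiked and observed AFs.
    """
    rates = rates if rates is not None else error_model
    per_bin: dict[int, list[tuple[float, float]]] = {i: [] for i in range(len(af_bins))}
    pearson = []
    for _ in range(n_reps):
        catalog, base_af = foreground_catalog(panel, rng, n=n_foreground)
        exp_af, obs_af, fg_scores_all = [], [], []
        for dil in dilution_factors:
            table = simulate_plasma(
                catalog, 0.0, depth, rates, panel, rng,
                per_mutation_af=np.minimum(base_af * dil, 0.999),
            )
            scan = PanelScan(table, error_model)
            fg_scores = scan.catalog_log_m(catalog)
            afs = np.array(
                [table.mutation_counts(m).af() for m in catalog]
            )
            exp_af.extend(np.minimum(base_af * dil, 1.0))
            obs_af.extend(afs)
            for b, (lo, hi) in enumerate(af_bins):
                keep = (afs >= lo) & (afs < hi)
                if keep.sum() == 0:
                    continue
                per_bin[b].append(_mutation_level_auc(scan, fg_scores, keep))
        r, _ = stats.pearsonr(np.sqrt(exp_af), np.sqrt(obs_af))
        pearson.append(r)
    rows = []
    for b, (lo, hi) in enumerate(af_bins):
        vals = per_bin[b]
        if not vals:
            import warnings

            warnings.warn(f"AF bin [{lo:g}, {hi:g}) is empty; skipped", stacklevel=2)
            continue
        roc = np.array([v[0] for v in vals])
        pr = np.array([v[1] for v in vals])
        half = 1.96 * roc.std(ddof=1) / np.sqrt(len(roc)) if len(roc) > 1 else 0.0
        rows.append(
            (lo, hi, len(vals), roc.mean(), roc.mean() - half, roc.mean() + half, pr.mean())
        )
    out = pd.DataFrame(
        rows,
        columns=["af_lo", "af_hi", "n_obs", "roc_auc", "roc_ci_lo", "roc_ci_hi", "pr_auc"],
    )
    out.attrs["pearson_r"] = float(np.mean(pearson))
    return out


def low_af_discrimination(
    panel: PanelDef,
    error_model: ErrorModel,
    rng: np.random.Generator,
    rates=None,
    n_foreground: int = 95,
    af_range: tuple[float, float] = (2.5e-4, 7.5e-4),
    depth: float = 10_000.0,
    n_reps: int = 20,
) -> float:
    """Mean mutation-level ROC AUC for foreground spiked near 0.05% AF.

    The focused low-AF version of the dilution benchmark: per repetition,
    foreground mutations receive binomial signal at AFs drawn uniformly
    from ``af_range`` and are discriminated against all other panel
    substitutions of the same sample.
    """
    rates = rates if rates is not None else error_model
    aucs = np.empty(n_reps)
    for rep in range(n_reps):
        catalog, _ = foreground_catalog(panel, rng, n=n_foreground)
        afs = rng.uniform(*af_range, size=len(catalog))
        table = simulate_plasma(
            catalog, 0.0, depth, rates, panel, rng, per_mutation_af=afs
        )
        scan = PanelScan(table, error_model)
        fg_scores = scan.catalog_log_m(catalog)
        aucs[rep], _ = _mutation_level_auc(
            scan, fg_scores, np.ones(len(catalog), dtype=bool)
        )
    return float(aucs.mean())
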
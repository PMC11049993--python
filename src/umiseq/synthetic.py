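"""Synthetic cohort generator.

Generates panels, panel-of-normals / plasma / PBMC count tables and patient
catalogs with the statistical structure the caller assumes, so the whole
pipeline runs and is testable without sequencing data.

The error profile emulates deep UMI-consensus targeted sequencing of cfDNA:
per site-substitution error rates are drawn from substitution-class- and
trinucleotide-context-dependent log-normal distributions calibrated so that
C>T / G>A / G>T substitutions are noisy (>90% of C/G sites above 0.001%,
roughly a quarter above 0.01%, with N(C>T)G contexts the noisiest), the
T>G / A>C / C>G / G>C group is quiet (~75-80% of sites below 0.001%), and
deletions, and especially insertions, are quieter still.  Counts are then
beta-binomial with per-site dispersion, independently per strand.

Signal reads are added on top of background (no displacement); at the cAFs
of interest (<< 1) the distortion is negligible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    BASES,
    DEL_COL,
    INS_COL,
    N_ALLELES,
    CountTable,
    MutationCatalog,
    MutationRecord,
    PanelDef,
    SyntheticCohortSpec,
    empirical_quantile,
)

_HIGH = {"C>T", "G>A", "G>T"}
_LOW = {"T>G", "A>C", "C>G", "G>C"}


@dataclass
class ContextErrorSpec:
    """Log-normal error-rate parameters (log10 scale) per substitution group.

    ``boost_ncg`` is added to log10 rates of C>T substitutions with a 3' G
    (and of the strand-complementary G>A with a 5' C); the group mean is
    shifted down by the expected boost so the marginal calibration holds.
    """

    high_mean: float = -4.23
    high_sd: float = 0.28
    mid_mean: float = -5.0
    mid_sd: float = 0.5
    low_mean: float = -5.39
    low_sd: float = 0.5
    del_mean: float = -5.8
    del_sd: float = 0.5
    ins_mean: float = -6.4
    ins_sd: float = 0.5
    boost_ncg: float = 0.35
    rho_log10_mean: float = -3.0
    rho_log10_sd: float = 0.4
    rho_bounds: tuple[float, float] = (1e-6, 0.05)
    depth_site_sd: float = 0.2  # lognormal sd of per-position capture efficiency


@dataclass
class TruthRates:
    """Generating error rates: the simulator's ground truth.

    Shares the array layout of the estimated error model (``mu_fwd``,
    ``mu_rev``, ``rho`` of shape (L, 5)) so scoring and LOD machinery accept
    either interchangeably.
    """

    mu: np.ndarray
    rho: np.ndarray
    site_factor: np.ndarray  # per-position capture efficiency multiplier

    @property
    def mu_fwd(self) -> np.ndarray:
        return self.mu

    @property
    def mu_rev(self) -> np.ndarray:
        return self.mu


def simulate_panel(
    size: int,
    rng: np.random.Generator,
    gc_fraction: float = 0.5,
    n_regions: int = 12,
    chrom_prefix: str = "sim",
) -> PanelDef:
    """Random panel: ``size`` covered positions split into a few regions.

    Sequence is iid with the requested GC fraction; one flanking base beyond
    each region edge provides the trinucleotide context of edge positions.
    """
    if size <= 0:
        raise ValueError("size must be positive")
    n_regions = min(n_regions, size)
    # random region lengths summing to `size`
    cuts = np.sort(rng.choice(size - 1, size=n_regions - 1, replace=False)) + 1 if n_regions > 1 else np.array([], dtype=int)
    lengths = np.diff(np.concatenate([[0], cuts, [size]]))
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    regions = []
    chroms, poss, refs, c5s, c3s = [], [], [], [], []
    cursor = 1000
    chrom = f"{chrom_prefix}1"
    for length in lengths:
        seq = rng.choice(np.array(list(BASES)), size=length + 2, p=p)
        start = cursor
        regions.append((chrom, start, start + int(length)))
        for i in range(length):
            chroms.append(chrom)
            poss.append(start + i + 1)  # 1-based
            refs.append(seq[i + 1])
            c5s.append(seq[i])
            c3s.append(seq[i + 2])
        cursor = start + int(length) + rng.integers(500, 5000)
    return PanelDef(
        regions=regions,
        chrom=np.array(chroms),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs),
        ctx5=np.array(c5s),
        ctx3=np.array(c3s),
    )


def simulate_error_rates(
    panel: PanelDef, rng: np.random.Generator, spec: ContextErrorSpec | None = None
) -> TruthRates:
    """Draw ground-truth per (position, allele) error rates and dispersions."""
    spec = spec or ContextErrorSpec()
    L = panel.size
    log10mu = np.empty((L, N_ALLELES))
    boosted = np.zeros((L, 3), dtype=bool)
    for col in range(3):
        subs = np.char.add(np.char.add(panel.ref, ">"), panel.alt_bases[:, col])
        mean = np.full(L, spec.mid_mean)
        sd = np.full(L, spec.mid_sd)
        hi = np.isin(subs, list(_HIGH))
        lo = np.isin(subs, list(_LOW))
        mean[hi], sd[hi] = spec.high_mean, spec.high_sd
        mean[lo], sd[lo] = spec.low_mean, spec.low_sd
        b = ((subs == "C>T") & (panel.ctx3 == "G")) | (
            (subs == "G>A") & (panel.ctx5 == "C")
        )
        boosted[:, col] = b
        # compensate the class mean so the marginal over contexts is stable
        frac_g = 0.25  # iid sequence: P(3' base is G) at gc 0.5
        mean = mean - np.where(hi & (np.char.startswith(subs, "C>T") | (subs == "G>A")), spec.boost_ncg * frac_g, 0.0)
        log10mu[:, col] = rng.normal(mean, sd) + np.where(b, spec.boost_ncg, 0.0)
    log10mu[:, DEL_COL] = rng.normal(spec.del_mean, spec.del_sd, size=L)
    log10mu[:, INS_COL] = rng.normal(spec.ins_mean, spec.ins_sd, size=L)
    mu = 10.0**log10mu
    rho = 10.0 ** rng.normal(spec.rho_log10_mean, spec.rho_log10_sd, size=(L, N_ALLELES))
    rho = np.clip(rho, *spec.rho_bounds)
    site_factor = np.exp(rng.normal(0.0, spec.depth_site_sd, size=L))
    return TruthRates(mu=mu, rho=rho, site_factor=site_factor)


def _bb_counts(
    depth: np.ndarray, mu: np.ndarray, rho: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Beta-binomial draws: depth (L,), mu/rho (L, A) -> (L, A)."""
    t = (1.0 - rho) / rho
    a = np.clip(mu * t, 1e-12, None)
    b = np.clip((1.0 - mu) * t, 1e-12, None)
    p = rng.beta(a, b)
    return rng.binomial(depth[:, None], p)


def simulate_background(
    panel: PanelDef,
    rates,
    depth: float,
    rng: np.random.Generator,
    sample_id: str = "",
) -> CountTable:
    """Noise-only sample at a mean total depth.

    ``rates`` is any object with ``mu_fwd``/``mu_rev``/``rho`` arrays of
    shape (L, 5) — the simulator truth or an estimated error model — plus an
    optional per-position ``site_factor``.
    """
    L = panel.size
    sf = getattr(rates, "site_factor", None)
    lam = depth / 2.0 * (sf if sf is not None else np.ones(L))
    d_f = rng.poisson(lam).astype(np.int64)
    d_r = rng.poisson(lam).astype(np.int64)
    alt_f = _bb_counts(d_f, np.asarray(rates.mu_fwd), np.asarray(rates.rho), rng)
    alt_r = _bb_counts(d_r, np.asarray(rates.mu_rev), np.asarray(rates.rho), rng)
    np.minimum(alt_f, d_f[:, None], out=alt_f)
    np.minimum(alt_r, d_r[:, None], out=alt_r)
    return CountTable(panel, d_f, d_r, alt_f, alt_r, sample_id=sample_id)


def simulate_pon(
    panel: PanelDef,
    rng: np.random.Generator,
    n_samples: int = 46,
    depth_median: float = 9_086.0,
    depth_sigma: float = 0.35,
    error_spec: ContextErrorSpec | None = None,
    rates: TruthRates | None = None,
) -> tuple[list[CountTable], TruthRates]:
    """Panel-of-normals count tables plus the generating truth."""
    if rates is None:
        rates = simulate_error_rates(panel, rng, error_spec)
    tables = []
    for j in range(n_samples):
        depth = depth_median * np.exp(rng.normal(0.0, depth_sigma))
        tables.append(
            simulate_background(panel, rates, depth, rng, sample_id=f"pon{j:03d}")
        )
    return tables, rates


def _adjacent_ok(panel: PanelDef, i: int) -> bool:
    """True when position i+1 exists and is contiguous on the same chrom."""
    return (
        i + 1 < panel.size
        and panel.chrom[i + 1] == panel.chrom[i]
        and panel.pos[i + 1] == panel.pos[i] + 1
    )


def simulate_catalog(
    panel: PanelDef,
    rng: np.random.Generator,
    size_dist: dict[int, float] | None = None,
    deletion_freq: float = 0.48,
    insertion_freq: float = 0.22,
    mnv_freq: float = 0.09,
    patient_id: str = "P0",
) -> MutationCatalog:
    """A patient's tumor catalog with realistic size and class mix.

    Catalog size follows the empirical distribution (default: median 3,
    IQR 2; minimum 1 enforced by construction).  Carrier probabilities for
    at least one deletion / insertion / MNV default to 48% / 22% / 9%;
    remaining slots are SNVs at random panel positions.
    """
    size_dist = size_dist or SyntheticCohortSpec(seed=0).catalog_size_dist
    sizes = np.array(sorted(size_dist))
    probs = np.array([size_dist[s] for s in sizes])
    n = int(rng.choice(sizes, p=probs))
    classes: list[str] = []
    if rng.random() < deletion_freq:
        classes.append("DEL")
    if rng.random() < insertion_freq:
        classes.append("INS")
    if rng.random() < mnv_freq:
        classes.append("MNV")
    rng.shuffle(classes)
    classes = classes[:n] + ["SNV"] * (n - len(classes[:n]))
    positions = rng.choice(panel.size, size=4 * n, replace=False)
    used: set[int] = set()
    records = []
    cursor = 0
    for vc in classes:
        while True:
            if cursor >= len(positions):  # extremely unlikely; resample
                positions = rng.choice(panel.size, size=4 * n, replace=False)
                cursor = 0
            i = int(positions[cursor])
            cursor += 1
            needs_next = vc in ("DEL", "MNV")
            if i in used or (needs_next and (i + 1 in used or not _adjacent_ok(panel, i))):
                continue
            break
        used.add(i)
        chrom, pos1, ref = panel.chrom[i], int(panel.pos[i]), panel.ref[i]
        if vc == "SNV":
            alt = str(rng.choice(panel.alt_bases[i]))
            records.append(
                MutationRecord(
                    chrom, pos1, ref, alt, "SNV",
                    patient_id=patient_id, context=panel.context_string(i),
                )
            )
        elif vc == "INS":
            alt = ref + str(rng.choice(list(BASES)))
            records.append(
                MutationRecord(chrom, pos1, ref, alt, "INS", patient_id=patient_id)
            )
        elif vc == "DEL":
            used.add(i + 1)
            records.append(
                MutationRecord(
                    chrom, pos1, ref + panel.ref[i + 1], ref, "DEL",
                    patient_id=patient_id,
                )
            )
        else:  # MNV over two adjacent positions
            used.add(i + 1)
            ref2 = ref + panel.ref[i + 1]
            alt2 = str(rng.choice(panel.alt_bases[i])) + str(
                rng.choice(panel.alt_bases[i + 1])
            )
            records.append(
                MutationRecord(
                    chrom, pos1, ref2, alt2, "MNV", patient_id=patient_id,
                    constituent_loci=[pos1, pos1 + 1],
                )
            )
    return MutationCatalog(patient_id=patient_id, mutations=records)


def _add_signal(
    table: CountTable,
    catalog: MutationCatalog,
    af,
    rng: np.random.Generator,
    poisson: bool = False,
    depth_for_poisson: float | None = None,
) -> None:
    """Spike variant-supporting reads into a count table, in place.

    ``af`` is a scalar or per-mutation array.  Binomial mode draws the
    signal from the simulated locus depth; Poisson mode draws
    ``Poisson(depth * af)`` per mutation (the in-silico detection study).
    Signal is split across strands as Binomial(x, 1/2) and added on top of
    the background, capped at the strand depth.
    """
    panel = table.panel
    af = np.broadcast_to(np.asarray(af, dtype=float), (len(catalog),))
    for record, f in zip(catalog, af):
        if f <= 0:
            continue
        targets: list[tuple[int, int]] = []
        if record.variant_class in ("SNV", "INS", "DEL"):
            i = panel.locus_index(record.chrom, record.pos)
            targets.append((i, panel.allele_column(i, record)))
        else:
            for offset, pos1 in enumerate(record.spans):
                i = panel.locus_index(record.chrom, pos1)
                if record.variant_class == "MNV" and offset < len(record.alt):
                    cols = np.where(panel.alt_bases[i] == record.alt[offset])[0]
                    targets.append((i, int(cols[0]) if len(cols) else 0))
                else:
                    targets.append((i, 0))
        # one fragment count per event, applied to every constituent locus
        i0 = targets[0][0]
        d_tot = int(table.depth_fwd[i0] + table.depth_rev[i0])
        if poisson:
            x = rng.poisson((depth_for_poisson or d_tot) * f)
        else:
            x = rng.binomial(d_tot, min(f, 1.0)) if d_tot > 0 else 0
        x_f = rng.binomial(x, 0.5)
        x_r = x - x_f
        for i, col in targets:
            table.alt_fwd[i, col] = min(
                table.alt_fwd[i, col] + x_f, table.depth_fwd[i]
            )
            table.alt_rev[i, col] = min(
                table.alt_rev[i, col] + x_r, table.depth_rev[i]
            )


def simulate_plasma(
    catalog: MutationCatalog,
    caf: float,
    depth: float,
    rates,
    panel: PanelDef,
    rng: np.random.Generator,
    sample_id: str = "",
    per_mutation_af=None,
) -> CountTable:
    """Plasma sample: panel-wide background plus tumor signal at ``caf``.

    Every catalog mutation receives binomial signal at allele fraction
    ``caf`` (or ``per_mutation_af`` when given), so the sample-level
    circulating AF matches ``caf`` in expectation.
    """
    if not 0 <= caf < 1:
        raise ValueError("caf must lie in [0, 1)")
    table = simulate_background(panel, rates, depth, rng, sample_id=sample_id)
    af = per_mutation_af if per_mutation_af is not None else caf
    _add_signal(table, catalog, af, rng)
    return table


def simulate_pbmc(
    catalog: MutationCatalog,
    rates,
    panel: PanelDef,
    rng: np.random.Generator,
    depth: float = 9_086.0,
    chip_prevalence: float = 0.034,
    chip_af_range: tuple[float, float] = (0.001, 0.01),
    sample_id: str = "",
) -> tuple[CountTable, list[int]]:
    """PBMC sample with optional CHIP spike-in.

    With probability ``chip_prevalence`` one catalog mutation is present in
    the patient's blood compartment at an AF drawn uniformly from
    ``chip_af_range`` (clonal hematopoiesis AFs are generally below 1%).
    Returns the table and the indices of spiked (true CHIP) mutations.
    """
    table = simulate_background(panel, rates, depth, rng, sample_id=sample_id)
    chip_idx: list[int] = []
    if rng.random() < chip_prevalence:
        j = int(rng.integers(len(catalog)))
        af = rng.uniform(*chip_af_range)
        sub = MutationCatalog(
            patient_id=catalog.patient_id, mutations=[catalog.mutations[j]]
        )
        _add_signal(table, sub, af, rng)
        chip_idx.append(j)
    return table, chip_idx


def spike_recurrent_artifacts(
    tables: list[CountTable],
    rng: np.random.Generator,
    n_artifacts: int = 69,
    af: float = 0.005,
    sample_fraction: float = 0.6,
) -> list[tuple[int, int]]:
    """Plant recurrent artifact alleles into healthy count tables, in place.

    Each planted (position, substitution) receives binomial counts at ``af``
    in a random ``sample_fraction`` of the samples.  Returns the planted
    (position index, allele column) pairs, for blacklist-recovery tests.
    """
    panel = tables[0].panel
    pos = rng.choice(panel.size, size=n_artifacts, replace=False)
    planted = [(int(i), int(rng.integers(3))) for i in pos]
    for table in tables:
        for i, col in planted:
            if rng.random() < sample_fraction:
                d_f, d_r = int(table.depth_fwd[i]), int(table.depth_rev[i])
                table.alt_fwd[i, col] = min(d_f, table.alt_fwd[i, col] + rng.binomial(d_f, af))
                table.alt_rev[i, col] = min(d_r, table.alt_rev[i, col] + rng.binomial(d_r, af))
    return planted


@dataclass
class PatientBundle:
    catalog: MutationCatalog
    caf: float
    plasma: CountTable
    pbmc: CountTable
    chip_truth: list[int]


@dataclass
class CohortBundle:
    """Everything one seeded cohort simulation produces."""

    spec: SyntheticCohortSpec
    panel: PanelDef
    truth: TruthRates
    pon: list[CountTable]
    healthy: list[CountTable]
    patients: list[PatientBundle]

    @property
    def catalog_pool(self) -> list[MutationRecord]:
        return [m for p in self.patients for m in p.catalog]


def simulate_cohort(spec: SyntheticCohortSpec) -> CohortBundle:
    """Full training-style cohort: PON, patients (catalog + plasma + PBMC),
    healthy controls.  Deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    panel = simulate_panel(spec.panel_size, rng, gc_fraction=spec.gc_fraction)
    pon, truth = simulate_pon(
        panel,
        rng,
        n_samples=spec.n_pon,
        depth_median=spec.depth_median,
        depth_sigma=spec.depth_sigma,
    )
    healthy = []
    for j in range(spec.n_healthy):
        depth = spec.depth_median * np.exp(rng.normal(0.0, spec.depth_sigma))
        healthy.append(
            simulate_background(panel, truth, depth, rng, sample_id=f"healthy{j:03d}")
        )
    lo, hi = spec.caf_range
    patients = []
    for j in range(spec.n_patients):
        pid = f"patient{j:03d}"
        catalog = simulate_catalog(
            panel,
            rng,
            size_dist=spec.catalog_size_dist,
            deletion_freq=spec.deletion_carrier_freq,
            insertion_freq=spec.insertion_carrier_freq,
            mnv_freq=spec.mnv_carrier_freq,
            patient_id=pid,
        )
        caf = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        depth = spec.depth_median * np.exp(rng.normal(0.0, spec.depth_sigma))
        plasma = simulate_plasma(
            catalog, caf, depth, truth, panel, rng, sample_id=f"{pid}_plasma"
        )
        pbmc, chip = simulate_pbmc(
            catalog,
            truth,
            panel,
            rng,
            depth=spec.depth_median,
            chip_prevalence=spec.chip_prevalence,
            chip_af_range=spec.chip_af_range,
            sample_id=f"{pid}_pbmc",
        )
        patients.append(PatientBundle(catalog, caf, plasma, pbmc, chip))
    return CohortBundle(
        spec=spec, panel=panel, truth=truth, pon=pon, healthy=healthy, patients=patients
    )
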
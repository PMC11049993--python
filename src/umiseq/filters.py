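"""Blacklisting of recurrent healthy-plasma artifacts and CHIP flagging.

Two orthogonal filters remove mutations whose plasma signal cannot be
trusted as tumor-derived: (1) a panel-level blacklist of alleles that recur
in cfDNA of healthy individuals (systematic artifacts), and (2) per-patient
flagging of catalog mutations that are present in the patient's own PBMC
DNA — clonal hematopoiesis (CHIP), which would otherwise mimic ctDNA.
Flagged mutations are excluded from the integrated score and the cAF but
remain in the catalog for reporting.
"""

from __future__ import annotations

import warnings

import numpy as np

from .model import CountTable, MutationCatalog, PanelDef
from .error_model import ErrorModel
from .scoring import mutation_score

DEFAULT_AF_MIN = 0.001  # 0.1% allele fraction
DEFAULT_FRAC_MIN = 0.20  # recurrent = seen in >= 20% of healthy samples
DEFAULT_CHIP_POSTERIOR = 0.95


def derive_blacklist(
    healthy: list[CountTable],
    panel: PanelDef,
    af_min: float = DEFAULT_AF_MIN,
    frac_min: float = DEFAULT_FRAC_MIN,
) -> list[tuple[int, int]]:
    """Recurrent-artifact alleles from healthy cfDNA.

    A (position, substitution) is blacklisted when its allele fraction
    exceeds ``af_min`` in at least ``frac_min`` of the healthy samples.
    Output is sorted (position, then allele column) and order-invariant in
    the input samples.
    """
    if len(healthy) < 2:
        raise ValueError("need >= 2 healthy samples")
    hits = np.zeros((panel.size, 3), dtype=np.int64)
    for table in healthy:
        depth = (table.depth_fwd + table.depth_rev).astype(float)[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            af = (table.alt_fwd[:, :3] + table.alt_rev[:, :3]) / depth
        hits += np.where(depth > 0, af, 0.0) > af_min
    rec = hits / len(healthy) >= frac_min
    return [(int(i), int(c)) for i, c in zip(*np.nonzero(rec))]


def apply_blacklist(
    catalog: MutationCatalog,
    blacklist: list[tuple[int, int]] | set[tuple[int, int]],
    panel: PanelDef,
) -> MutationCatalog:
    """Set blacklist flags on catalog mutations matching blacklisted alleles."""
    bl = set(blacklist)
    for j, record in enumerate(catalog):
        if record.variant_class != "SNV":
            continue
        if not panel.contains(record.chrom, record.pos):
            continue
        i = panel.locus_index(record.chrom, record.pos)
        if (i, panel.allele_column(i, record)) in bl:
            catalog.blacklisted.add(j)
    return catalog


def flag_chip(
    catalog: MutationCatalog,
    pbmc: CountTable,
    error_model: ErrorModel,
    posterior_threshold: float = DEFAULT_CHIP_POSTERIOR,
) -> MutationCatalog:
    """Flag catalog mutations with variant evidence in matched PBMC DNA.

    Reuses the plasma Bayes-factor machinery on the PBMC counts: with prior
    odds 1 the posterior probability of a variant is BF / (1 + BF); a
    mutation is flagged as CHIP when that probability exceeds
    ``posterior_threshold``.  Mutations without usable PBMC counts are kept
    unflagged with a warning.
    """
    if not 0 < posterior_threshold < 1:
        raise ValueError("posterior_threshold must lie in (0, 1)")
    log_bf_cut = float(
        np.log(posterior_threshold) - np.log1p(-posterior_threshold)
    )
    panel = error_model.panel
    for j, record in enumerate(catalog):
        try:
            counts = pbmc.mutation_counts(record)
            mu_f, mu_r, rho = error_model.params_for(record)
        except KeyError:
            warnings.warn(
                f"no PBMC counts at {record.chrom}:{record.pos}; "
                "mutation retained unflagged",
                stacklevel=2,
            )
            continue
        if counts.alt == 0:
            continue  # no alt reads can never be flagged
        if mutation_score(counts, mu_f, mu_r, rho) > log_bf_cut:
            catalog.chip.add(j)
    return catalog
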
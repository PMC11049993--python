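"""Panel-of-normals error model.

Healthy-donor cfDNA samples carry no tumor mutations, so every non-reference
call in them is an error.  Pooling the panel of normals (PON) per
(position, allele, strand) yields a locus-specific error rate ``mu``;
between-sample variation at the same locus yields a beta-binomial
overdispersion ``rho`` via a method-of-moments estimate in the Shearwater
lineage.  A trinucleotide-context profile summarizes how error rates vary by
substitution type and flanking bases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    DEL_COL,
    INS_COL,
    N_ALLELES,
    CountTable,
    MutationRecord,
    PanelDef,
    round_half_away,
)

DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_RHO_BOUNDS = (1e-6, 0.1)

#: thresholds of the exceedance summary (0.001% and 0.01% error rate)
EXCEEDANCE_THRESHOLDS = (1e-5, 1e-4)

_PYRIMIDINE_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def pool_pon(
    pon: list[CountTable], locus_idx: int, allele_col: int
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Pool PON counts at one (position, allele) by simple summation.

    Returns ``((alt_fwd, total_fwd), (alt_rev, total_rev))``.
    """
    af = sum(int(t.alt_fwd[locus_idx, allele_col]) for t in pon)
    ar = sum(int(t.alt_rev[locus_idx, allele_col]) for t in pon)
    df = sum(int(t.depth_fwd[locus_idx]) for t in pon)
    dr = sum(int(t.depth_rev[locus_idx]) for t in pon)
    return (af, df), (ar, dr)


def estimate_error_rate(
    pooled: tuple[int, int], pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> float:
    """Error rate from pooled (alt, total) counts with a symmetric pseudocount."""
    alt, total = pooled
    if total <= 0:
        raise ValueError("pooled total depth must be positive")
    return (alt + pseudocount) / (total + 2.0 * pseudocount)


def _mom_dispersion(
    x: np.ndarray, n: np.ndarray, bounds: tuple[float, float]
) -> float:
    """Weighted method-of-moments intraclass-correlation estimate.

    Classical ANOVA-type estimator for overdispersed binomial counts with
    unequal denominators; degenerate inputs collapse to the lower bound.
    """
    keep = n > 0
    x, n = x[keep].astype(float), n[keep].astype(float)
    m = len(n)
    if m < 2:
        return bounds[0]
    N = n.sum()
    p = x.sum() / N
    if p <= 0.0 or p >= 1.0:
        return bounds[0]
    chi2 = float((((x - n * p) ** 2) / (n * p * (1.0 - p))).sum())
    nbar = (N - (n**2).sum() / N) / (m - 1)
    if nbar <= 1.0:
        return bounds[0]
    rho = (chi2 / (m - 1) - 1.0) / (nbar - 1.0)
    return float(np.clip(rho, bounds[0], bounds[1]))


def estimate_dispersion(
    per_sample_alt: np.ndarray,
    per_sample_depth: np.ndarray,
    bounds: tuple[float, float] = DEFAULT_RHO_BOUNDS,
) -> float:
    """Beta-binomial overdispersion across PON samples at one locus-allele.

    Order-invariant; all-zero alt counts (no observable variation) return
    the lower truncation bound.
    """
    if (per_sample_depth > 0).sum() < 2:
        raise ValueError("need >= 2 PON samples with positive depth")
    return _mom_dispersion(
        np.asarray(per_sample_alt), np.asarray(per_sample_depth), bounds
    )


@dataclass
class ErrorModel:
    """PON-derived error rates and dispersions over the whole panel.

    Arrays have shape (L, 5) on the allele axis (three substitutions, then
    insertion and deletion).  ``mu_*`` include the pseudocount; ``rho`` is
    truncated to ``rho_bounds``.  Positions with zero pooled depth on either
    strand are unmodelable and excluded from the random-catalog pool.
    """

    panel: PanelDef
    mu_fwd: np.ndarray
    mu_rev: np.ndarray
    rho: np.ndarray
    pooled_alt_fwd: np.ndarray
    pooled_alt_rev: np.ndarray
    pooled_depth_fwd: np.ndarray  # (L,)
    pooled_depth_rev: np.ndarray
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    rho_bounds: tuple[float, float] = DEFAULT_RHO_BOUNDS

    @property
    def modelable(self) -> np.ndarray:
        """Boolean (L,) mask of positions with pooled depth on both strands."""
        return (self.pooled_depth_fwd > 0) & (self.pooled_depth_rev > 0)

    def params_at(self, locus_idx: int, allele_col: int) -> tuple[float, float, float]:
        """(mu_fwd, mu_rev, rho) at one (position, allele)."""
        return (
            float(self.mu_fwd[locus_idx, allele_col]),
            float(self.mu_rev[locus_idx, allele_col]),
            float(self.rho[locus_idx, allele_col]),
        )

    def params_for(self, record: MutationRecord) -> tuple[float, float, float]:
        """(mu_fwd, mu_rev, rho) for a mutation of any class.

        Composite events (MNV/PHASED) use the mean of the constituent
        substitutions' pooled counts (rounded to integers) re-normalized
        with the pseudocount, and the mean dispersion.
        """
        panel = self.panel
        if record.variant_class in ("SNV", "INS", "DEL"):
            idx = panel.locus_index(record.chrom, record.pos)
            return self.params_at(idx, panel.allele_column(idx, record))
        alts_f, alts_r, dep_f, dep_r, rhos = [], [], [], [], []
        for offset, pos1 in enumerate(record.spans):
            idx = panel.locus_index(record.chrom, pos1)
            if record.variant_class == "MNV" and offset < len(record.alt):
                cols = np.where(panel.alt_bases[idx] == record.alt[offset])[0]
                col = int(cols[0]) if len(cols) else 0
            else:
                col = 0
            alts_f.append(self.pooled_alt_fwd[idx, col])
            alts_r.append(self.pooled_alt_rev[idx, col])
            dep_f.append(self.pooled_depth_fwd[idx])
            dep_r.append(self.pooled_depth_rev[idx])
            rhos.append(self.rho[idx, col])
        pc = self.pseudocount
        af = round_half_away(float(np.mean(alts_f)))
        ar = round_half_away(float(np.mean(alts_r)))
        df = round_half_away(float(np.mean(dep_f)))
        dr = round_half_away(float(np.mean(dep_r)))
        return (
            (af + pc) / (df + 2 * pc),
            (ar + pc) / (dr + 2 * pc),
            float(np.mean(rhos)),
        )


def build_error_model(
    pon: list[CountTable],
    panel: PanelDef,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    rho_bounds: tuple[float, float] = DEFAULT_RHO_BOUNDS,
    strand_pooled: bool = False,
) -> ErrorModel:
    """Estimate the error model from a panel of normals.

    ``strand_pooled=True`` replaces the per-strand rates with the combined
    rate on both strands (the Bayes factor is strand-aware, so the
    per-strand default is usually what you want).
    """
    if len(pon) < 2:
        raise ValueError("need >= 2 PON samples")
    S, L = len(pon), panel.size
    alt_f = np.stack([t.alt_fwd for t in pon])  # (S, L, A)
    alt_r = np.stack([t.alt_rev for t in pon])
    dep_f = np.stack([t.depth_fwd for t in pon])  # (S, L)
    dep_r = np.stack([t.depth_rev for t in pon])

    pooled_af = alt_f.sum(axis=0)
    pooled_ar = alt_r.sum(axis=0)
    pooled_df = dep_f.sum(axis=0)
    pooled_dr = dep_r.sum(axis=0)

    pc = pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        if strand_pooled:
            tot = (pooled_df + pooled_dr)[:, None]
            mu = (pooled_af + pooled_ar + pc) / (tot + 2 * pc)
            mu_f = mu_r = mu
        else:
            mu_f = (pooled_af + pc) / (pooled_df[:, None] + 2 * pc)
            mu_r = (pooled_ar + pc) / (pooled_dr[:, None] + 2 * pc)
    mu_f = np.where(pooled_df[:, None] > 0, mu_f, 0.0)
    mu_r = np.where(pooled_dr[:, None] > 0, mu_r, 0.0)

    # vectorized method-of-moments dispersion across samples, both strands
    # of a sample combined (one biological replicate per donor)
    x = (alt_f + alt_r).astype(float)  # (S, L, A)
    n = (dep_f + dep_r).astype(float)[:, :, None]  # (S, L, 1)
    n = np.broadcast_to(n, x.shape)
    live = n > 0
    m = live.sum(axis=0)  # (L, A)
    N = n.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = x.sum(axis=0) / N
        chi2 = np.where(live, (x - n * p) ** 2 / (n * p * (1.0 - p)), 0.0).sum(axis=0)
        nbar = (N - (n**2).sum(axis=0) / N) / (m - 1)
        rho = (chi2 / (m - 1) - 1.0) / (nbar - 1.0)
    bad = (
        ~np.isfinite(rho)
        | (m < 2)
        | (p <= 0.0)
        | (p >= 1.0)
        | (nbar <= 1.0)
    )
    rho = np.where(bad, rho_bounds[0], rho)
    rho = np.clip(rho, rho_bounds[0], rho_bounds[1])

    return ErrorModel(
        panel=panel,
        mu_fwd=mu_f,
        mu_rev=mu_r,
        rho=rho,
        pooled_alt_fwd=pooled_af,
        pooled_alt_rev=pooled_ar,
        pooled_depth_fwd=pooled_df,
        pooled_depth_rev=pooled_dr,
        pseudocount=pc,
        rho_bounds=rho_bounds,
    )


def substitution_label(ref: str, alt: str) -> str:
    return f"{ref}>{alt}"


def context_class(ctx5: str, ref: str, alt: str, ctx3: str) -> str:
    """Pyrimidine-collapsed trinucleotide context class, e.g. ``A(C>T)G``.

    Substitutions at purine reference bases are reverse-complemented so each
    of the 96 classes is centered on C or T.
    """
    if ref in "AG":
        rc = _PYRIMIDINE_COMPLEMENT
        ctx5, ctx3 = rc[ctx3], rc[ctx5]
        ref, alt = rc[ref], rc[alt]
    return f"{ctx5}({ref}>{alt}){ctx3}"


def _site_rates(model: ErrorModel) -> np.ndarray:
    """Per (position, allele) strand-combined ML error rate (no pseudocount)."""
    tot = (model.pooled_depth_fwd + model.pooled_depth_rev).astype(float)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = (model.pooled_alt_fwd + model.pooled_alt_rev) / tot
    return np.where(tot > 0, rates, np.nan)


def context_profile(model: ErrorModel) -> pd.DataFrame:
    """Mean error rate per (substitution, trinucleotide-context) class.

    Returns one row per observed pyrimidine-collapsed class (96 possible);
    classes with zero panel sites are absent, not zero.  Columns:
    ``context_class``, ``substitution``, ``ctx5``, ``ctx3``, ``n_sites``,
    ``mean_rate``, ``median_rate``.
    """
    panel = model.panel
    rates = _site_rates(model)
    rows = []
    for i in range(panel.size):
        if not model.modelable[i]:
            continue
        for col in range(3):
            rows.append(
                (
                    context_class(
                        panel.ctx5[i], panel.ref[i], panel.alt_bases[i, col], panel.ctx3[i]
                    ),
                    substitution_label(panel.ref[i], panel.alt_bases[i, col]),
                    rates[i, col],
                )
            )
    df = pd.DataFrame(rows, columns=["context_class", "substitution", "rate"])
    out = (
        df.groupby("context_class")
        .agg(
            n_sites=("rate", "size"),
            mean_rate=("rate", "mean"),
            median_rate=("rate", "median"),
        )
        .reset_index()
    )
    out["ctx5"] = out["context_class"].str[0]
    out["ctx3"] = out["context_class"].str[-1]
    out["substitution"] = out["context_class"].str[2:5]
    return out.sort_values("context_class", ignore_index=True)


def exceedance_fractions(
    model: ErrorModel, thresholds: tuple[float, ...] = EXCEEDANCE_THRESHOLDS
) -> pd.DataFrame:
    """Fraction of sites above each error-rate threshold per substitution.

    Substitutions are the 12 strand-specific single-base changes plus
    ``ins`` and ``del``.  Mirrors the exceedance summary used to
    characterize the panel error profile (sites above 0.001% and 0.01%).
    """
    panel = model.panel
    rates = _site_rates(model)
    keep = model.modelable
    rows = []
    labels = []
    for i in np.flatnonzero(keep):
        for col in range(N_ALLELES):
            if col < 3:
                lab = substitution_label(panel.ref[i], panel.alt_bases[i, col])
            elif col == INS_COL:
                lab = "ins"
            else:
                lab = "del"
            labels.append(lab)
            rows.append(rates[i, col])
    df = pd.DataFrame({"substitution": labels, "rate": rows})
    agg: dict[str, object] = {"n_sites": ("rate", "size")}
    for thr in thresholds:
        agg[f"frac_above_{thr:g}"] = (
            "rate",
            lambda r, thr=thr: float((r > thr).mean()),
        )
    return df.groupby("substitution").agg(**agg).reset_index()
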
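"""Core domain types shared by every stage of the pipeline.

The central abstraction is the strand-split count vector: every mutation,
regardless of class (SNV, INDEL, MNV, phased), is reduced to four consensus
read counts at its locus — variant-supporting reads on the forward and
reverse strand (``alt_fwd``/``alt_rev``) and non-supporting reads on each
strand (``other_fwd``/``other_rev``).  All downstream statistics (error
model, Bayes factors, sample score) operate on these vectors.

Coordinates follow the two conventions of the interchange formats: panel
regions are 0-based half-open (BED), mutation records are 1-based (VCF).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

import numpy as np

DEFAULT_PANEL_SIZE = 15_465  # bp covered by the CRC capture panel
DEFAULT_K = 100_000  # random catalogs behind the rank score S

VariantClass = Literal["SNV", "INS", "DEL", "MNV", "PHASED"]

BASES = ("A", "C", "G", "T")
_BASE_IDX = {b: i for i, b in enumerate(BASES)}

#: allele-axis layout of count/rate matrices: the three non-reference bases
#: (in alphabetical order) followed by single-base insertion and deletion.
N_ALLELES = 5
INS_COL = 3
DEL_COL = 4


class UncallablePatientError(ValueError):
    """Raised when a patient has no usable (panel-overlapping, non-flagged)
    mutations, mirroring the exclusion of patients whose tumor mutations do
    not overlap the capture panel."""


def round_half_away(x: float | np.ndarray) -> np.ndarray | int:
    """Round half away from zero (0.5 -> 1), as required when averaging
    integer counts across the loci of a multi-base event."""
    r = np.sign(x) * np.floor(np.abs(x) + 0.5)
    if np.isscalar(x) or np.ndim(x) == 0:
        return int(r)
    return r.astype(np.int64)


def pos0_to_pos1(pos0: int) -> int:
    """0-based coordinate -> 1-based (VCF) coordinate."""
    return pos0 + 1


def pos1_to_pos0(pos1: int) -> int:
    """1-based (VCF) coordinate -> 0-based coordinate."""
    return pos1 - 1


# ---------------------------------------------------------------------------
# Panel


@dataclass
class PanelDef:
    """Definition of the fixed capture panel.

    Parameters
    ----------
    regions
        ``(chrom, start, end)`` half-open 0-based intervals.
    chrom, pos
        Per covered position: chromosome name and 1-based coordinate.
    ref
        Reference base per position (one of ``ACGT``).
    ctx5, ctx3
        The 5' and 3' neighboring reference bases (trinucleotide context).
    """

    regions: list[tuple[str, int, int]]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    ctx5: np.ndarray
    ctx3: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.pos)
        for arr in (self.chrom, self.ref, self.ctx5, self.ctx3):
            if len(arr) != n:
                raise ValueError("panel arrays must have equal length")
        covered = sum(e - s for _, s, e in self.regions)
        if covered != n:
            raise ValueError(
                f"regions cover {covered} bp but {n} positions given"
            )
        keys = list(zip(self.chrom.tolist(), self.pos.tolist()))
        if len(set(keys)) != n:
            raise ValueError("duplicate panel positions")
        self._index = {k: i for i, k in enumerate(keys)}
        # substitution alleles: the three non-reference bases per position,
        # alphabetical, as columns 0..2 of the allele axis
        ref_idx = np.array([_BASE_IDX[b] for b in self.ref])
        alts = np.empty((n, 3), dtype="U1")
        for i, r in enumerate(ref_idx):
            alts[i] = [b for j, b in enumerate(BASES) if j != r]
        self.alt_bases = alts

    @property
    def size(self) -> int:
        return len(self.pos)

    def locus_index(self, chrom: str, pos1: int) -> int:
        """Index of a 1-based locus in the panel arrays (KeyError if absent)."""
        return self._index[(chrom, pos1)]

    def contains(self, chrom: str, pos1: int) -> bool:
        return (chrom, pos1) in self._index

    def allele_column(self, locus_idx: int, record: "MutationRecord") -> int:
        """Column on the allele axis for a mutation at ``locus_idx``."""
        if record.variant_class == "SNV":
            cols = np.where(self.alt_bases[locus_idx] == record.alt)[0]
            if len(cols) == 0:
                raise ValueError(
                    f"alt {record.alt!r} equals the reference base at "
                    f"{record.chrom}:{record.pos}"
                )
            return int(cols[0])
        if record.variant_class == "INS":
            return INS_COL
        if record.variant_class == "DEL":
            return DEL_COL
        raise ValueError(
            f"{record.variant_class} has no single allele column; use the "
            "composite (per-locus mean) path"
        )

    def context_string(self, locus_idx: int) -> str:
        return f"{self.ctx5[locus_idx]}{self.ref[locus_idx]}{self.ctx3[locus_idx]}"


# ---------------------------------------------------------------------------
# Mutations and catalogs


@dataclass
class MutationRecord:
    """One tumor-informed variant searched for in plasma/PBMC counts."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    variant_class: VariantClass
    patient_id: str = ""
    context: str | None = None  # trinucleotide, SNV only
    tumor_af: float | None = None
    constituent_loci: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        vc = self.variant_class
        if vc == "SNV" and not (len(self.ref) == len(self.alt) == 1):
            raise ValueError("SNV requires single-base ref and alt")
        if vc == "INS" and not len(self.alt) > len(self.ref):
            raise ValueError("INS requires |alt| > |ref|")
        if vc == "DEL" and not len(self.ref) > len(self.alt):
            raise ValueError("DEL requires |ref| > |alt|")
        if vc == "PHASED" and len(self.constituent_loci) < 2:
            raise ValueError("PHASED requires >= 2 constituent loci")
        if vc == "MNV" and not self.constituent_loci:
            # default: the spanned reference positions
            self.constituent_loci = list(
                range(self.pos, self.pos + len(self.ref))
            )
        if self.tumor_af is not None and not 0 <= self.tumor_af <= 1:
            raise ValueError("tumor_af must lie in [0, 1]")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.alt)

    @property
    def spans(self) -> list[int]:
        """1-based positions whose counts enter this mutation's vector."""
        if self.variant_class in ("MNV", "PHASED") and self.constituent_loci:
            return list(self.constituent_loci)
        return [self.pos]


def infer_variant_class(ref: str, alt: str) -> VariantClass:
    """Classify a (ref, alt) pair by the VCF length rules."""
    if len(ref) == len(alt) == 1:
        return "SNV"
    if len(alt) > len(ref):
        return "INS"
    if len(ref) > len(alt):
        return "DEL"
    return "MNV"


@dataclass
class MutationCatalog:
    """A patient's tumor-informed mutation catalog with filter flags."""

    patient_id: str
    mutations: list[MutationRecord]
    blacklisted: set[int] = field(default_factory=set)
    chip: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.mutations:
            raise UncallablePatientError(
                f"patient {self.patient_id!r} has no panel-overlapping mutations"
            )
        keys = [(m.chrom, m.pos, m.alt) for m in self.mutations]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (locus, alt) pairs in catalog")

    def __len__(self) -> int:
        return len(self.mutations)

    def __iter__(self) -> Iterator[MutationRecord]:
        return iter(self.mutations)

    def retained_indices(self) -> list[int]:
        """Indices of mutations that survive blacklist and CHIP filtering."""
        dropped = self.blacklisted | self.chip
        return [i for i in range(len(self.mutations)) if i not in dropped]

    def retained(self) -> list[MutationRecord]:
        return [self.mutations[i] for i in self.retained_indices()]


# ---------------------------------------------------------------------------
# Counts


@dataclass(frozen=True)
class CountVector:
    """Strand-split consensus counts at one mutation.

    ``alt_*`` are reads supporting the variant; ``other_*`` are all other
    reads on that strand, so ``depth = alt + other`` per strand.
    """

    alt_fwd: int
    alt_rev: int
    other_fwd: int
    other_rev: int

    def __post_init__(self) -> None:
        for v in (self.alt_fwd, self.alt_rev, self.other_fwd, self.other_rev):
            if v < 0:
                raise ValueError("counts must be non-negative")

    @property
    def depth_fwd(self) -> int:
        return self.alt_fwd + self.other_fwd

    @property
    def depth_rev(self) -> int:
        return self.alt_rev + self.other_rev

    @property
    def depth(self) -> int:
        return self.depth_fwd + self.depth_rev

    @property
    def alt(self) -> int:
        return self.alt_fwd + self.alt_rev

    def af(self) -> float:
        return self.alt / self.depth if self.depth else 0.0


class CountTable:
    """Panel-wide strand-split counts for one sample.

    Arrays are aligned to a :class:`PanelDef`:

    - ``depth_fwd``, ``depth_rev`` — per-position strand depths, shape (L,)
    - ``alt_fwd``, ``alt_rev`` — per (position, allele) variant-supporting
      counts, shape (L, 5); allele columns are the three non-reference bases
      followed by insertion and deletion.
    """

    def __init__(
        self,
        panel: PanelDef,
        depth_fwd: np.ndarray,
        depth_rev: np.ndarray,
        alt_fwd: np.ndarray,
        alt_rev: np.ndarray,
        sample_id: str = "",
    ) -> None:
        L = panel.size
        if depth_fwd.shape != (L,) or depth_rev.shape != (L,):
            raise ValueError("depth arrays must have shape (L,)")
        if alt_fwd.shape != (L, N_ALLELES) or alt_rev.shape != (L, N_ALLELES):
            raise ValueError(f"alt arrays must have shape (L, {N_ALLELES})")
        if (alt_fwd > depth_fwd[:, None]).any() or (
            alt_rev > depth_rev[:, None]
        ).any():
            raise ValueError("alt counts exceed strand depth")
        if (depth_fwd < 0).any() or (depth_rev < 0).any():
            raise ValueError("negative depths")
        self.panel = panel
        self.depth_fwd = depth_fwd.astype(np.int64)
        self.depth_rev = depth_rev.astype(np.int64)
        self.alt_fwd = alt_fwd.astype(np.int64)
        self.alt_rev = alt_rev.astype(np.int64)
        self.sample_id = sample_id
        #: extra rows for composite events (PHASED) keyed by mutation key
        self.extra: dict[tuple[str, int, str], CountVector] = {}

    def count_vector(self, locus_idx: int, allele_col: int) -> CountVector:
        af, ar = self.alt_fwd[locus_idx, allele_col], self.alt_rev[locus_idx, allele_col]
        return CountVector(
            alt_fwd=int(af),
            alt_rev=int(ar),
            other_fwd=int(self.depth_fwd[locus_idx] - af),
            other_rev=int(self.depth_rev[locus_idx] - ar),
        )

    def mutation_counts(self, record: MutationRecord) -> CountVector:
        """Count vector for a mutation of any class.

        Multi-base events (MNV/PHASED without a dedicated row) use the mean
        of per-position counts across the spanned loci, rounded half away
        from zero before likelihood evaluation.
        """
        if record.key in self.extra:
            return self.extra[record.key]
        panel = self.panel
        if record.variant_class in ("SNV", "INS", "DEL"):
            idx = panel.locus_index(record.chrom, record.pos)
            return self.count_vector(idx, panel.allele_column(idx, record))
        # composite: mean over constituent loci of the corresponding
        # substitution columns (MNV) or all-substitution mean (PHASED)
        vecs = []
        for offset, pos1 in enumerate(record.spans):
            idx = panel.locus_index(record.chrom, pos1)
            if record.variant_class == "MNV" and offset < len(record.alt):
                alt_base = record.alt[offset]
                cols = np.where(panel.alt_bases[idx] == alt_base)[0]
                col = int(cols[0]) if len(cols) else 0
            else:
                col = 0
            vecs.append(self.count_vector(idx, col))
        return CountVector(
            alt_fwd=round_half_away(float(np.mean([v.alt_fwd for v in vecs]))),
            alt_rev=round_half_away(float(np.mean([v.alt_rev for v in vecs]))),
            other_fwd=round_half_away(float(np.mean([v.other_fwd for v in vecs]))),
            other_rev=round_half_away(float(np.mean([v.other_rev for v in vecs]))),
        )


# ---------------------------------------------------------------------------
# Results


@dataclass
class SampleScore:
    """Sample-level result of the rank-based caller."""

    m_scores: np.ndarray  # per-mutation log Bayes factors (retained catalog)
    s: float  # integrated score, log space
    r: int  # random catalog scores strictly greater than s
    K: int
    alpha: float
    caf: float

    def __post_init__(self) -> None:
        if not 0 <= self.r <= self.K:
            raise ValueError("r must lie in [0, K]")
        if not 0 <= self.alpha < 1:
            raise ValueError("alpha must lie in [0, 1)")

    @property
    def S(self) -> float:
        """Empirical rank score: S = 1 - (r + 1) / (K + 1), in [0, 1)."""
        return 1.0 - (self.r + 1) / (self.K + 1)

    @property
    def call(self) -> bool:
        """ctDNA-positive iff S strictly exceeds the threshold."""
        return self.S > self.alpha


@dataclass
class LODResult:
    """Limit-of-detection summary at a fixed specificity and power."""

    lod: float | None  # minimal detectable AF (or sample cAF); None if undefined
    depth: float
    specificity: float
    power: float
    interval: tuple[float, float] | None = None  # bracketing interval (MC mode)
    call_rate: float | None = None  # call fraction at `lod` (MC mode)


# ---------------------------------------------------------------------------
# Simulator configuration


@dataclass
class SyntheticCohortSpec:
    """Parameters of the synthetic cohort generator.

    Defaults mirror the study conditions: a 46-sample panel of normals at
    ~9,086x median depth, 126 patients and 37 healthy controls for training,
    catalog sizes with median 3 (IQR 2), deletion/insertion/MNV carrier
    frequencies of 48%/22%/9%, 3.4% CHIP prevalence with PBMC AFs below 1%,
    and patient cAFs log-uniform in [0.01%, 1%].
    """

    seed: int
    n_pon: int = 46
    n_patients: int = 126
    n_healthy: int = 37
    panel_size: int = DEFAULT_PANEL_SIZE
    gc_fraction: float = 0.5
    depth_median: float = 9_086.0
    depth_sigma: float = 0.35  # lognormal sd of per-sample mean depth
    catalog_size_dist: dict[int, float] = field(
        default_factory=lambda: {
            1: 0.10, 2: 0.20, 3: 0.30, 4: 0.20, 5: 0.10, 6: 0.05, 7: 0.03, 8: 0.02,
        }
    )
    deletion_carrier_freq: float = 0.48
    insertion_carrier_freq: float = 0.22
    mnv_carrier_freq: float = 0.09
    chip_prevalence: float = 0.034
    chip_af_range: tuple[float, float] = (0.001, 0.01)
    caf_range: tuple[float, float] = (1e-4, 1e-2)  # log-uniform
    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for f in (
            self.deletion_carrier_freq,
            self.insertion_carrier_freq,
            self.mnv_carrier_freq,
            self.chip_prevalence,
            self.gc_fraction,
        ):
            if not 0 <= f <= 1:
                raise ValueError("frequencies must lie in [0, 1]")
        total = sum(self.catalog_size_dist.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError("catalog size distribution must sum to 1")


def empirical_quantile(dist: dict[int, float], q: float) -> int:
    """Quantile of a discrete size distribution (smallest size with CDF >= q)."""
    c = 0.0
    for size in sorted(dist):
        c += dist[size]
        if c >= q - 1e-12:
            return size
    return max(dist)
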
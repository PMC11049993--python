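"""Readers and writers for the interchange formats, plus the optional BAM
count extractor and a minimal UMI-family consensus collapser.

The canonical interchange format is the strand-split count table (TSV, one
row per position-allele); BAM extraction is an adapter on top of it so the
statistical core stays testable without alignment data.  Catalogs travel as
VCF (one per patient), panels as a TSV with reference base and trinucleotide
context (derivable from BED + FASTA).
"""

from __future__ import annotations

import json
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .model import (
    DEL_COL,
    INS_COL,
    N_ALLELES,
    CountTable,
    MutationCatalog,
    MutationRecord,
    PanelDef,
    UncallablePatientError,
    infer_variant_class,
)
from .error_model import ErrorModel

INS_TOKEN = "<INS>"
DEL_TOKEN = "<DEL>"

COUNT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "class",
    "alt_fwd", "alt_rev", "other_fwd", "other_rev", "sample_id",
]


# ---------------------------------------------------------------------------
# Panel

def write_panel(panel: PanelDef, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "chrom": panel.chrom,
            "pos": panel.pos,
            "ref": panel.ref,
            "ctx5": panel.ctx5,
            "ctx3": panel.ctx3,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_panel(path: str | Path) -> PanelDef:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    regions = _regions_from_positions(df["chrom"].to_numpy(), df["pos"].to_numpy())
    return PanelDef(
        regions=regions,
        chrom=df["chrom"].to_numpy(dtype="U32"),
        pos=df["pos"].to_numpy(dtype=np.int64),
        ref=df["ref"].to_numpy(dtype="U1"),
        ctx5=df["ctx5"].to_numpy(dtype="U1"),
        ctx3=df["ctx3"].to_numpy(dtype="U1"),
    )


def _regions_from_positions(chrom: np.ndarray, pos: np.ndarray):
    """Reconstruct half-open 0-based regions from sorted covered positions."""
    regions = []
    start = prev = None
    cur_chrom = None
    for c, p in zip(chrom, pos):
        if cur_chrom == c and prev is not None and p == prev + 1:
            prev = p
            continue
        if start is not None:
            regions.append((cur_chrom, start - 1, prev))
        cur_chrom, start, prev = c, int(p), int(p)
    if start is not None:
        regions.append((cur_chrom, start - 1, prev))
    return regions


def write_panel_bed(panel: PanelDef, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in panel.regions:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_panel_bed(bed_path: str | Path, fasta_path: str | Path) -> PanelDef:
    """Panel from a BED file plus a reference FASTA (contexts from sequence)."""
    from pyfaidx import Fasta

    fasta = Fasta(str(fasta_path))
    regions, chroms, poss, refs, c5s, c3s = [], [], [], [], [], []
    with open(bed_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end = line.split()[:3]
            start, end = int(start), int(end)
            regions.append((chrom, start, end))
            seq = str(fasta[chrom][max(start - 1, 0) : end + 1]).upper()
            offset = 1 if start > 0 else 0
            for i in range(end - start):
                chroms.append(chrom)
                poss.append(start + i + 1)
                refs.append(seq[i + offset])
                c5s.append(seq[i + offset - 1] if i + offset - 1 >= 0 else "N")
                c3s.append(
                    seq[i + offset + 1] if i + offset + 1 < len(seq) else "N"
                )
    return PanelDef(
        regions=regions,
        chrom=np.array(chroms, dtype="U32"),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype="U1"),
        ctx5=np.array(c5s, dtype="U1"),
        ctx3=np.array(c3s, dtype="U1"),
    )


# ---------------------------------------------------------------------------
# Count tables

def _allele_token(panel: PanelDef, i: int, col: int) -> tuple[str, str]:
    if col < 3:
        return panel.alt_bases[i, col], "SNV"
    if col == INS_COL:
        return INS_TOKEN, "INS"
    return DEL_TOKEN, "DEL"


def count_table_to_frame(table: CountTable) -> pd.DataFrame:
    panel = table.panel
    rows = []
    for i in range(panel.size):
        for col in range(N_ALLELES):
            alt, vc = _allele_token(panel, i, col)
            af, ar = int(table.alt_fwd[i, col]), int(table.alt_rev[i, col])
            rows.append(
                (
                    panel.chrom[i], int(panel.pos[i]), panel.ref[i], alt, vc,
                    af, ar,
                    int(table.depth_fwd[i]) - af, int(table.depth_rev[i]) - ar,
                    table.sample_id,
                )
            )
    for (chrom, pos, alt), vec in sorted(table.extra.items()):
        rows.append(
            (
                chrom, pos, ".", alt, "PHASED",
                vec.alt_fwd, vec.alt_rev, vec.other_fwd, vec.other_rev,
                table.sample_id,
            )
        )
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


def write_count_table(table: CountTable, path: str | Path) -> None:
    count_table_to_frame(table).to_csv(path, sep="\t", index=False)


def read_count_table(path: str | Path, panel: PanelDef) -> CountTable:
    from .model import CountVector

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "alt": str}).rename(
        columns={"class": "vclass"}
    )
    L = panel.size
    alt_f = np.zeros((L, N_ALLELES), dtype=np.int64)
    alt_r = np.zeros((L, N_ALLELES), dtype=np.int64)
    depth_f = np.zeros(L, dtype=np.int64)
    depth_r = np.zeros(L, dtype=np.int64)
    sample_id = str(df["sample_id"].iloc[0]) if len(df) else ""
    extra = {}
    for row in df.itertuples(index=False):
        if row.vclass == "PHASED":
            extra[(row.chrom, int(row.pos), row.alt)] = CountVector(
                int(row.alt_fwd), int(row.alt_rev),
                int(row.other_fwd), int(row.other_rev),
            )
            continue
        i = panel.locus_index(row.chrom, int(row.pos))
        if row.alt == INS_TOKEN:
            col = INS_COL
        elif row.alt == DEL_TOKEN:
            col = DEL_COL
        else:
            col = int(np.where(panel.alt_bases[i] == row.alt)[0][0])
        alt_f[i, col] = row.alt_fwd
        alt_r[i, col] = row.alt_rev
        df_here = row.alt_fwd + row.other_fwd
        dr_here = row.alt_rev + row.other_rev
        if depth_f[i] and depth_f[i] != df_here:
            raise ValueError(f"inconsistent forward depth at {row.chrom}:{row.pos}")
        if depth_r[i] and depth_r[i] != dr_here:
            raise ValueError(f"inconsistent reverse depth at {row.chrom}:{row.pos}")
        depth_f[i], depth_r[i] = df_here, dr_here
    table = CountTable(panel, depth_f, depth_r, alt_f, alt_r, sample_id=sample_id)
    table.extra = extra
    return table


# ---------------------------------------------------------------------------
# Error model

def write_error_model(model: ErrorModel, path: str | Path) -> None:
    panel = model.panel
    rows = []
    for i in range(panel.size):
        for col in range(N_ALLELES):
            alt, _ = _allele_token(panel, i, col)
            for strand, mu, alt_c, dep in (
                ("+", model.mu_fwd[i, col], model.pooled_alt_fwd[i, col], model.pooled_depth_fwd[i]),
                ("-", model.mu_rev[i, col], model.pooled_alt_rev[i, col], model.pooled_depth_rev[i]),
            ):
                rows.append(
                    (
                        panel.chrom[i], int(panel.pos[i]), panel.ref[i], alt,
                        strand, float(mu), float(model.rho[i, col]),
                        int(alt_c), int(dep),
                    )
                )
    pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "strand", "mu", "rho",
            "pooled_alt", "pooled_depth",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_error_model(path: str | Path, panel: PanelDef) -> ErrorModel:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "alt": str})
    L = panel.size
    mu_f = np.zeros((L, N_ALLELES))
    mu_r = np.zeros((L, N_ALLELES))
    rho = np.full((L, N_ALLELES), 1e-6)
    p_af = np.zeros((L, N_ALLELES), dtype=np.int64)
    p_ar = np.zeros((L, N_ALLELES), dtype=np.int64)
    p_df = np.zeros(L, dtype=np.int64)
    p_dr = np.zeros(L, dtype=np.int64)
    for row in df.itertuples(index=False):
        i = panel.locus_index(row.chrom, int(row.pos))
        if row.alt == INS_TOKEN:
            col = INS_COL
        elif row.alt == DEL_TOKEN:
            col = DEL_COL
        else:
            col = int(np.where(panel.alt_bases[i] == row.alt)[0][0])
        rho[i, col] = row.rho
        if row.strand == "+":
            mu_f[i, col] = row.mu
            p_af[i, col] = row.pooled_alt
            p_df[i] = row.pooled_depth
        else:
            mu_r[i, col] = row.mu
            p_ar[i, col] = row.pooled_alt
            p_dr[i] = row.pooled_depth
    return ErrorModel(
        panel=panel, mu_fwd=mu_f, mu_rev=mu_r, rho=rho,
        pooled_alt_fwd=p_af, pooled_alt_rev=p_ar,
        pooled_depth_fwd=p_df, pooled_depth_rev=p_dr,
    )


# ---------------------------------------------------------------------------
# Blacklist

def write_blacklist(
    blacklist: list[tuple[int, int]], panel: PanelDef, path: str | Path
) -> None:
    rows = [
        (panel.chrom[i], int(panel.pos[i]), panel.ref[i], panel.alt_bases[i, c])
        for i, c in sorted(blacklist)
    ]
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"]).to_csv(
        path, sep="\t", index=False
    )


def read_blacklist(path: str | Path, panel: PanelDef) -> list[tuple[int, int]]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = []
    for row in df.itertuples(index=False):
        i = panel.locus_index(row.chrom, int(row.pos))
        out.append((i, int(np.where(panel.alt_bases[i] == row.alt)[0][0])))
    return sorted(out)


# ---------------------------------------------------------------------------
# Catalog VCF

def write_catalog_vcf(catalog: MutationCatalog, path: str | Path, panel: PanelDef) -> None:
    header = pysam.VariantHeader()
    header.add_meta("source", "umiseq")
    for chrom in dict.fromkeys(panel.chrom.tolist()):
        end = max(e for c, _, e in panel.regions if c == chrom)
        header.contigs.add(chrom, length=end + 10_000)
    header.info.add("VCLASS", 1, "String", "Variant class")
    header.info.add("PGROUP", 1, "String", "Phased group identifier")
    header.info.add("TAF", 1, "Float", "Tumor allele fraction")
    header.info.add("CLOCI", ".", "Integer", "Constituent loci (1-based)")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for rec in sorted(catalog, key=lambda m: (m.chrom, m.pos)):
            site = vcf.new_record(
                contig=rec.chrom, start=rec.pos - 1,
                alleles=(rec.ref or ".", rec.alt or "."),
            )
            site.info["VCLASS"] = rec.variant_class
            if rec.tumor_af is not None:
                site.info["TAF"] = rec.tumor_af
            if rec.variant_class in ("MNV", "PHASED"):
                site.info["CLOCI"] = rec.constituent_loci
            if rec.variant_class == "PHASED":
                site.info["PGROUP"] = f"{catalog.patient_id}_pg"
            vcf.write(site)


def read_catalog_vcf(
    path: str | Path, panel: PanelDef, patient_id: str | None = None
) -> MutationCatalog:
    """Patient catalog from VCF; records outside the panel are dropped with
    a warning, and a patient with zero in-panel mutations is rejected."""
    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for site in vcf:
            ref = site.ref
            alt = site.alts[0] if site.alts else ""
            vclass = site.info.get("VCLASS") or infer_variant_class(ref, alt)
            pos1 = site.pos
            cloci = list(site.info.get("CLOCI", []) or [])
            rec = MutationRecord(
                chrom=site.chrom, pos=pos1, ref=ref, alt=alt,
                variant_class=vclass, patient_id=patient_id or "",
                tumor_af=site.info.get("TAF"),
                constituent_loci=cloci,
            )
            in_panel = all(panel.contains(rec.chrom, p) for p in rec.spans)
            if not in_panel:
                warnings.warn(
                    f"{rec.chrom}:{rec.pos} {ref}>{alt} outside the panel; dropped",
                    stacklevel=2,
                )
                continue
            records.append(rec)
    if not records:
        raise UncallablePatientError(
            f"no mutations in {path} overlap the capture panel"
        )
    return MutationCatalog(patient_id=patient_id or "", mutations=records)


# ---------------------------------------------------------------------------
# BAM adapter

def extract_counts_bam(
    bam_path: str | Path, panel: PanelDef, sample_id: str = ""
) -> CountTable:
    """Strand-split counts from a coordinate-sorted, indexed consensus BAM.

    The strand of a consensus read is its alignment orientation.  Reads are
    counted per panel position: non-reference bases feed the matching
    substitution column, insertions starting at the position feed the
    insertion column, deleted bases the deletion column.
    """
    L = panel.size
    alt_f = np.zeros((L, N_ALLELES), dtype=np.int64)
    alt_r = np.zeros((L, N_ALLELES), dtype=np.int64)
    depth_f = np.zeros(L, dtype=np.int64)
    depth_r = np.zeros(L, dtype=np.int64)
    with pysam.AlignmentFile(str(bam_path)) as bam:
        if not bam.has_index():
            raise ValueError(f"{bam_path} has no index; run samtools index")
        for chrom, start, end in panel.regions:
            for col in bam.pileup(
                chrom, start, end, truncate=True, min_base_quality=0,
                stepper="nofilter",
            ):
                pos1 = col.reference_pos + 1
                if not panel.contains(chrom, pos1):
                    continue
                i = panel.locus_index(chrom, pos1)
                for pr in col.pileups:
                    rev = pr.alignment.is_reverse
                    if rev:
                        depth_r[i] += 1
                    else:
                        depth_f[i] += 1
                    target = alt_r if rev else alt_f
                    if pr.is_del:
                        target[i, DEL_COL] += 1
                        continue
                    if pr.indel > 0:
                        target[i, INS_COL] += 1
                    base = pr.alignment.query_sequence[pr.query_position]
                    if base != panel.ref[i]:
                        hit = np.where(panel.alt_bases[i] == base)[0]
                        if len(hit):
                            target[i, int(hit[0])] += 1
    return CountTable(panel, depth_f, depth_r, alt_f, alt_r, sample_id=sample_id)


# ---------------------------------------------------------------------------
# UMI-family consensus

@dataclass(frozen=True)
class TaggedRead:
    """A raw read carrying its UMI and fragment coordinates."""

    umi: str
    start: int  # fragment start (0-based)
    end: int
    strand: str  # "+" or "-"
    seq: str


@dataclass(frozen=True)
class ConsensusRead:
    start: int
    end: int
    strand: str
    seq: str
    family_size: int


def umi_consensus(
    reads: list[TaggedRead], ref_seq: str, min_family: int = 3
) -> list[ConsensusRead]:
    """Collapse UMI families into consensus reads.

    Reads are grouped by (UMI, fragment start, fragment end, strand);
    families smaller than ``min_family`` are discarded (random errors
    survive consensus only when a family is too small to vote them out).
    Per position the simple-majority base wins; ties fall back to the
    reference base (``ref_seq`` is indexed by the read coordinates).
    """
    families: dict[tuple, list[TaggedRead]] = defaultdict(list)
    for read in reads:
        families[(read.umi, read.start, read.end, read.strand)].append(read)
    out = []
    for (umi, start, end, strand), members in sorted(families.items()):
        if len(members) < min_family:
            continue
        length = end - start
        bases = []
        for i in range(length):
            votes = Counter(r.seq[i] for r in members if i < len(r.seq))
            if not votes:
                bases.append(ref_seq[start + i])
                continue
            ranked = votes.most_common()
            top, top_n = ranked[0]
            tied = [b for b, c in ranked if c == top_n]
            bases.append(ref_seq[start + i] if len(tied) > 1 else top)
        out.append(
            ConsensusRead(
                start=start, end=end, strand=strand,
                seq="".join(bases), family_size=len(members),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Cohort directory

def write_cohort(bundle, out_dir: str | Path) -> None:
    """Write a simulated cohort to a directory of standard-format files.

    Layout: ``panel.tsv``, ``pon/*.tsv``, ``healthy/*.tsv``,
    ``patients/<id>.vcf`` + ``<id>_plasma.tsv`` + ``<id>_pbmc.tsv``, and
    ``truth.json`` with seeds, cAFs and CHIP ground truth.
    """
    out = Path(out_dir)
    (out / "pon").mkdir(parents=True, exist_ok=True)
    (out / "healthy").mkdir(exist_ok=True)
    (out / "patients").mkdir(exist_ok=True)
    write_panel(bundle.panel, out / "panel.tsv")
    for t in bundle.pon:
        write_count_table(t, out / "pon" / f"{t.sample_id}.tsv")
    for t in bundle.healthy:
        write_count_table(t, out / "healthy" / f"{t.sample_id}.tsv")
    truth = {"seed": bundle.spec.seed, "patients": {}}
    for p in bundle.patients:
        pid = p.catalog.patient_id
        write_catalog_vcf(p.catalog, out / "patients" / f"{pid}.vcf", bundle.panel)
        write_count_table(p.plasma, out / "patients" / f"{pid}_plasma.tsv")
        write_count_table(p.pbmc, out / "patients" / f"{pid}_pbmc.tsv")
        truth["patients"][pid] = {
            "caf": p.caf,
            "chip": sorted(p.chip_truth),
            "n_mutations": len(p.catalog),
        }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)


def read_cohort_counts(cohort_dir: str | Path):
    """(panel, pon tables, healthy tables, patient catalogs+tables) from a
    cohort directory written by :func:`write_cohort`."""
    root = Path(cohort_dir)
    panel = read_panel(root / "panel.tsv")
    pon = [read_count_table(p, panel) for p in sorted((root / "pon").glob("*.tsv"))]
    healthy = [
        read_count_table(p, panel) for p in sorted((root / "healthy").glob("*.tsv"))
    ]
    patients = {}
    for vcf_path in sorted((root / "patients").glob("*.vcf")):
        pid = vcf_path.stem
        catalog = read_catalog_vcf(vcf_path, panel, patient_id=pid)
        plasma = read_count_table(root / "patients" / f"{pid}_plasma.tsv", panel)
        pbmc_path = root / "patients" / f"{pid}_pbmc.tsv"
        pbmc = read_count_table(pbmc_path, panel) if pbmc_path.exists() else None
        patients[pid] = (catalog, plasma, pbmc)
    return panel, pon, healthy, patients
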
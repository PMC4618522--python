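"""Readers and writers for call tables, genotypes, annotation tracks and outputs.

All tab-separated inputs/outputs print 1-based inclusive coordinates; the
conversion to the internal 0-based half-open convention happens here and
nowhere else.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    ALGORITHM_PLATFORM,
    CnClass,
    CnvCall,
    GenomicInterval,
    normalize_chrom,
)


class FormatError(ValueError):
    """Structural problem with an input file (missing columns, no samples)."""


class RecordError(ValueError):
    """One or more malformed records; message lists offending line numbers."""


# ---------------------------------------------------------------------------
# CNV call tables


@dataclass(frozen=True)
class CallFileDialect:
    """Column layout + coordinate convention of one caller's output table.

    The four caller formats differ arbitrarily, so dialects are declared
    explicitly rather than sniffed.
    """

    algorithm: str
    platform: str
    columns: dict  # logical name -> column name; keys: sample, chrom, start, end, cn, n_units[, quality]
    convention: str = "1-inclusive"  # or "0-half-open"

    def __post_init__(self):
        missing = {"sample", "chrom", "start", "end", "cn", "n_units"} - set(self.columns)
        if missing:
            raise FormatError(f"dialect for {self.algorithm} lacks columns {sorted(missing)}")
        if self.convention not in ("1-inclusive", "0-half-open"):
            raise FormatError(f"unknown coordinate convention {self.convention!r}")


def default_dialect(algorithm: str) -> CallFileDialect:
    """The dialect the synthetic cohort writes: uniform 1-based tables."""
    cols = {k: k for k in ("sample", "chrom", "start", "end", "cn", "n_units", "quality")}
    return CallFileDialect(algorithm, ALGORITHM_PLATFORM[algorithm], cols)


def read_cnv_calls(path: str, dialect: CallFileDialect) -> list[CnvCall]:
    """Read one caller's table into validated ``CnvCall`` records.

    Row order is preserved; malformed rows abort with a message naming the
    offending line numbers (header = line 1).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in dialect.columns.values() if c != "quality" and c not in df.columns]
    missing = [c for n, c in dialect.columns.items() if n != "quality" and c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    calls: list[CnvCall] = []
    bad: list[str] = []
    has_quality = "quality" in dialect.columns and dialect.columns["quality"] in df.columns
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(df.columns, row))
        try:
            start = int(rec[dialect.columns["start"]])
            end = int(rec[dialect.columns["end"]])
            if dialect.convention == "1-inclusive":
                start -= 1  # 1-based inclusive -> 0-based half-open
            if end <= start:
                raise ValueError("end <= start after conversion")
            cn = CnClass.from_copy_number(rec[dialect.columns["cn"]])
            q = None
            if has_quality:
                qs = rec[dialect.columns["quality"]]
                q = float(qs) if qs not in (None, "", "nan") and not pd.isna(qs) else None
            calls.append(
                CnvCall(
                    sample_id=str(rec[dialect.columns["sample"]]),
                    platform=dialect.platform,
                    algorithm=dialect.algorithm,
                    interval=GenomicInterval(
                        normalize_chrom(rec[dialect.columns["chrom"]]), start, end
                    ),
                    cn=cn,
                    n_units=int(rec[dialect.columns["n_units"]]),
                    quality=q,
                )
            )
        except (ValueError, KeyError) as e:
            bad.append(f"line {i}: {e}")
    if bad:
        raise RecordError(f"{path}: {len(bad)} malformed record(s): " + "; ".join(bad[:10]))
    return calls


def write_cnv_calls(calls: Sequence[CnvCall], path: str) -> None:
    """Write calls as a 1-based inclusive tab-separated table (default dialect)."""
    rows = [
        {
            "sample": c.sample_id,
            "chrom": c.interval.chrom,
            "start": c.interval.start + 1,
            "end": c.interval.end,
            "cn": c.cn.value,
            "n_units": c.n_units,
            "quality": "" if c.quality is None else c.quality,
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "cn", "n_units", "quality"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# SNP genotypes


@dataclass
class SnpGenotypeMatrix:
    """Samples × SNP dosage matrix (0/1/2, −1 missing) with SNP coordinates."""

    sample_ids: list[str]
    snp_ids: list[str]
    chroms: np.ndarray  # object array of str, one per SNP
    positions: np.ndarray  # int array, 0-based position, one per SNP
    dosages: np.ndarray  # int8 (n_snps, n_samples); -1 = missing
    n_skipped_multiallelic: int = 0

    def __post_init__(self):
        if self.dosages.shape != (len(self.snp_ids), len(self.sample_ids)):
            raise ValueError("dosage matrix shape mismatch")


def read_genotype_matrix(path_vcf: str, expected_samples: Optional[Sequence[str]] = None) -> SnpGenotypeMatrix:
    """Read biallelic SNP dosages from a VCF.

    Multi-allelic records are skipped (count logged on the result).  GT './.'
    becomes a missing entry.  If ``expected_samples`` is given, any mismatch
    with the VCF sample set is fatal, naming the offenders.
    """
    from cyvcf2 import VCF

    vcf = VCF(path_vcf)
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"{path_vcf}: VCF has no samples")
    if expected_samples is not None:
        missing = sorted(set(expected_samples) - set(samples))
        extra = sorted(set(samples) - set(expected_samples))
        if missing or extra:
            raise FormatError(
                f"{path_vcf}: sample mismatch with metadata; missing={missing} extra={extra}"
            )
    snp_ids, chroms, positions, rows = [], [], [], []
    skipped = 0
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    dose_map = np.array([0, 1, -1, 2], dtype=np.int8)
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            skipped += 1
            continue
        snp_ids.append(rec.ID if rec.ID not in (None, ".") else f"snp{i}")
        chroms.append(normalize_chrom(rec.CHROM))
        positions.append(rec.POS - 1)  # VCF is 1-based
        rows.append(dose_map[rec.gt_types])
    dosages = (
        np.array(rows, dtype=np.int8) if rows else np.empty((0, len(samples)), dtype=np.int8)
    )
    return SnpGenotypeMatrix(
        sample_ids=samples,
        snp_ids=snp_ids,
        chroms=np.array(chroms, dtype=object),
        positions=np.array(positions, dtype=np.int64),
        dosages=dosages,
        n_skipped_multiallelic=skipped,
    )


def write_genotype_vcf(mat: SnpGenotypeMatrix, path: str) -> None:
    """Write a minimal VCF 4.2 (GT only) for a dosage matrix."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    order = np.lexsort((mat.positions, mat.chroms.astype(str)))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in sorted(set(mat.chroms.astype(str))):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(mat.sample_ids) + "\n")
        for j in order:
            gts = "\t".join(gt_map[int(d)] for d in mat.dosages[j])
            fh.write(
                f"{mat.chroms[j]}\t{mat.positions[j] + 1}\t{mat.snp_ids[j]}\tA\tC\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Annotation tracks


@dataclass(frozen=True)
class Gene:
    """A gene model with ordered, non-overlapping exons."""

    name: str
    interval: GenomicInterval
    strand: str
    exons: tuple[GenomicInterval, ...]  # sorted by start, transcription order applied via strand

    def __post_init__(self):
        ex = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(ex, ex[1:]):
            if b.start < a.end:
                raise ValueError(f"gene {self.name}: exons overlap")
        object.__setattr__(self, "exons", tuple(ex))

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass
class AnnotationBundle:
    """All annotation tracks the CNVR annotator consumes."""

    genes: list[Gene] = field(default_factory=list)
    mirnas: list[GenomicInterval] = field(default_factory=list)
    promoters: list[GenomicInterval] = field(default_factory=list)
    tfbs: list[GenomicInterval] = field(default_factory=list)
    cytobands: list[tuple[GenomicInterval, str]] = field(default_factory=list)
    disease_genes: dict[str, str] = field(default_factory=dict)  # symbol -> disorder id
    # (interval, direction, resolution) per reference record
    reference_cnvrs: list[tuple[GenomicInterval, str, str]] = field(default_factory=list)

    def __post_init__(self):
        by_chrom: dict[str, list[tuple[GenomicInterval, str]]] = {}
        for iv, name in self.cytobands:
            by_chrom.setdefault(iv.chrom, []).append((iv, name))
        for chrom, bands in by_chrom.items():
            bands.sort(key=lambda t: t[0].start)
            for (a, _), (b, _) in zip(bands, bands[1:]):
                if b.start < a.end:
                    raise ValueError(f"cytobands overlap on chromosome {chrom}")


def read_bed_intervals(path: str) -> list[GenomicInterval]:
    """Read a BED3(+) file into half-open intervals (BED is already 0-based)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(GenomicInterval(normalize_chrom(f[0]), int(f[1]), int(f[2])))
    return out


def read_cytobands(path: str) -> list[tuple[GenomicInterval, str]]:
    """Read a UCSC-style cytoband table: chrom, start, end, name[, stain]."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            chrom = normalize_chrom(f[0])
            out.append((GenomicInterval(chrom, int(f[1]), int(f[2])), f"{chrom}{f[3]}"))
    return out


def read_gff3_genes(path: str) -> list[Gene]:
    """Read gene models (gene + exon features) from a GFF3 file.

    Exons are attached to their gene via the Parent chain; only the standard
    gene/mRNA/exon hierarchy is handled.
    """

    def attrs(s: str) -> dict:
        return dict(kv.split("=", 1) for kv in s.strip().split(";") if "=" in kv)

    genes: dict[str, dict] = {}
    parent_of: dict[str, str] = {}
    exon_rows: list[tuple[str, GenomicInterval]] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise FormatError(f"{path}: GFF3 line with <9 columns")
            chrom, _, ftype, start, end, _, strand, _, attr = f[:9]
            a = attrs(attr)
            iv = GenomicInterval(normalize_chrom(chrom), int(start) - 1, int(end))
            if ftype == "gene":
                gid = a.get("ID", a.get("Name", f"gene{len(genes)}"))
                genes[gid] = {"name": a.get("Name", gid), "interval": iv, "strand": strand, "exons": []}
            elif ftype in ("mRNA", "transcript"):
                parent_of[a["ID"]] = a["Parent"]
            elif ftype == "exon":
                exon_rows.append((a["Parent"], iv))
    for parent, iv in exon_rows:
        gid = parent_of.get(parent, parent)
        if gid in genes:
            genes[gid]["exons"].append(iv)
    out = []
    for gid, g in genes.items():
        out.append(Gene(g["name"], g["interval"], g["strand"], tuple(g["exons"])))
    return out


def read_disease_genes(path: str) -> dict[str, str]:
    """Two-column tab-separated gene symbol -> disorder identifier."""
    out = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            sym, disorder = line.rstrip("\n").split("\t")[:2]
            out[sym] = disorder
    return out


def read_reference_cnvrs(path: str) -> list[tuple[GenomicInterval, str, str]]:
    """BED + direction + resolution columns: chrom, start, end, direction, resolution."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(
                (GenomicInterval(normalize_chrom(f[0]), int(f[1]), int(f[2])), f[3], f[4])
            )
    return out


# ---------------------------------------------------------------------------
# CNVR tables

CNVR_COLUMNS = [
    "subpopulation",
    "chrom",
    "start",
    "end",
    "cn",
    "carrier_count",
    "frequency",
    "freq_bin",
    "freq_dichotomy",
    "carriers",
]


def write_cnvr_table(cnvrs, path: str, subpop_sizes: Optional[dict] = None, bins=(0.01, 0.10), common=0.20) -> None:
    """Write merged CNVRs as a 1-based inclusive tab-separated table."""
    from .cnvr import classify_frequency

    rows = []
    for r in cnvrs:
        if subpop_sizes is not None:
            dich, b = classify_frequency(r, subpop_sizes[r.subpopulation], bins, common)
        else:
            dich = b = ""
        rows.append(
            {
                "subpopulation": r.subpopulation,
                "chrom": r.interval.chrom,
                "start": r.interval.start + 1,
                "end": r.interval.end,
                "cn": r.cn.value,
                "carrier_count": r.carrier_count,
                "frequency": f"{r.frequency:.6g}" if r.frequency is not None else "",
                "freq_bin": b,
                "freq_dichotomy": dich,
                "carriers": ",".join(sorted(r.carriers)),
            }
        )
    pd.DataFrame(rows, columns=CNVR_COLUMNS).to_csv(path, sep="\t", index=False)


def read_cnvr_table(path: str):
    """Inverse of :func:`write_cnvr_table` (intervals and core fields)."""
    from .cnvr import CnvRegion

    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, r in df.iterrows():
        carriers = set(str(r["carriers"]).split(",")) if pd.notna(r["carriers"]) and r["carriers"] else set()
        out.append(
            CnvRegion(
                subpopulation=r["subpopulation"],
                interval=GenomicInterval(normalize_chrom(r["chrom"]), int(r["start"]) - 1, int(r["end"])),
                cn=CnClass(r["cn"]),
                carriers=carriers,
                frequency=float(r["frequency"]) if r["frequency"] not in (None, "") and pd.notna(r["frequency"]) else None,
            )
        )
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str, names: Optional[Sequence[str]] = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")
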
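"""Functional annotation of CNVRs: cytobands, genic impact, regulatory
features, disease genes and novelty against a reference CNVR catalogue.

"Affected" exons are those fully contained within the CNV's breakpoints;
exons merely overlapped are reported separately.  The genic/nongenic
partition uses gene-span overlap; the per-gene impact classes use exon
containment and the position of the duplication endpoints relative to the
gene span.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .core import CnClass, GenomicInterval, overlap_bp
from .cnvr import CnvRegion
from .io import AnnotationBundle, Gene

IMPACT_CLASSES = (
    "intronic",
    "exonic_deletion",
    "full_gene_duplication",
    "internal_duplication",
    "partial_genic_duplication",
    "nongenic",
)


@dataclass
class GeneImpact:
    """Impact of one CNVR on one gene."""

    gene: str
    impact: str  # one of IMPACT_CLASSES
    affected_exons: tuple[int, int] | None  # 1-based inclusive index range, or None
    overlapped_exons: tuple[int, int] | None  # overlapped but not contained
    n_exons: int

    @property
    def affected_label(self) -> str:
        """Printed form, e.g. '2-3/12'."""
        if self.affected_exons is None:
            return f"-/{self.n_exons}"
        a, b = self.affected_exons
        return (f"{a}/{self.n_exons}" if a == b else f"{a}-{b}/{self.n_exons}")


@dataclass
class AnnotatedCnvr:
    """A CNVR plus every annotation layer."""

    cnvr: CnvRegion
    cytobands: list[str] = field(default_factory=list)
    gene_impacts: list[GeneImpact] = field(default_factory=list)
    mirna: bool = False
    promoter: bool = False
    tfbs: bool = False
    disease_genes: list[str] = field(default_factory=list)
    novel: bool = True

    @property
    def genic(self) -> bool:
        return bool(self.gene_impacts)


def assign_cytoband(
    interval: GenomicInterval, cytobands: Sequence[tuple[GenomicInterval, str]]
) -> list[str]:
    """All cytobands overlapping the interval, in genomic order."""
    chroms = {iv.chrom for iv, _ in cytobands}
    if interval.chrom not in chroms:
        raise ValueError(f"chromosome {interval.chrom!r} absent from cytoband track")
    hits = [
        (iv.start, name)
        for iv, name in cytobands
        if overlap_bp(iv, interval) >= 1
    ]
    return [name for _, name in sorted(hits)]


def affected_exons(
    interval: GenomicInterval, gene: Gene
) -> tuple[tuple[int, int] | None, tuple[int, int] | None]:
    """(contained exon index range, overlapped-only exon index range).

    Indices are 1-based in exon order along the chromosome (transcript
    numbering for + strand genes; reversed for − strand).  "Affected" means
    fully contained within the CNV breakpoints.
    """
    contained, overlapped = [], []
    n = gene.n_exons
    for i, ex in enumerate(gene.exons):
        idx = i + 1 if gene.strand != "-" else n - i
        if ex.chrom != interval.chrom:
            continue
        if interval.start <= ex.start and ex.end <= interval.end:
            contained.append(idx)
        elif overlap_bp(ex, interval) >= 1:
            overlapped.append(idx)

    def rng(ids):
        return (min(ids), max(ids)) if ids else None

    return rng(contained), rng(overlapped)


def classify_genic_impact(cnvr: CnvRegion, gene: Gene) -> GeneImpact | None:
    """Impact class of one CNVR on one gene; None when spans don't overlap.

    Deletions containing ≥1 whole exon are exonic; duplications are split by
    endpoint position: encompassing the whole gene (dosage gain), internal
    (both endpoints strictly inside, possibly frame-disrupting), or partial
    (one endpoint inside — excluded from the disease-gene report).
    """
    iv = cnvr.interval
    if overlap_bp(iv, gene.interval) < 1:
        return None
    contained, overlapped = affected_exons(iv, gene)
    if cnvr.direction == "deletion":
        impact = "exonic_deletion" if contained else "intronic"
        return GeneImpact(gene.name, impact, contained, overlapped, gene.n_exons)
    g = gene.interval
    if iv.start <= g.start and iv.end >= g.end:
        impact = "full_gene_duplication"
    elif g.start < iv.start and iv.end < g.end:
        impact = "internal_duplication" if contained else "intronic"
    else:
        impact = "partial_genic_duplication"
    return GeneImpact(gene.name, impact, contained, overlapped, gene.n_exons)


def flag_novelty(
    cnvr: CnvRegion,
    reference: Sequence[tuple[GenomicInterval, str, str]],
    reciprocal_overlap: float = 0.0,
    high_res_only: bool = True,
) -> bool:
    """True iff no same-direction reference record overlaps the CNVR.

    The reference set is pruned to high-resolution records first (matching
    the resolution of the discovery platforms), unless disabled.
    """
    for iv, direction, resolution in reference:
        if high_res_only and resolution != "high":
            continue
        if direction != cnvr.direction:
            continue
        ov = overlap_bp(iv, cnvr.interval)
        if ov < 1:
            continue
        if reciprocal_overlap > 0 and not (
            ov >= reciprocal_overlap * iv.span and ov >= reciprocal_overlap * cnvr.interval.span
        ):
            continue
        return False
    return True


def annotate_cnvr(cnvr: CnvRegion, bundle: AnnotationBundle, reciprocal_overlap: float = 0.0) -> AnnotatedCnvr:
    """Apply every annotation layer to one CNVR."""
    iv = cnvr.interval

    def any_overlap(track):
        return any(overlap_bp(t, iv) >= 1 for t in track)

    impacts = []
    for gene in bundle.genes:
        gi = classify_genic_impact(cnvr, gene)
        if gi is not None:
            impacts.append(gi)
    disease = sorted(
        {
            gi.gene
            for gi in impacts
            if gi.gene in bundle.disease_genes and gi.impact != "partial_genic_duplication"
        }
    )
    try:
        bands = assign_cytoband(iv, bundle.cytobands) if bundle.cytobands else []
    except ValueError:
        bands = []
    return AnnotatedCnvr(
        cnvr=cnvr,
        cytobands=bands,
        gene_impacts=impacts,
        mirna=any_overlap(bundle.mirnas),
        promoter=any_overlap(bundle.promoters),
        tfbs=any_overlap(bundle.tfbs),
        disease_genes=disease,
        novel=flag_novelty(cnvr, bundle.reference_cnvrs, reciprocal_overlap)
        if bundle.reference_cnvrs
        else True,
    )


def annotate_all(
    cnvrs: Sequence[CnvRegion],
    bundle: AnnotationBundle,
    reciprocal_overlap: float = 0.0,
) -> tuple[list[AnnotatedCnvr], pd.DataFrame]:
    """Annotate all CNVRs and tabulate per-subpopulation per-class counts.

    The counts table mirrors the functional-annotation summary layout: one
    row per (subpopulation, class), columns total / nongenic / genic / miRNA
    / disease-gene / #disease genes / known / novel / novel genic / promoter
    / TFBS.  Internally consistent: genic + nongenic = total.
    """
    annotated = [annotate_cnvr(r, bundle, reciprocal_overlap) for r in cnvrs]
    rows = []
    groups: dict[tuple[str, str], list[AnnotatedCnvr]] = defaultdict(list)
    for a in annotated:
        groups[(a.cnvr.subpopulation, a.cnvr.cn.value)].append(a)
    for (subpop, cls) in sorted(groups):
        items = groups[(subpop, cls)]
        genic = [a for a in items if a.genic]
        novel = [a for a in items if a.novel]
        rows.append(
            {
                "subpopulation": subpop,
                "cn": cls,
                "total": len(items),
                "nongenic": len(items) - len(genic),
                "genic": len(genic),
                "mirna": sum(a.mirna for a in items),
                "disease_gene": sum(bool(a.disease_genes) for a in items),
                "n_disease_genes": len({g for a in items for g in a.disease_genes}),
                "known": len(items) - len(novel),
                "novel": len(novel),
                "novel_genic": sum(a.genic for a in novel),
                "promoter": sum(a.promoter for a in items),
                "tfbs": sum(a.tfbs for a in items),
            }
        )
    return annotated, pd.DataFrame(rows)
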
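"""Subpopulation-level CNV region (CNVR) merging and summaries.

Per-individual final CNVs are merged within each subpopulation by
single-linkage overlap, per copy-number class.  A CNVR's interval is the
cluster hull (min start – max end across carriers).  Loci where deletion and
duplication CNVRs overlap in different individuals are "polymorphic"; in the
combined accounting each such locus is counted once.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import CnClass, GenomicInterval, SampleMeta, union_span
from .consensus import ConsensusCnv


@dataclass
class CnvRegion:
    """A merged population-level CNV locus within one subpopulation."""

    subpopulation: str
    interval: GenomicInterval
    cn: CnClass
    carriers: set = field(default_factory=set)
    frequency: Optional[float] = None
    member_cnvs: list = field(default_factory=list)  # provenance: contributing ConsensusCnv

    @property
    def carrier_count(self) -> int:
        return len(self.carriers)

    @property
    def direction(self) -> str:
        return self.cn.direction


@dataclass
class PolymorphicLocus:
    """Overlapping deletion + duplication CNVRs at one site in one subpopulation."""

    subpopulation: str
    deletion: CnvRegion
    duplication: CnvRegion
    combined_interval: GenomicInterval


def _single_linkage_merge(items: Sequence, key) -> list[list]:
    """Single-linkage clustering of intervals by ≥1 bp overlap (sorted sweep)."""
    items = sorted(items, key=lambda x: (key(x).chrom, key(x).start, key(x).end))
    clusters: list[list] = []
    cur: list = []
    cur_chrom, cur_end = None, -1
    for it in items:
        iv = key(it)
        if cur and iv.chrom == cur_chrom and iv.start < cur_end:
            cur.append(it)
            cur_end = max(cur_end, iv.end)
        else:
            if cur:
                clusters.append(cur)
            cur = [it]
            cur_chrom, cur_end = iv.chrom, iv.end
    if cur:
        clusters.append(cur)
    return clusters


def merge_to_cnvrs(
    cnvs: Sequence[ConsensusCnv],
    subpopulation: str,
    subpop_size: Optional[int] = None,
) -> list[CnvRegion]:
    """Merge one subpopulation's final CNVs into per-class CNVRs.

    Same-class overlapping CNVs across individuals collapse into one region
    whose interval is the hull of the cluster; carriers are the distinct
    contributing samples.  Regions of one class are pairwise disjoint.
    """
    out: list[CnvRegion] = []
    by_class: dict[CnClass, list[ConsensusCnv]] = defaultdict(list)
    for c in cnvs:
        by_class[c.cn].append(c)
    for cls in sorted(by_class, key=lambda c: c.value):
        for cluster in _single_linkage_merge(by_class[cls], key=lambda c: c.interval):
            hull = GenomicInterval(
                cluster[0].interval.chrom,
                min(c.interval.start for c in cluster),
                max(c.interval.end for c in cluster),
            )
            carriers = {c.sample_id for c in cluster}
            freq = len(carriers) / subpop_size if subpop_size else None
            out.append(
                CnvRegion(
                    subpopulation=subpopulation,
                    interval=hull,
                    cn=cls,
                    carriers=carriers,
                    frequency=freq,
                    member_cnvs=list(cluster),
                )
            )
    out.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end, r.cn.value))
    return out


def merge_direction_loci(cnvrs: Sequence[CnvRegion]) -> list[CnvRegion]:
    """Collapse same-direction CNVRs into direction-level loci.

    Overlapping CN0/CN1 regions become one deletion locus (class kept as the
    more extreme member's for labelling); analogously for duplications.  Used
    for the combined (polymorphic-aware) tally and for deletion genotyping.
    """
    from .core import more_extreme

    out: list[CnvRegion] = []
    by_dir: dict[str, list[CnvRegion]] = defaultdict(list)
    for r in cnvrs:
        by_dir[r.direction].append(r)
    for direction in sorted(by_dir):
        for cluster in _single_linkage_merge(by_dir[direction], key=lambda r: r.interval):
            hull = GenomicInterval(
                cluster[0].interval.chrom,
                min(r.interval.start for r in cluster),
                max(r.interval.end for r in cluster),
            )
            cls = cluster[0].cn
            for r in cluster[1:]:
                cls = more_extreme(cls, r.cn)
            carriers = set().union(*(r.carriers for r in cluster))
            out.append(
                CnvRegion(
                    subpopulation=cluster[0].subpopulation,
                    interval=hull,
                    cn=cls,
                    carriers=carriers,
                    member_cnvs=[m for r in cluster for m in r.member_cnvs],
                )
            )
    out.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end))
    return out


def find_polymorphic(
    cnvrs: Sequence[CnvRegion],
) -> tuple[list[PolymorphicLocus], dict]:
    """Find loci carrying both deletions and duplications; combined tally.

    Pairing is at the direction-locus level (overlapping CN0/CN1 regions are
    one deletion locus).  The combined count records each overlapped
    deletion/duplication pair once:

        combined = deletion_loci + duplication_loci − polymorphic_pairs
    """
    loci = merge_direction_loci(cnvrs)
    dels = [r for r in loci if r.direction == "deletion"]
    dups = [r for r in loci if r.direction == "duplication"]
    pairs: list[PolymorphicLocus] = []
    from .core import overlap_bp

    dups_by_chrom: dict[str, list[CnvRegion]] = defaultdict(list)
    for d in dups:
        dups_by_chrom[d.interval.chrom].append(d)
    for de in dels:
        for du in dups_by_chrom[de.interval.chrom]:
            if overlap_bp(de.interval, du.interval) >= 1:
                hull = GenomicInterval(
                    de.interval.chrom,
                    min(de.interval.start, du.interval.start),
                    max(de.interval.end, du.interval.end),
                )
                pairs.append(
                    PolymorphicLocus(de.subpopulation, de, du, hull)
                )
    tally = {
        "deletion_loci": len(dels),
        "duplication_loci": len(dups),
        "polymorphic": len(pairs),
        "combined": len(dels) + len(dups) - len(pairs),
    }
    return pairs, tally


def classify_frequency(
    cnvr: CnvRegion, subpop_n: int, bins: tuple[float, ...] = (0.01, 0.10), common: float = 0.20
) -> tuple[str, str]:
    """(low-frequency/common dichotomy, frequency bin label) for a CNVR.

    Bin edges read literally: "<1%" is f<0.01, "1-10%" is 0.01≤f≤0.10,
    ">10%" is f>0.10; "common" is f>0.20.
    """
    f = cnvr.carrier_count / subpop_n
    dichotomy = "common" if f > common else "low-frequency"
    lo, hi = bins
    if f < lo:
        b = f"<{lo:.0%}"
    elif f <= hi:
        b = f"{lo:.0%}-{hi:.0%}".replace("%-", "-")
    else:
        b = f">{hi:.0%}"
    return dichotomy, b


def summarize_by_class(
    per_sample_cnvs: dict[str, list[ConsensusCnv]],
    cnvrs_by_subpop: dict[str, list[CnvRegion]],
) -> dict[str, pd.DataFrame]:
    """Cohort summary tables.

    ``per_sample``: per sample, CNV count and total affected bp per class.
    ``cohort``: mean/median of those per class.
    ``cnvr``: per subpopulation and class, CNVR count, mean size and the
    non-overlapping total size (union span) per subpopulation.
    """
    classes = list(CnClass)
    rows = []
    for sid, cnvs in sorted(per_sample_cnvs.items()):
        row = {"sample": sid}
        for cls in classes:
            sub = [c for c in cnvs if c.cn == cls]
            row[f"n_{cls.value}"] = len(sub)
            row[f"bp_{cls.value}"] = sum(c.interval.span for c in sub)
        row["n_total"] = len(cnvs)
        row["bp_total"] = union_span([c.interval for c in cnvs]) if cnvs else 0
        rows.append(row)
    per_sample = pd.DataFrame(rows)

    stat_rows = []
    for stat, fn in (("mean", np.mean), ("median", np.median)):
        r = {"statistic": stat}
        for col in per_sample.columns:
            if col != "sample":
                r[col] = float(fn(per_sample[col])) if len(per_sample) else np.nan
        stat_rows.append(r)
    cohort = pd.DataFrame(stat_rows)

    cnvr_rows = []
    for subpop, regions in sorted(cnvrs_by_subpop.items()):
        row = {"subpopulation": subpop}
        for cls in classes:
            sub = [r for r in regions if r.cn == cls]
            row[f"n_cnvr_{cls.value}"] = len(sub)
            row[f"mean_size_{cls.value}"] = (
                float(np.mean([r.interval.span for r in sub])) if sub else 0.0
            )
        _, tally = find_polymorphic(regions)
        row["n_cnvr_total"] = len(regions)
        row["polymorphic"] = tally["polymorphic"]
        row["combined"] = tally["combined"]
        row["union_bp"] = union_span([r.interval for r in regions]) if regions else 0
        cnvr_rows.append(row)
    cnvr_table = pd.DataFrame(cnvr_rows)
    return {"per_sample": per_sample, "cohort": cohort, "cnvr": cnvr_table}
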
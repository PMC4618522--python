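"""Two-tier consensus integration of multi-caller CNV call sets.

The funnel: size filter (≥5 consecutive probes/windows) → removal of outlier
samples with a large excess of calls → within-individual cross-algorithm
consensus (a call must be seen by more than one algorithm) → rescue of
remaining singletons by a second occurrence in another individual →
breakpoint curation (sequencing breakpoints win over array; same-platform
overlaps take the narrower intersection).  Calls observed only once in the
entire cohort are discarded.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import (
    CnClass,
    CnvCall,
    GenomicInterval,
    PipelineConfig,
    intersect,
    more_extreme,
    overlap_bp,
)


@dataclass(frozen=True)
class ConsensusCnv:
    """A per-individual high-confidence CNV with support provenance."""

    sample_id: str
    interval: GenomicInterval
    cn: CnClass
    support: frozenset  # of (platform, algorithm)
    support_mode: str  # 'intra' | 'inter'
    breakpoint_source: str  # 'ngs' | 'array' | 'intersection'
    fallback: bool = False  # empty same-platform intersection; narrowest member used

    def __post_init__(self):
        if not self.support:
            raise ValueError("support must be non-empty")
        if self.support_mode == "intra" and len({a for _, a in self.support}) < 2:
            raise ValueError("intra-individual consensus requires >=2 algorithms")


def filter_min_units(calls: Sequence[CnvCall], min_units: int = 5) -> list[CnvCall]:
    """Keep calls spanning at least ``min_units`` consecutive probes/windows."""
    return [c for c in calls if c.n_units >= min_units]


def detect_outlier_samples(calls: Sequence[CnvCall], k: float = 3.0) -> list[str]:
    """Samples whose raw call count exceeds median + k × scaled MAD.

    Degenerate spread (MAD = 0) falls back to the IQR-based scale estimate;
    if that is also 0 no sample is excluded.
    """
    counts = pd.Series([c.sample_id for c in calls]).value_counts()
    if len(counts) < 5:
        raise ValueError("outlier detection requires >=5 samples")
    x = counts.to_numpy(dtype=float)
    med = np.median(x)
    scale = 1.4826 * np.median(np.abs(x - med))
    if scale == 0:
        q75, q25 = np.percentile(x, [75, 25])
        scale = (q75 - q25) / 1.349
    if scale == 0:
        return []
    out = sorted(counts.index[x > med + k * scale])
    if len(out) == len(counts):
        raise ValueError("all samples flagged as outliers; degenerate distribution")
    return out


def _reciprocal_ok(a: GenomicInterval, b: GenomicInterval, frac: float) -> bool:
    ov = overlap_bp(a, b)
    return ov >= frac * a.span and ov >= frac * b.span


def calls_match(a: CnvCall, b: CnvCall, reciprocal_overlap: float = 0.0) -> bool:
    """True iff the calls overlap by ≥1 bp and share direction.

    Matching is by direction, not exact class: a heterozygous and a
    homozygous deletion at one locus are the same event seen differently.
    """
    if a.cn.direction != b.cn.direction:
        return False
    if overlap_bp(a.interval, b.interval) < 1:
        return False
    if reciprocal_overlap > 0 and not _reciprocal_ok(a.interval, b.interval, reciprocal_overlap):
        return False
    return True


class _UnionFind:
    def __init__(self, n: int):
        self.p = list(range(n))

    def find(self, i: int) -> int:
        while self.p[i] != i:
            self.p[i] = self.p[self.p[i]]
            i = self.p[i]
        return i

    def union(self, i: int, j: int):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.p[rj] = ri


def intra_individual_consensus(
    sample_calls: Sequence[CnvCall], reciprocal_overlap: float = 0.0
) -> tuple[list[list[CnvCall]], list[CnvCall]]:
    """Group one sample's calls by cross-algorithm overlap.

    Connected components (edges only between calls from *different*
    algorithms that match) with ≥2 distinct algorithms are retained groups;
    every other call is a singleton.
    """
    calls = sorted(sample_calls, key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end, c.algorithm))
    uf = _UnionFind(len(calls))
    # sweep within chromosome: candidate pairs are those whose intervals overlap
    by_chrom: dict[str, list[int]] = defaultdict(list)
    for i, c in enumerate(calls):
        by_chrom[c.interval.chrom].append(i)
    for idxs in by_chrom.values():
        active: list[int] = []
        for i in idxs:
            ci = calls[i]
            active = [j for j in active if calls[j].interval.end > ci.interval.start]
            for j in active:
                cj = calls[j]
                if ci.algorithm != cj.algorithm and calls_match(ci, cj, reciprocal_overlap):
                    uf.union(i, j)
            active.append(i)
    comps: dict[int, list[CnvCall]] = defaultdict(list)
    for i, c in enumerate(calls):
        comps[uf.find(i)].append(c)
    groups, singletons = [], []
    for members in comps.values():
        if len({m.algorithm for m in members}) >= 2:
            groups.append(members)
        else:
            singletons.extend(members)
    return groups, singletons


def inter_individual_rescue(
    singletons: Sequence[CnvCall],
    cohort_calls: Sequence[CnvCall],
    reciprocal_overlap: float = 0.0,
) -> tuple[list[CnvCall], list[CnvCall]]:
    """Rescue singletons with a second occurrence in another individual.

    A singleton survives iff it matches any post-QC raw call in a *different*
    sample; otherwise it is discarded.  Rescued calls keep their own
    breakpoints.
    """
    if not singletons:
        return [], []
    # index only the chromosomes singletons live on: tree construction over
    # the full cohort dominates runtime otherwise
    wanted = {s.interval.chrom for s in singletons}
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for c in cohort_calls:
        if c.interval.chrom in wanted:
            trees[c.interval.chrom].addi(c.interval.start, c.interval.end, c)
    rescued, discarded = [], []
    for s in singletons:
        hit = False
        for iv in trees[s.interval.chrom].overlap(s.interval.start, s.interval.end):
            other: CnvCall = iv.data
            if other.sample_id != s.sample_id and calls_match(s, other, reciprocal_overlap):
                hit = True
                break
        (rescued if hit else discarded).append(s)
    return rescued, discarded


def curate_breakpoints(group: Sequence[CnvCall]) -> ConsensusCnv:
    """Collapse one matched group into a single curated CNV.

    Mixed platforms: only the sequencing members define the breakpoints.
    Multiple members of the donor platform: their common intersection (max
    start, min end) — the narrower, more conservative call.  The class
    follows the breakpoint donor; for intersections, the narrowest member's
    class, ties broken toward the extreme class (0 over 1, 4+ over 3).
    """
    if not group:
        raise ValueError("empty group")
    sample = group[0].sample_id
    platforms = {c.platform for c in group}
    mixed = platforms == {"array", "ngs"}
    donors = [c for c in group if c.platform == "ngs"] if mixed else list(group)
    support = frozenset((c.platform, c.algorithm) for c in group)

    def donor_class(members: Sequence[CnvCall]) -> CnClass:
        narrowest = min(m.interval.span for m in members)
        cls = None
        for m in members:
            if m.interval.span == narrowest:
                cls = m.cn if cls is None else more_extreme(cls, m.cn)
        return cls

    if len(donors) == 1:
        d = donors[0]
        return ConsensusCnv(
            sample_id=sample,
            interval=d.interval,
            cn=d.cn,
            support=support,
            support_mode="intra" if len({a for _, a in support}) >= 2 else "inter",
            breakpoint_source="ngs" if mixed else d.platform,
        )
    start = max(c.interval.start for c in donors)
    end = min(c.interval.end for c in donors)
    if end > start:
        return ConsensusCnv(
            sample_id=sample,
            interval=GenomicInterval(donors[0].interval.chrom, start, end),
            cn=donor_class(donors),
            support=support,
            support_mode="intra",
            breakpoint_source="ngs" if mixed else "intersection",
        )
    # donors do not share a common segment (chained overlaps): fall back to
    # the narrowest single member, flagged
    d = min(donors, key=lambda c: (c.interval.span, c.interval.start))
    return ConsensusCnv(
        sample_id=sample,
        interval=d.interval,
        cn=d.cn,
        support=support,
        support_mode="intra",
        breakpoint_source="ngs" if mixed else d.platform,
        fallback=True,
    )


def _rescued_to_consensus(call: CnvCall) -> ConsensusCnv:
    return ConsensusCnv(
        sample_id=call.sample_id,
        interval=call.interval,
        cn=call.cn,
        support=frozenset({(call.platform, call.algorithm)}),
        support_mode="inter",
        breakpoint_source=call.platform,
    )


@dataclass
class IntegrationReport:
    """Per-sample funnel counts: raw → post-QC → intra-retained → rescued → final."""

    excluded_samples: list[str]
    funnel: pd.DataFrame  # columns: sample, raw, post_qc, intra_groups, singletons, rescued, final

    def to_tsv(self, path: str) -> None:
        self.funnel.to_csv(path, sep="\t", index=False)


def integrate(
    calls: Sequence[CnvCall], cfg: Optional[PipelineConfig] = None
) -> tuple[dict[str, list[ConsensusCnv]], IntegrationReport]:
    """Run the full consensus funnel; returns per-sample final CNVs + report."""
    cfg = cfg or PipelineConfig()
    raw_by_sample: dict[str, list[CnvCall]] = defaultdict(list)
    for c in calls:
        raw_by_sample[c.sample_id].append(c)

    sized = filter_min_units(calls, cfg.min_units)
    excluded = detect_outlier_samples(calls, cfg.outlier_mad_k)
    excluded_set = set(excluded)
    post_qc = [c for c in sized if c.sample_id not in excluded_set]

    by_sample: dict[str, list[CnvCall]] = defaultdict(list)
    for c in post_qc:
        by_sample[c.sample_id].append(c)

    final: dict[str, list[ConsensusCnv]] = {}
    all_singletons: dict[str, list[CnvCall]] = {}
    groups_by_sample: dict[str, list[list[CnvCall]]] = {}
    for sid in sorted(by_sample):
        groups, singles = intra_individual_consensus(by_sample[sid], cfg.reciprocal_overlap)
        groups_by_sample[sid] = groups
        all_singletons[sid] = singles

    flat_singletons = [s for sid in sorted(all_singletons) for s in all_singletons[sid]]
    rescued, _discarded = inter_individual_rescue(flat_singletons, post_qc, cfg.reciprocal_overlap)
    rescued_by_sample: dict[str, list[CnvCall]] = defaultdict(list)
    for r in rescued:
        rescued_by_sample[r.sample_id].append(r)

    rows = []
    for sid in sorted(by_sample):
        cnvs = [curate_breakpoints(g) for g in groups_by_sample[sid]]
        cnvs += [_rescued_to_consensus(r) for r in rescued_by_sample.get(sid, [])]
        cnvs.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end))
        final[sid] = cnvs
        rows.append(
            {
                "sample": sid,
                "raw": len(raw_by_sample[sid]),
                "post_qc": len(by_sample[sid]),
                "intra_groups": len(groups_by_sample[sid]),
                "singletons": len(all_singletons[sid]),
                "rescued": len(rescued_by_sample.get(sid, [])),
                "final": len(cnvs),
            }
        )
    report = IntegrationReport(excluded_samples=excluded, funnel=pd.DataFrame(rows))
    return final, report
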
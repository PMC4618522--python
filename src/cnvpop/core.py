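"""Shared domain types, coordinate conventions and interval arithmetic.

All intervals are 0-based half-open internally (``[start, end)``), the BED
convention.  File readers/writers convert from/to the 1-based inclusive
convention used in printed tables.  Copy-number state is categorical: classes
0 and 1 are deletions, 3 and "4+" duplications; the copy-neutral class 2 is
never represented.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields
from typing import Iterable, Optional, Sequence


class CnClass(enum.Enum):
    """Copy-number class of a CNV: 0/1 deletions, 3/4+ duplications."""

    HOM_DEL = "0"
    HET_DEL = "1"
    DUP = "3"
    AMP = "4+"

    @property
    def direction(self) -> str:
        """'deletion' or 'duplication' — a pure function of the class."""
        return "deletion" if self in (CnClass.HOM_DEL, CnClass.HET_DEL) else "duplication"

    @classmethod
    def from_copy_number(cls, cn: int | str) -> "CnClass":
        """Map a reported integer copy number to a class.

        Copy numbers above 4 collapse into the single amplification class.
        Copy number 2 (copy-neutral) is rejected.
        """
        s = str(cn).strip()
        if s in ("4+", ">4", "4plus"):
            return cls.AMP
        n = int(s)
        if n == 2:
            raise ValueError("copy-neutral class (CN=2) is not a CNV")
        if n in (0, 1):
            return cls(str(n))
        if n == 3:
            return cls.DUP
        if n >= 4:
            return cls.AMP
        raise ValueError(f"invalid copy number {cn!r}")


#: deterministic ordering used when breaking class ties toward the extreme
_EXTREMENESS = {CnClass.HOM_DEL: 0, CnClass.AMP: 0, CnClass.HET_DEL: 1, CnClass.DUP: 1}


def more_extreme(a: CnClass, b: CnClass) -> CnClass:
    """Of two same-direction classes, the more extreme (0 over 1, 4+ over 3)."""
    return a if _EXTREMENESS[a] <= _EXTREMENESS[b] else b


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start ({self.chrom}:{self.start}-{self.end})")
        if self.start < 0:
            raise ValueError("start must be non-negative")

    @property
    def span(self) -> int:
        return self.end - self.start


def normalize_chrom(chrom: str) -> str:
    """Strip any 'chr' prefix so one chromosome dialect is used internally."""
    c = str(chrom).strip()
    return c[3:] if c.lower().startswith("chr") else c


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Bases shared by two intervals; 0 on different chromosomes."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def intersect(a: GenomicInterval, b: GenomicInterval) -> GenomicInterval:
    """The shared segment of two overlapping intervals.

    Raises ``ValueError`` when the intervals do not overlap — callers must
    check ``overlap_bp`` first.
    """
    if overlap_bp(a, b) < 1:
        raise ValueError(f"intervals {a} and {b} do not overlap")
    return GenomicInterval(a.chrom, max(a.start, b.start), min(a.end, b.end))


def union_span(intervals: Iterable[GenomicInterval]) -> int:
    """Total bases covered by the union of intervals (each base once)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    total = 0
    for segs in by_chrom.values():
        segs.sort()
        cur_s, cur_e = segs[0]
        for s, e in segs[1:]:
            if s > cur_e:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        total += cur_e - cur_s
    return total


#: caller registry: algorithm identifier -> platform family
ALGORITHM_PLATFORM = {
    "quantisnp": "array",
    "cnvpartition": "array",
    "cnmops": "ngs",
    "vendor_ngs": "ngs",
}


@dataclass(frozen=True)
class CnvCall:
    """One raw CNV call from one algorithm on one sample."""

    sample_id: str
    platform: str  # 'array' | 'ngs'
    algorithm: str
    interval: GenomicInterval
    cn: CnClass
    n_units: int  # consecutive probes (array) or windows (ngs)
    quality: Optional[float] = None

    def __post_init__(self):
        if self.platform not in ("array", "ngs"):
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.algorithm in ALGORITHM_PLATFORM and ALGORITHM_PLATFORM[self.algorithm] != self.platform:
            raise ValueError(
                f"algorithm {self.algorithm!r} is registered as "
                f"{ALGORITHM_PLATFORM[self.algorithm]!r}, not {self.platform!r}"
            )
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")


SUBPOPULATIONS = ("Q1", "Q2", "Q3")


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata: subpopulation label and ancestry fraction."""

    sample_id: str
    subpopulation: str  # Q1 | Q2 | Q3 | admixed
    ancestry_fraction: float = 1.0
    ancestry_threshold: float = 0.65

    def __post_init__(self):
        if self.subpopulation not in SUBPOPULATIONS + ("admixed",):
            raise ValueError(f"unknown subpopulation {self.subpopulation!r}")
        if not 0.0 <= self.ancestry_fraction <= 1.0:
            raise ValueError("ancestry_fraction must be in [0,1]")
        if self.subpopulation != "admixed" and self.ancestry_fraction < self.ancestry_threshold:
            raise ValueError(
                f"assigned subpopulation requires ancestry fraction >= {self.ancestry_threshold}"
            )


@dataclass
class PipelineConfig:
    """All thresholds of the pipeline, every one overridable.

    Defaults follow the study design: a five-consecutive-unit size cut-off,
    at-least-twice observation for retention, a ±500 kb tagging window,
    deletions carried by at least 4 of 97 individuals (MAF ≈ 2%) for the LD
    analysis, a 20% carrier-frequency boundary between low-frequency and
    common CNVRs, and a 6.7e-6 significance level for cytoband enrichment.
    """

    min_units: int = 5
    min_consensus_observations: int = 2
    outlier_mad_k: float = 3.0
    tag_window_bp: int = 500_000
    min_deletion_carriers: int = 4
    common_cnvr_threshold: float = 0.20
    freq_bins: tuple[float, ...] = (0.01, 0.10)
    enrichment_alpha: float = 6.7e-6
    ancestry_threshold: float = 0.65
    reciprocal_overlap: float = 0.0  # 0 disables the reciprocal-overlap requirement
    rng_seed: int = 0

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name in ("rng_seed", "reciprocal_overlap"):
                continue
            if isinstance(v, (int, float)) and v <= 0:
                raise ValueError(f"{f.name} must be strictly positive")
        if tuple(sorted(self.freq_bins)) != tuple(self.freq_bins) or len(set(self.freq_bins)) != len(
            self.freq_bins
        ):
            raise ValueError("freq_bins must be strictly increasing")
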
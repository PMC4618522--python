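"""Deletion-tagging LD analysis.

Common deletions (carried by at least ``min_deletion_carriers`` individuals,
MAF ≈ 2% at the default 4-of-97) are coded as binary carrier vectors and
correlated (squared Pearson r) against every SNP within ±500 kb of the
deletion breakpoints, separately for two SNP panels (the full sequencing
panel and the array subset).  For each deletion the closest SNP with the
highest r² wins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cnvr import CnvRegion, merge_direction_loci
from .consensus import ConsensusCnv
from .core import GenomicInterval, overlap_bp
from .io import SnpGenotypeMatrix


@dataclass
class DeletionGenotypeVector:
    """Binary carrier status of one deletion locus across the cohort."""

    deletion_id: str
    interval: GenomicInterval
    carrier_status: np.ndarray  # int8 per sample: 0/1, -1 missing
    sample_ids: list[str]

    @property
    def carrier_count(self) -> int:
        return int((self.carrier_status > 0).sum())


@dataclass
class TagResult:
    """Best tagging SNP for one deletion in one panel."""

    deletion_id: str
    snp_id: Optional[str]
    r2: Optional[float]
    distance_bp: Optional[int]
    panel: str
    n_snps_in_window: int


def select_common_deletions(
    per_sample_cnvs: dict[str, list[ConsensusCnv]],
    cnvrs: Sequence[CnvRegion],
    min_carriers: int = 4,
    coding: str = "binary",
) -> list[DeletionGenotypeVector]:
    """Cohort-wide deletion loci with ≥ ``min_carriers`` distinct carriers.

    Loci are the subpopulation-merged deletion CNVRs lifted to the full
    cohort: overlapping deletion regions (any subpopulation, CN0 or CN1)
    collapse into one locus, and a sample is a carrier iff it has any final
    deletion-direction CNV overlapping the locus.  ``coding='binary'``
    (default) records carrier status 0/1; ``coding='dosage'`` records the
    deleted-allele count inferred from the CN class (CN0 → 2, CN1 → 1).
    """
    if coding not in ("binary", "dosage"):
        raise ValueError(f"unknown coding {coding!r}")
    from .core import CnClass

    samples = sorted(per_sample_cnvs)
    loci = [r for r in merge_direction_loci(list(cnvrs)) if r.direction == "deletion"]
    out = []
    for i, locus in enumerate(loci):
        status = np.zeros(len(samples), dtype=np.int8)
        for si, sid in enumerate(samples):
            for c in per_sample_cnvs[sid]:
                if c.cn.direction == "deletion" and overlap_bp(c.interval, locus.interval) >= 1:
                    if coding == "binary":
                        status[si] = 1
                        break
                    status[si] = max(status[si], 2 if c.cn is CnClass.HOM_DEL else 1)
        vec = DeletionGenotypeVector(
            deletion_id=f"del_{locus.interval.chrom}_{locus.interval.start}_{locus.interval.end}",
            interval=locus.interval,
            carrier_status=status,
            sample_ids=samples,
        )
        if vec.carrier_count >= min_carriers:
            out.append(vec)
    return out


def snps_in_window(
    locus: GenomicInterval,
    snp_chroms: np.ndarray,
    snp_positions: np.ndarray,
    window: int = 500_000,
) -> np.ndarray:
    """Indices of SNPs within [start−window, end+window] on the locus chromosome.

    Window boundaries are closed; SNPs inside the deletion are included.
    """
    on_chrom = np.flatnonzero(snp_chroms.astype(str) == locus.chrom)
    pos = snp_positions[on_chrom]
    lo, hi = locus.start - window, locus.end + window
    keep = (pos >= lo) & (pos <= hi)
    return on_chrom[keep]


def pairwise_r2(carrier: np.ndarray, dosage: np.ndarray) -> Optional[float]:
    """Squared Pearson correlation over pairwise-complete samples.

    Returns None when fewer than 2 complete pairs exist or either vector is
    constant over the complete cases (undefined r²).
    """
    c = np.asarray(carrier, dtype=float)
    d = np.asarray(dosage, dtype=float)
    ok = (c >= 0) & (d >= 0)
    c, d = c[ok], d[ok]
    if len(c) < 2:
        return None
    if np.all(c == c[0]) or np.all(d == d[0]):
        return None
    r = np.corrcoef(c, d)[0, 1]
    return float(r * r)


def _distance(locus: GenomicInterval, pos: int) -> int:
    """Distance from a SNP to the nearer breakpoint (0 inside the deletion)."""
    if locus.start <= pos < locus.end:
        return 0
    return int(locus.start - pos) if pos < locus.start else int(pos - locus.end + 1)


def best_tag(
    deletion: DeletionGenotypeVector,
    snps: SnpGenotypeMatrix,
    panel_indices: Optional[np.ndarray] = None,
    window: int = 500_000,
    panel: str = "wgs_full",
) -> TagResult:
    """The closest SNP with the highest r² inside the window.

    Ties on r² break by smaller distance to the nearer breakpoint, then by
    lower position.  SNPs with undefined r² never compete.
    """
    idx = snps_in_window(deletion.interval, snps.chroms, snps.positions, window)
    if panel_indices is not None:
        idx = idx[np.isin(idx, panel_indices)]
    best = None  # (-r2, distance, position, snp index)
    for j in idx:
        r2 = pairwise_r2(deletion.carrier_status, snps.dosages[j])
        if r2 is None:
            continue
        key = (-r2, _distance(deletion.interval, int(snps.positions[j])), int(snps.positions[j]), int(j))
        if best is None or key < best:
            best = key
    if best is None:
        return TagResult(deletion.deletion_id, None, None, None, panel, len(idx))
    neg_r2, dist, pos, j = best
    return TagResult(
        deletion_id=deletion.deletion_id,
        snp_id=snps.snp_ids[j],
        r2=-neg_r2,
        distance_bp=dist,
        panel=panel,
        n_snps_in_window=len(idx),
    )


def tag_all(
    deletions: Sequence[DeletionGenotypeVector],
    snps: SnpGenotypeMatrix,
    panels: dict[str, Optional[np.ndarray]],
    window: int = 500_000,
) -> pd.DataFrame:
    """Best-tag table over every deletion × panel."""
    rows = []
    for name, panel_idx in panels.items():
        for d in deletions:
            t = best_tag(d, snps, panel_idx, window, panel=name)
            rows.append(
                {
                    "deletion": t.deletion_id,
                    "panel": t.panel,
                    "snp": t.snp_id,
                    "r2": t.r2,
                    "distance_bp": t.distance_bp,
                    "n_snps_in_window": t.n_snps_in_window,
                }
            )
    return pd.DataFrame(rows)


def tagging_summary(
    tag_table: pd.DataFrame,
    thresholds: Sequence[float] = (0.5, 0.7, 0.8, 0.9, 1.0),
    genic_deletions: Optional[set] = None,
) -> pd.DataFrame:
    """Per-panel tagged counts/fractions at each r² threshold.

    A deletion counts at threshold t when its best r² exceeds t; the top
    threshold 1.0 counts complete LD (r² ≥ 1 within numerical tolerance),
    so a perfectly tagged set scores 1.0 at every threshold.  Fractions are
    monotone non-increasing in t.  When ``genic_deletions`` is given the
    same summary is repeated for that subset.
    """
    rows = []
    for panel, sub in tag_table.groupby("panel"):
        subsets = {"all": sub}
        if genic_deletions is not None:
            subsets["genic"] = sub[sub["deletion"].isin(genic_deletions)]
        for subset_name, ss in subsets.items():
            n = len(ss)
            r2 = pd.to_numeric(ss["r2"], errors="coerce").fillna(-1.0).to_numpy(dtype=float)
            for t in thresholds:
                hit = int((r2 >= 1.0 - 1e-12).sum()) if t >= 1.0 else int((r2 > t).sum())
                rows.append(
                    {
                        "panel": panel,
                        "subset": subset_name,
                        "threshold": t,
                        "n_deletions": n,
                        "n_tagged": hit,
                        "fraction": hit / n if n else 0.0,
                    }
                )
    return pd.DataFrame(rows)
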
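"""Distribution summaries and hypothesis tests for the cohort.

Per-class density curves of CNV counts and affected bases, one-way
ANOVA + Tukey HSD comparisons between subpopulations, PCA on the
sample × CNVR carrier matrix, and Fisher's-exact cytoband burden tests
against a reference cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cnvr import CnvRegion
from .consensus import ConsensusCnv


@dataclass
class DensityCurve:
    """A Gaussian-kernel density estimate evaluated on a fixed grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    group: str = ""
    variable: str = ""

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule of thumb: 0.9 · min(sd, IQR/1.34) · n^(−1/5)."""
    n = len(values)
    sd = float(np.std(values, ddof=1)) if n > 1 else 0.0
    q75, q25 = np.percentile(values, [75, 25])
    iqr = float(q75 - q25)
    spread = min(x for x in (sd, iqr / 1.34) if x > 0) if (sd > 0 or iqr > 0) else 0.0
    return 0.9 * spread * n ** (-1 / 5)


def density_curve(
    values: Sequence[float],
    bandwidth: Optional[float] = None,
    grid_points: int = 512,
    group: str = "",
    variable: str = "",
) -> DensityCurve:
    """Gaussian KDE on a grid spanning [min−3h, max+3h].

    Default bandwidth is Silverman's rule; a floor of 1e−6 × data range
    (or 1e−6 for constant input) keeps degenerate samples well defined —
    a constant sample yields one narrow spike that still integrates to 1.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 2 or not np.all(np.isfinite(x)):
        raise ValueError("density_curve needs >=2 finite values")
    rng_ = float(x.max() - x.min())
    h = bandwidth if bandwidth is not None else silverman_bandwidth(x)
    h = max(h, 1e-6 * rng_ if rng_ > 0 else 1e-6)
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, grid_points)
    z = (grid[:, None] - x[None, :]) / h
    dens = np.exp(-0.5 * z**2).sum(axis=1) / (len(x) * h * np.sqrt(2 * np.pi))
    return DensityCurve(grid=grid, density=dens, bandwidth=h, group=group, variable=variable)


def anova_tukey(groups: dict[str, Sequence[float]]) -> pd.DataFrame:
    """One-way ANOVA F test plus Tukey HSD pairwise adjusted p-values.

    Returns a long-form table (group_a, group_b, mean_diff, p_tukey) with one
    row per unordered pair, plus ``anova_F``/``anova_p`` attached in
    ``DataFrame.attrs``.  Zero variance in every group makes the p-values
    undefined (NaN).
    """
    names = sorted(groups)
    if len(names) < 2:
        raise ValueError("need >=2 groups")
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs >=2 values")
    pooled_var = np.sum([np.var(a, ddof=1) * (len(a) - 1) for a in arrays])
    rows = []
    if pooled_var == 0:
        F, p = np.nan, np.nan
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                rows.append(
                    {
                        "group_a": names[i],
                        "group_b": names[j],
                        "mean_diff": float(arrays[j].mean() - arrays[i].mean()),
                        "p_tukey": np.nan,
                    }
                )
    else:
        F, p = sps.f_oneway(*arrays)
        res = sps.tukey_hsd(*arrays)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                rows.append(
                    {
                        "group_a": names[i],
                        "group_b": names[j],
                        "mean_diff": float(arrays[j].mean() - arrays[i].mean()),
                        "p_tukey": float(res.pvalue[i, j]),
                    }
                )
    out = pd.DataFrame(rows)
    out.attrs["anova_F"] = float(F) if np.isfinite(F) else np.nan
    out.attrs["anova_p"] = float(p) if np.isfinite(p) else np.nan
    return out


def carrier_matrix(
    per_sample_cnvs: dict[str, list[ConsensusCnv]], cnvrs: Sequence[CnvRegion]
) -> tuple[np.ndarray, list[str]]:
    """Samples × CNVR 0/1 incidence matrix (carrier = member of the region)."""
    samples = sorted(per_sample_cnvs)
    sample_idx = {s: i for i, s in enumerate(samples)}
    M = np.zeros((len(samples), len(cnvrs)), dtype=float)
    for j, r in enumerate(cnvrs):
        for sid in r.carriers:
            if sid in sample_idx:
                M[sample_idx[sid], j] = 1.0
    return M, samples


def cnv_pca(
    per_sample_cnvs: dict[str, list[ConsensusCnv]],
    cnvrs: Sequence[CnvRegion],
    n_components: int = 2,
) -> pd.DataFrame:
    """PCA of CNV sharing: SVD of the column-centred carrier matrix.

    Coordinates are deterministic up to sign (signs are fixed so each
    component's largest-magnitude loading is positive).
    """
    if len(per_sample_cnvs) < 3 or len(cnvrs) < 2:
        raise ValueError("PCA needs >=3 samples and >=2 CNVRs")
    M, samples = carrier_matrix(per_sample_cnvs, cnvrs)
    if not np.any(M):
        raise ValueError("carrier matrix has rank 0")
    X = M - M.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(n_components, len(S))
    coords = U[:, :k] * S[:k]
    for c in range(k):  # sign convention
        m = np.argmax(np.abs(Vt[c]))
        if Vt[c, m] < 0:
            coords[:, c] *= -1
    return pd.DataFrame(coords, index=samples, columns=[f"PC{i+1}" for i in range(k)])


@dataclass
class EnrichmentResult:
    """Fisher's-exact burden comparison for one cytoband."""

    cytoband: str
    count_a: int
    total_a: int
    count_b: int
    total_b: int
    odds_ratio: float
    p_value: float
    significant: bool


def cytoband_enrichment(
    counts_a: dict[str, int],
    total_a: int,
    counts_b: dict[str, int],
    total_b: int,
    alpha: float = 6.7e-6,
) -> list[EnrichmentResult]:
    """Two-sided Fisher's exact test per cytoband.

    The 2×2 table per band is [[a, A−a], [b, B−b]] with A/B the cohorts'
    CNVR totals.  Bands absent from both cohorts get p=1.
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("cohort totals must be positive")
    out = []
    for band in sorted(set(counts_a) | set(counts_b)):
        a = counts_a.get(band, 0)
        b = counts_b.get(band, 0)
        if a > total_a or b > total_b:
            raise ValueError(f"band {band}: count exceeds cohort total")
        odds, p = sps.fisher_exact([[a, total_a - a], [b, total_b - b]], alternative="two-sided")
        out.append(
            EnrichmentResult(
                cytoband=band,
                count_a=a,
                total_a=total_a,
                count_b=b,
                total_b=total_b,
                odds_ratio=float(odds),
                p_value=float(p),
                significant=bool(p < alpha),
            )
        )
    out.sort(key=lambda r: r.p_value)
    return out


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cytoband": r.cytoband,
                "count_reference": r.count_b,
                "count_cohort": r.count_a,
                "odds_ratio": r.odds_ratio,
                "p_value": r.p_value,
                "significant": r.significant,
            }
            for r in results
        ]
    )
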
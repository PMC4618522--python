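"""Synthetic CNV cohort generator with planted, recoverable truth.

The generator emulates the statistical structure of a three-subpopulation
cohort genotyped on two platform families:

* three subpopulations (default 57/20/20 samples) with distinct CNV
  allele-frequency spectra; inbreeding coefficients inflate homozygosity in
  the first two groups (consanguinity), planting a homozygous-deletion
  excess there, while a duplication allele-frequency scale plants an
  amplification excess in the third;
* diploid genotypes drawn under Hardy–Weinberg within each subpopulation
  (hom deletion allele → CN0, het → CN1; hom duplication → CN4+, het → CN3);
* four caller call-sets: array callers are less sensitive with coarse
  (high-jitter) breakpoints, sequencing callers more sensitive with precise
  breakpoints; the vendor sequencing caller never reports CN0 and
  over-reports duplications; every algorithm appends false positives, and a
  few designated outlier samples get a large excess of them;
* SNPs around each deletion locus, with perfect tagging SNPs (carrier
  indicator genotypes, r² = 1 by construction) planted at a configured
  probability for common deletions.

Fixed seed ⇒ byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import CnClass, CnvCall, GenomicInterval, SampleMeta
from .io import SnpGenotypeMatrix

ALGORITHMS = ("quantisnp", "cnvpartition", "cnmops", "vendor_ngs")
PLATFORM_OF = {
    "quantisnp": "array",
    "cnvpartition": "array",
    "cnmops": "ngs",
    "vendor_ngs": "ngs",
}


@dataclass
class SimConfig:
    """Study-scale defaults for the synthetic cohort.

    CNVR size medians per class follow the cohort summary (4187 bp CN0,
    8604 CN1, 20101 CN3, 10669 CN4+); locus sizes are drawn from the
    heterozygous-class medians (most carriers are het), the homozygous-class
    medians shape false-positive calls of those classes.
    """

    n_samples: dict = field(default_factory=lambda: {"Q1": 57, "Q2": 20, "Q3": 20})
    n_deletion_loci: int = 150
    n_duplication_loci: int = 120
    n_polymorphic_loci: int = 12  # duplication loci planted on top of deletion loci
    af_beta: tuple[float, float] = (0.8, 4.0)
    af_private: tuple[float, float] = (0.2, 0.6)  # uniform range for private loci
    private_locus_fraction: float = 0.30
    inbreeding_f: dict = field(default_factory=lambda: {"Q1": 0.08, "Q2": 0.05, "Q3": 0.0})
    dup_af_scale: dict = field(default_factory=lambda: {"Q1": 1.0, "Q2": 1.0, "Q3": 1.25})
    size_medians: dict = field(
        default_factory=lambda: {"0": 4187.0, "1": 8604.0, "3": 20101.0, "4+": 10669.0}
    )
    size_sigma: float = 0.7  # log-normal sigma (log scale)
    n_chromosomes: int = 22
    chrom_length: int = 100_000_000
    # platform model
    sensitivity: dict = field(
        default_factory=lambda: {
            "quantisnp": 0.75,
            "cnvpartition": 0.55,
            "cnmops": 0.88,
            "vendor_ngs": 0.85,
        }
    )
    jitter_sd: dict = field(default_factory=lambda: {"array": 800.0, "ngs": 50.0})
    unit_size: dict = field(default_factory=lambda: {"array": 1000, "ngs": 500})
    fp_rate: dict = field(
        default_factory=lambda: {
            "quantisnp": 25.0,
            "cnvpartition": 15.0,
            "cnmops": 30.0,
            "vendor_ngs": 30.0,
        }
    )
    duplication_excess: float = 3.0  # vendor_ngs FP duplication bias factor
    n_outliers: int = 3
    outlier_fp_multiplier: float = 40.0
    # SNP model
    snps_per_window: int = 25
    perfect_tag_prob: float = 0.6
    array_subset_fraction: float = 0.35
    array_tag_prob: float = 0.2  # probability a planted tag is on the array panel
    min_tag_carriers: int = 4
    rng_seed: int = 0

    def __post_init__(self):
        for name, v in (
            ("private_locus_fraction", self.private_locus_fraction),
            ("perfect_tag_prob", self.perfect_tag_prob),
            ("array_subset_fraction", self.array_subset_fraction),
            ("array_tag_prob", self.array_tag_prob),
        ):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        for s in self.sensitivity.values():
            if not 0.0 <= s <= 1.0:
                raise ValueError("sensitivities must be in [0,1]")
        if any(m <= 0 for m in self.size_medians.values()):
            raise ValueError("size medians must be positive")


@dataclass
class TruthLocus:
    """One planted CNV locus shared by all its carriers."""

    locus_id: str
    interval: GenomicInterval
    direction: str  # 'deletion' | 'duplication'
    af: dict  # subpopulation -> allele frequency
    private_to: Optional[str] = None


@dataclass
class TrueCnv:
    """One true CNV event in one sample."""

    sample_id: str
    locus_id: str
    interval: GenomicInterval
    cn: CnClass


@dataclass
class TruthSet:
    """Planted ground truth of the synthetic cohort."""

    loci: list[TruthLocus]
    cnvs: list[TrueCnv]
    samples: list[SampleMeta]
    outlier_samples: list[str]
    # filled by simulate_linked_snps: deletion locus_id -> (snp_id, target r2)
    tags: dict = field(default_factory=dict)

    def loci_by_id(self) -> dict:
        return {l.locus_id: l for l in self.loci}

    def cnvs_of(self, sample_id: str) -> list[TrueCnv]:
        return [c for c in self.cnvs if c.sample_id == sample_id]

    def carrier_counts(self) -> dict:
        out: dict[str, int] = {l.locus_id: 0 for l in self.loci}
        seen = set()
        for c in self.cnvs:
            key = (c.locus_id, c.sample_id)
            if key not in seen:
                seen.add(key)
                out[c.locus_id] += 1
        return out


def expected_carrier_prob(af: float, f: float) -> dict:
    """Hardy–Weinberg (with inbreeding F) genotype probabilities at a locus."""
    hom = af * af + f * af * (1 - af)
    het = 2 * af * (1 - af) * (1 - f)
    return {"hom": hom, "het": het, "any": hom + het}


def _place_loci(cfg: SimConfig, rng: np.random.Generator) -> list[tuple[GenomicInterval, str]]:
    """Lay out non-overlapping loci along the simulated chromosomes.

    Returns (interval, direction) pairs; the first ``n_polymorphic_loci``
    duplication loci are placed overlapping a deletion locus to plant
    polymorphic (del+dup) sites.
    """
    sizes_del = np.exp(
        np.log(cfg.size_medians["1"]) + cfg.size_sigma * rng.standard_normal(cfg.n_deletion_loci)
    ).astype(int)
    sizes_dup = np.exp(
        np.log(cfg.size_medians["3"]) + cfg.size_sigma * rng.standard_normal(cfg.n_duplication_loci)
    ).astype(int)
    sizes_del = np.maximum(sizes_del, 50)
    sizes_dup = np.maximum(sizes_dup, 50)

    placed: list[tuple[GenomicInterval, str]] = []
    cursor = {c: 1_000_000 for c in range(1, cfg.n_chromosomes + 1)}
    order = [("deletion", int(s)) for s in sizes_del] + [
        ("duplication", int(s)) for s in sizes_dup[cfg.n_polymorphic_loci :]
    ]
    for i, (direction, size) in enumerate(order):
        chrom = i % cfg.n_chromosomes + 1
        gap = int(rng.integers(1_100_000, 1_500_000))  # keep ±500 kb SNP windows apart
        pos = cursor[chrom]
        if pos + size + gap > cfg.chrom_length:
            raise ValueError("not enough simulated genome to place all loci")
        placed.append((GenomicInterval(str(chrom), pos, pos + size), direction))
        cursor[chrom] = pos + size + gap
    # polymorphic duplications ride on top of the first deletion loci
    del_loci = [iv for iv, d in placed if d == "deletion"]
    for k in range(cfg.n_polymorphic_loci):
        base = del_loci[k]
        size = int(sizes_dup[k])
        start = base.start + base.span // 2
        placed.append((GenomicInterval(base.chrom, start, start + size), "duplication"))
    return placed


def simulate_truth(cfg: SimConfig) -> TruthSet:
    """Draw the cohort: loci, allele frequencies, genotypes, outliers."""
    rng = np.random.default_rng(cfg.rng_seed)
    subpops = sorted(cfg.n_samples)
    samples: list[SampleMeta] = []
    for sp in subpops:
        for i in range(cfg.n_samples[sp]):
            samples.append(SampleMeta(f"{sp}_s{i:04d}", sp, ancestry_fraction=0.9))

    layout = _place_loci(cfg, rng)
    loci: list[TruthLocus] = []
    n_private = int(round(cfg.private_locus_fraction * len(layout)))
    for i, (iv, direction) in enumerate(layout):
        private_to = subpops[i % len(subpops)] if i < n_private else None
        af = {}
        if private_to is not None:
            base = float(rng.uniform(*cfg.af_private))
            for sp in subpops:
                af[sp] = base if sp == private_to else 0.0
        else:
            base = float(rng.beta(*cfg.af_beta))
            for sp in subpops:
                a = base * (cfg.dup_af_scale[sp] if direction == "duplication" else 1.0)
                af[sp] = min(a, 0.95)
        loci.append(
            TruthLocus(f"{direction[:3]}_{i:04d}", iv, direction, af, private_to)
        )

    cnvs: list[TrueCnv] = []
    for locus in loci:
        for sm in samples:
            p = locus.af[sm.subpopulation]
            if p <= 0:
                continue
            f = cfg.inbreeding_f[sm.subpopulation]
            probs = expected_carrier_prob(p, f)
            u = rng.random()
            if u < probs["hom"]:
                cn = CnClass.HOM_DEL if locus.direction == "deletion" else CnClass.AMP
            elif u < probs["hom"] + probs["het"]:
                cn = CnClass.HET_DEL if locus.direction == "deletion" else CnClass.DUP
            else:
                continue
            cnvs.append(TrueCnv(sm.sample_id, locus.locus_id, locus.interval, cn))

    ids = [s.sample_id for s in samples]
    outliers = sorted(rng.choice(ids, size=min(cfg.n_outliers, len(ids)), replace=False).tolist())
    return TruthSet(loci=loci, cnvs=cnvs, samples=samples, outlier_samples=outliers)


def _fp_class(rng: np.random.Generator, algorithm: str, dup_excess: float) -> CnClass:
    if algorithm == "vendor_ngs":
        # never CN0; duplications over-represented
        w = np.array([0.0, 1.0, dup_excess, dup_excess / 2])
    else:
        w = np.array([0.5, 1.0, 1.0, 0.5])
    w = w / w.sum()
    return list(CnClass)[int(rng.choice(4, p=w))]


def emit_platform_calls(truth: TruthSet, cfg: SimConfig) -> dict[str, list[CnvCall]]:
    """Produce the four per-algorithm raw call sets from the truth.

    Each true CNV is detected with the algorithm's sensitivity; detected
    calls get Gaussian breakpoint jitter (array ≫ sequencing) and a unit
    count proportional to span.  False positives are appended per algorithm,
    heavily inflated for the designated outlier samples.  The vendor
    sequencing caller relabels CN0 as CN1 and over-emits duplications.
    """
    rng = np.random.default_rng(cfg.rng_seed + 1)
    out: dict[str, list[CnvCall]] = {a: [] for a in ALGORITHMS}
    outlier_set = set(truth.outlier_samples)

    for alg in ALGORITHMS:
        platform = PLATFORM_OF[alg]
        sd = cfg.jitter_sd[platform]
        unit = cfg.unit_size[platform]
        sens = cfg.sensitivity[alg]
        for tc in truth.cnvs:
            if rng.random() >= sens:
                continue
            iv = tc.interval
            if sd > 0:
                ds, de = rng.normal(0, sd, 2)
                start = max(0, int(round(iv.start + ds)))
                end = int(round(iv.end + de))
                if end <= start:
                    end = start + max(unit, iv.span // 2)
            else:
                start, end = iv.start, iv.end
            cn = tc.cn
            if alg == "vendor_ngs" and cn == CnClass.HOM_DEL:
                cn = CnClass.HET_DEL
            out[alg].append(
                CnvCall(
                    sample_id=tc.sample_id,
                    platform=platform,
                    algorithm=alg,
                    interval=GenomicInterval(iv.chrom, start, end),
                    cn=cn,
                    n_units=max(1, int(round((end - start) / unit))),
                )
            )
        # false positives
        base_rate = cfg.fp_rate[alg]
        for sm in truth.samples:
            rate = base_rate * (cfg.outlier_fp_multiplier if sm.sample_id in outlier_set else 1.0)
            n_fp = int(rng.poisson(rate)) if rate > 0 else 0
            for _ in range(n_fp):
                cn = _fp_class(rng, alg, cfg.duplication_excess)
                size = max(
                    unit,
                    int(np.exp(np.log(cfg.size_medians[cn.value]) + cfg.size_sigma * rng.standard_normal())),
                )
                chrom = str(int(rng.integers(1, cfg.n_chromosomes + 1)))
                start = int(rng.integers(0, cfg.chrom_length - size))
                out[alg].append(
                    CnvCall(
                        sample_id=sm.sample_id,
                        platform=platform,
                        algorithm=alg,
                        interval=GenomicInterval(chrom, start, start + size),
                        cn=cn,
                        n_units=max(1, int(round(size / unit))),
                    )
                )
        out[alg].sort(key=lambda c: (c.sample_id, c.interval.chrom, c.interval.start, c.interval.end))
    return out


@dataclass
class TagRegistry:
    """Planted tagging SNPs and the array panel definition."""

    tags: dict  # deletion locus_id -> snp_id (target r2 = 1 by construction)
    array_subset_snp_ids: list[str]


def simulate_linked_snps(truth: TruthSet, cfg: SimConfig) -> tuple[SnpGenotypeMatrix, TagRegistry]:
    """SNPs around each deletion locus, with planted perfect tags.

    For each common deletion (truth carriers ≥ ``min_tag_carriers``), with
    probability ``perfect_tag_prob`` one SNP in the window carries the
    carrier-indicator genotype (dosage 1 for carriers, 0 otherwise), giving
    r² = 1 against the binary CNV coding by construction.  All other SNPs
    are drawn independently of the deletion under Hardy–Weinberg.
    """
    rng = np.random.default_rng(cfg.rng_seed + 2)
    sample_ids = [s.sample_id for s in truth.samples]
    n = len(sample_ids)
    carrier_of: dict[str, np.ndarray] = {}
    idx = {sid: i for i, sid in enumerate(sample_ids)}
    for locus in truth.loci:
        if locus.direction != "deletion":
            continue
        v = np.zeros(n, dtype=np.int8)
        carrier_of[locus.locus_id] = v
    for tc in truth.cnvs:
        if tc.locus_id in carrier_of:
            carrier_of[tc.locus_id][idx[tc.sample_id]] = 1

    snp_ids: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    rows: list[np.ndarray] = []
    tags: dict[str, str] = {}
    array_ids: list[str] = []
    window = 500_000

    for locus in truth.loci:
        if locus.direction != "deletion" or cfg.snps_per_window == 0:
            continue
        lo = max(0, locus.interval.start - window)
        hi = locus.interval.end + window
        pos = np.sort(rng.integers(lo, hi, size=cfg.snps_per_window))
        carriers = carrier_of[locus.locus_id]
        tag_slot = -1
        if carriers.sum() >= cfg.min_tag_carriers and rng.random() < cfg.perfect_tag_prob:
            tag_slot = int(rng.integers(0, cfg.snps_per_window))
        for k in range(cfg.snps_per_window):
            sid = f"snp_{locus.locus_id}_{k}"
            if k == tag_slot:
                geno = carriers.copy()
                tags[locus.locus_id] = sid
                on_array = rng.random() < cfg.array_tag_prob
            else:
                af = float(rng.uniform(0.05, 0.5))
                u = rng.random(n)
                geno = np.where(u < af * af, 2, np.where(u < af * af + 2 * af * (1 - af), 1, 0)).astype(np.int8)
                on_array = rng.random() < cfg.array_subset_fraction
            snp_ids.append(sid)
            chroms.append(locus.interval.chrom)
            positions.append(int(pos[k]))
            rows.append(geno)
            if on_array:
                array_ids.append(sid)

    dosages = np.array(rows, dtype=np.int8) if rows else np.empty((0, n), dtype=np.int8)
    mat = SnpGenotypeMatrix(
        sample_ids=sample_ids,
        snp_ids=snp_ids,
        chroms=np.array(chroms, dtype=object),
        positions=np.array(positions, dtype=np.int64),
        dosages=dosages,
    )
    truth.tags = {lid: (sid, 1.0) for lid, sid in tags.items()}
    return mat, TagRegistry(tags=tags, array_subset_snp_ids=array_ids)


def synthetic_annotation_bundle(truth: TruthSet, cfg: SimConfig, seed: Optional[int] = None):
    """A synthetic annotation bundle matched to the simulated genome.

    Cytobands tile every chromosome; genes (with exon models), miRNA,
    promoter and TFBS intervals are placed partly on the planted loci and
    partly at random; a reference CNVR catalogue is built from jittered
    copies of most truth loci (mostly high-resolution records), so a known
    fraction of CNVRs is novel.  A random tenth of the genes is marked as a
    disease gene.  All components are synthetic stand-ins for the public
    annotation tracks a real analysis would load.
    """
    from .io import AnnotationBundle, Gene

    rng = np.random.default_rng(cfg.rng_seed + 3 if seed is None else seed)
    cytobands = []
    band_size = 5_000_000
    for c in range(1, cfg.n_chromosomes + 1):
        n_bands = cfg.chrom_length // band_size
        for b in range(n_bands):
            arm = "p" if b < n_bands // 2 else "q"
            k = b + 1 if arm == "p" else b + 1 - n_bands // 2
            cytobands.append(
                (GenomicInterval(str(c), b * band_size, (b + 1) * band_size), f"{c}{arm}{k}")
            )

    def random_point(on_locus_prob: float) -> tuple[str, int]:
        if truth.loci and rng.random() < on_locus_prob:
            l = truth.loci[int(rng.integers(0, len(truth.loci)))]
            return l.interval.chrom, int(
                rng.integers(max(0, l.interval.start - 5000), l.interval.end + 5000)
            )
        return str(int(rng.integers(1, cfg.n_chromosomes + 1))), int(
            rng.integers(0, cfg.chrom_length - 200_000)
        )

    genes, disease = [], {}
    for g in range(300):
        chrom, start = random_point(on_locus_prob=0.4)
        n_ex = int(rng.integers(2, 16))
        exon_len, intron_len = 150, int(rng.integers(500, 8000))
        exons = []
        pos = start
        for _ in range(n_ex):
            exons.append(GenomicInterval(chrom, pos, pos + exon_len))
            pos += exon_len + intron_len
        gene = Gene(
            f"GENE{g:03d}",
            GenomicInterval(chrom, start, exons[-1].end),
            "+" if rng.random() < 0.5 else "-",
            tuple(exons),
        )
        genes.append(gene)
        if rng.random() < 0.1:
            disease[gene.name] = f"MIM{600000 + g}"

    def flat_track(n: int, size: int, on_locus_prob: float) -> list[GenomicInterval]:
        out = []
        for _ in range(n):
            chrom, start = random_point(on_locus_prob)
            out.append(GenomicInterval(chrom, start, start + size))
        return out

    reference = []
    for l in truth.loci:
        if rng.random() < 0.8:
            jit = int(rng.integers(-2000, 2000))
            s = max(0, l.interval.start + jit)
            reference.append(
                (
                    GenomicInterval(l.interval.chrom, s, s + l.interval.span),
                    l.direction,
                    "high" if rng.random() < 0.85 else "low",
                )
            )
    return AnnotationBundle(
        genes=genes,
        mirnas=flat_track(150, 100, 0.3),
        promoters=flat_track(250, 1500, 0.3),
        tfbs=flat_track(500, 30, 0.35),
        cytobands=cytobands,
        disease_genes=disease,
        reference_cnvrs=reference,
    )


def noiseless_config(**overrides) -> SimConfig:
    """A noise-free copy of the defaults: sensitivity 1, no jitter, no FPs.

    The limit in which the four call sets equal the planted truth (modulo
    the vendor caller's CN0 relabelling); used by recovery tests.
    """
    cfg = SimConfig(**overrides)
    cfg.sensitivity = {a: 1.0 for a in ALGORITHMS}
    cfg.jitter_sd = {"array": 0.0, "ngs": 0.0}
    cfg.fp_rate = {a: 0.0 for a in ALGORITHMS}
    cfg.n_outliers = 0
    return cfg
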
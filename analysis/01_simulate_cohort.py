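#!/usr/bin/env python
"""Simulate the synthetic study cohort and write its raw inputs.

Generates 97 samples (57 Q1 / 20 Q2 / 20 Q3) with planted CNV loci,
per-algorithm call sets from the two platform families, SNP genotypes with
planted tagging SNPs, and the truth tables downstream scripts are scored
against.
"""

import os

import pandas as pd

from _common import SEED, cohort, outdir
from cnvpop import simulate as sim
from cnvpop.io import write_cnv_calls, write_genotype_vcf

d = outdir("01_cohort")
cfg, truth, call_sets = cohort()
snps, registry = sim.simulate_linked_snps(truth, cfg)

for alg in sim.ALGORITHMS:
    write_cnv_calls(call_sets[alg], os.path.join(d, f"calls_{alg}.tsv"))
write_genotype_vcf(snps, os.path.join(d, "snps.vcf"))
pd.DataFrame(
    [
        {"sample": s.sample_id, "subpopulation": s.subpopulation,
         "ancestry_fraction": s.ancestry_fraction,
         "outlier": int(s.sample_id in truth.outlier_samples)}
        for s in truth.samples
    ]
).to_csv(os.path.join(d, "samples.tsv"), sep="\t", index=False)
pd.DataFrame(
    [
        {"locus_id": l.locus_id, "chrom": l.interval.chrom,
         "start": l.interval.start + 1, "end": l.interval.end,
         "direction": l.direction, "private_to": l.private_to or "",
         **{f"af_{sp}": l.af[sp] for sp in sorted(l.af)}}
        for l in truth.loci
    ]
).to_csv(os.path.join(d, "truth_loci.tsv"), sep="\t", index=False)

n_calls = {a: len(call_sets[a]) for a in sim.ALGORITHMS}
print(f"seed {SEED}: {len(truth.samples)} samples, {len(truth.loci)} planted loci "
      f"({sum(1 for l in truth.loci if l.direction == 'deletion')} deletion, "
      f"{sum(1 for l in truth.loci if l.direction == 'duplication')} duplication), "
      f"{len(truth.cnvs)} true CNV events")
print(f"raw calls per algorithm: {n_calls}")
print(f"planted outlier samples: {truth.outlier_samples}")
print(f"{len(snps.snp_ids)} SNPs simulated, {len(registry.tags)} perfect tags planted, "
      f"{len(registry.array_subset_snp_ids)} SNPs on the array panel")
print(f"outputs in {d}")
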
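#!/usr/bin/env python
"""Find tagging SNPs for common deletions and compare the two SNP panels.

Common deletions (≥4 carriers of 97, MAF ≈ 2%) are coded as binary carrier
vectors; for each, the closest SNP with the highest r² within ±500 kb is
selected, separately for the full sequencing panel and its array subset.
The planted perfect tags bound what the panels can recover.
"""

import dataclasses
import os

import numpy as np

from _common import merged, outdir
from cnvpop import simulate as sim
from cnvpop.tagging import DeletionGenotypeVector, select_common_deletions, tag_all, tagging_summary

d = outdir("06_tagging")
cfg, truth, final, report, subpop_of, sizes, cnvrs_by_subpop = merged()
snps, registry = sim.simulate_linked_snps(truth, cfg)

all_cnvrs = [r for sp in ("Q1", "Q2", "Q3") for r in cnvrs_by_subpop[sp]]
deletions = select_common_deletions(final, all_cnvrs, min_carriers=4)
kept = sorted(final)
order = [snps.sample_ids.index(s) for s in kept]
deletions = [
    DeletionGenotypeVector(x.deletion_id, x.interval,
                           x.carrier_status[[x.sample_ids.index(s) for s in kept]], kept)
    for x in deletions
]
snps_kept = dataclasses.replace(snps, sample_ids=kept, dosages=snps.dosages[:, order])
snp_index = {s: i for i, s in enumerate(snps.snp_ids)}
array_idx = np.array(sorted(snp_index[s] for s in registry.array_subset_snp_ids))

table = tag_all(deletions, snps_kept, {"wgs_full": None, "array_subset": array_idx})
table.to_csv(os.path.join(d, "tag_table.tsv"), sep="\t", index=False)
summary = tagging_summary(table)
summary.to_csv(os.path.join(d, "tag_summary.tsv"), sep="\t", index=False)

print(f"{len(deletions)} common deletions (>=4 carriers of {len(kept)}); "
      f"{len(registry.tags)} perfect tags were planted cohort-wide")
sel = summary[summary["subset"] == "all"].pivot_table(
    index="threshold", columns="panel", values="fraction")
print("fraction of deletions tagged (best r² > threshold):")
for t, row in sel.iterrows():
    print(f"  r² > {t}: sequencing panel {row['wgs_full']:.1%} | "
          f"array subset {row['array_subset']:.1%}")
print(f"outputs in {d}")
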
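#!/usr/bin/env python
"""Merge per-individual CNVs into subpopulation CNV regions (CNVRs).

Single-linkage merge per copy-number class within each subpopulation, the
polymorphic (deletion+duplication co-located) accounting, frequency classes,
and the per-class summary tables.
"""

import os

from _common import merged, outdir
from cnvpop.cnvr import find_polymorphic, summarize_by_class
from cnvpop.io import write_cnvr_table

d = outdir("03_cnvr")
cfg, truth, final, report, subpop_of, sizes, cnvrs_by_subpop = merged()

all_cnvrs = [r for sp in ("Q1", "Q2", "Q3") for r in cnvrs_by_subpop[sp]]
write_cnvr_table(all_cnvrs, os.path.join(d, "cnvrs.tsv"), sizes)
tables = summarize_by_class(final, cnvrs_by_subpop)
for name, df in tables.items():
    df.to_csv(os.path.join(d, f"summary_{name}.tsv"), sep="\t", index=False)

print(f"subpopulation sizes after QC: {sizes}")
for sp in ("Q1", "Q2", "Q3"):
    pairs, tally = find_polymorphic(cnvrs_by_subpop[sp])
    print(f"{sp}: {len(cnvrs_by_subpop[sp])} per-class CNVRs; "
          f"combined {tally['combined']} "
          f"({tally['deletion_loci']} deletion + {tally['duplication_loci']} duplication "
          f"- {tally['polymorphic']} polymorphic)")
coh = tables["cohort"].set_index("statistic")
print(f"median CNVs per individual: {coh.loc['median', 'n_total']:.0f}; "
      f"median genome affected: {coh.loc['median', 'bp_total'] / 1e6:.2f} Mb")
print(f"outputs in {d}")
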
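#!/usr/bin/env python
"""Annotate CNVRs: cytobands, genic impact, regulatory features, novelty.

Uses the synthetic annotation bundle matched to the simulated genome (gene
models with exons, miRNA/promoter/TFBS tracks, a disease-gene list and a
reference CNVR catalogue) and writes the per-subpopulation per-class
functional annotation counts.
"""

import os

from _common import merged, outdir
from cnvpop import simulate as sim
from cnvpop.annotation import annotate_all

d = outdir("04_annotation")
cfg, truth, final, report, subpop_of, sizes, cnvrs_by_subpop = merged()
bundle = sim.synthetic_annotation_bundle(truth, cfg)

all_cnvrs = [r for sp in ("Q1", "Q2", "Q3") for r in cnvrs_by_subpop[sp]]
annotated, counts = annotate_all(all_cnvrs, bundle)
counts.to_csv(os.path.join(d, "annotation_counts.tsv"), sep="\t", index=False)

tot = counts["total"].sum()
print(f"{tot} CNVRs annotated against {len(bundle.genes)} gene models, "
      f"{len(bundle.cytobands)} cytobands, {len(bundle.reference_cnvrs)} reference records")
print(f"genic: {counts['genic'].sum()} ({counts['genic'].sum() / tot:.1%}); "
      f"novel vs reference catalogue: {counts['novel'].sum()} "
      f"({counts['novel'].sum() / tot:.1%}); "
      f"novel genic: {counts['novel_genic'].sum()}")
n_disease = counts["disease_gene"].sum()
print(f"CNVRs hitting a curated disease gene (excluding partially-genic "
      f"duplications): {n_disease}")
impacts = {}
for a in annotated:
    for gi in a.gene_impacts:
        impacts[gi.impact] = impacts.get(gi.impact, 0) + 1
print(f"per-gene impact classes: {impacts}")
print(f"outputs in {d}")
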
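#!/usr/bin/env python
"""Subpopulation comparisons: density curves, ANOVA–Tukey, PCA, cytoband burden.

Per-class CNV-count density curves per subpopulation, Tukey-adjusted
pairwise tests of the per-class burden (the planted effects: homozygous
deletions elevated in the consanguineous Q1/Q2, duplications elevated in
Q3), PCA on CNV sharing, and Fisher's-exact cytoband burden against the
reference catalogue.
"""

import os
from collections import defaultdict

import pandas as pd

from _common import merged, outdir
from cnvpop import simulate as sim
from cnvpop.annotation import annotate_all, assign_cytoband
from cnvpop.core import CnClass
from cnvpop.stats import anova_tukey, cnv_pca, cytoband_enrichment, density_curve, enrichment_table

d = outdir("05_stats")
cfg, truth, final, report, subpop_of, sizes, cnvrs_by_subpop = merged()

counts = {cls: {sp: [] for sp in ("Q1", "Q2", "Q3")} for cls in CnClass}
for sid, cnvs in final.items():
    sp = subpop_of[sid]
    for cls in CnClass:
        counts[cls][sp].append(sum(1 for c in cnvs if c.cn is cls))

dens_rows, tk_rows = [], []
for cls in CnClass:
    for sp, vals in counts[cls].items():
        if len(set(vals)) > 1:
            dc = density_curve(vals, group=sp, variable=f"count_cn{cls.value}")
            dens_rows += [{"variable": dc.variable, "group": sp, "x": x, "density": y}
                          for x, y in zip(dc.grid[::16], dc.density[::16])]
    tk = anova_tukey(counts[cls])
    for _, r in tk.iterrows():
        tk_rows.append({"cn": cls.value, **r.to_dict()})
pd.DataFrame(dens_rows).to_csv(os.path.join(d, "density_curves.tsv"), sep="\t", index=False)
tk_df = pd.DataFrame(tk_rows)
tk_df.to_csv(os.path.join(d, "anova_tukey.tsv"), sep="\t", index=False)

print("Tukey-adjusted pairwise p-values for per-individual CNV counts:")
for _, r in tk_df.iterrows():
    print(f"  CN {r['cn']}: {r['group_a']} vs {r['group_b']}: p={r['p_tukey']:.3g}")

all_cnvrs = [r for sp in ("Q1", "Q2", "Q3") for r in cnvrs_by_subpop[sp]]
pca = cnv_pca(final, all_cnvrs)
pca.round(6).to_csv(os.path.join(d, "pca_coords.tsv"), sep="\t")
spread = pca.join(pd.Series(subpop_of, name="subpop")).groupby("subpop")["PC1"].mean()
print(f"PC1 subpopulation means (CNV-sharing PCA): "
      + ", ".join(f"{k}={v:.2f}" for k, v in spread.items()))

bundle = sim.synthetic_annotation_bundle(truth, cfg)
annotated, _ = annotate_all(all_cnvrs, bundle)
ref_counts = defaultdict(int)
n_ref = 0
for iv, _, res in bundle.reference_cnvrs:
    if res == "high":
        n_ref += 1
        for band in assign_cytoband(iv, bundle.cytobands):
            ref_counts[band] += 1
frames = []
for sp in ("Q1", "Q2", "Q3"):
    band_counts = defaultdict(int)
    for a in annotated:
        if a.cnvr.subpopulation == sp:
            for band in a.cytobands:
                band_counts[band] += 1
    res = cytoband_enrichment(dict(band_counts), len(cnvrs_by_subpop[sp]),
                              dict(ref_counts), max(n_ref, 1))
    df = enrichment_table(res)
    df.insert(0, "subpopulation", sp)
    frames.append(df)
enr = pd.concat(frames, ignore_index=True)
enr.to_csv(os.path.join(d, "cytoband_enrichment.tsv"), sep="\t", index=False)
n_sig = int(enr["significant"].sum())
print(f"cytoband burden: {len(enr)} tests, {n_sig} significant at alpha=6.7e-6 "
      f"(no enrichment planted; smallest p={enr['p_value'].min():.2g})")
print(f"outputs in {d}")
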
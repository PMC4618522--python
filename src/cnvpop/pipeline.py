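"""End-to-end orchestration: simulate → integrate → merge → annotate →
stats → tag → report, with serialized intermediates and a run manifest.

This is a library surface: the numbered drivers under ``analysis/`` call
these functions; there is no shell entry point.  All stage outputs are
tab-separated text under one output directory, and two runs with the same
configuration and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from collections import defaultdict
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann
from . import cnvr as cnvr_mod
from . import consensus as cons
from . import simulate as sim
from . import stats as st
from . import tagging as tag
from .core import CnClass, CnvCall, GenomicInterval, PipelineConfig, normalize_chrom
from .io import write_cnv_calls, write_cnvr_table, write_genotype_vcf


def load_config(path_or_dict) -> tuple[PipelineConfig, sim.SimConfig]:
    """Build (pipeline, simulation) configs from a YAML file or dict.

    Unknown keys are fatal and named, so every threshold in a config file is
    guaranteed to be meaningful.
    """
    if isinstance(path_or_dict, (str, os.PathLike)):
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(path_or_dict or {})
    pipe_keys = {f.name for f in dataclasses.fields(PipelineConfig)}
    sim_keys = {f.name for f in dataclasses.fields(sim.SimConfig)}
    unknown = set(raw.get("pipeline", {})) - pipe_keys
    unknown |= set(raw.get("simulation", {})) - sim_keys
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    pcfg = PipelineConfig(**raw.get("pipeline", {}))
    scfg = sim.SimConfig(**raw.get("simulation", {}))
    seed = raw.get("seed")
    if seed is not None:
        pcfg.rng_seed = int(seed)
        scfg.rng_seed = int(seed)
    return pcfg, scfg


def _final_cnvs_frame(per_sample: dict[str, list[cons.ConsensusCnv]]) -> pd.DataFrame:
    rows = []
    for sid in sorted(per_sample):
        for c in per_sample[sid]:
            rows.append(
                {
                    "sample": sid,
                    "chrom": c.interval.chrom,
                    "start": c.interval.start + 1,
                    "end": c.interval.end,
                    "cn": c.cn.value,
                    "support": ";".join(sorted(f"{p}:{a}" for p, a in c.support)),
                    "support_mode": c.support_mode,
                    "breakpoint_source": c.breakpoint_source,
                    "fallback": int(c.fallback),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sample", "chrom", "start", "end", "cn",
            "support", "support_mode", "breakpoint_source", "fallback",
        ],
    )


def read_final_cnvs(path: str) -> dict[str, list[cons.ConsensusCnv]]:
    """Inverse of the serialized final-CNV table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, list[cons.ConsensusCnv]] = defaultdict(list)
    for _, r in df.iterrows():
        support = frozenset(tuple(x.split(":")) for x in r["support"].split(";"))
        out[r["sample"]].append(
            cons.ConsensusCnv(
                sample_id=r["sample"],
                interval=GenomicInterval(normalize_chrom(r["chrom"]), int(r["start"]) - 1, int(r["end"])),
                cn=CnClass(r["cn"]),
                support=support,
                support_mode=r["support_mode"],
                breakpoint_source=r["breakpoint_source"],
                fallback=bool(int(r["fallback"])),
            )
        )
    return dict(out)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record: config snapshot, seed, stage counts, digests."""

    seed: int
    config: dict
    stage_counts: dict
    output_digests: dict

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_pipeline(config=None, outdir: str = "results/run", resume: bool = False) -> dict:
    """Execute the full pipeline on a synthetic cohort.

    Returns a dict of in-memory artifacts (truth, final CNVs, CNVR lists,
    summary tables, tag table, manifest).  With ``resume=True`` the
    simulate/integrate stages reload serialized intermediates when present.
    """
    pcfg, scfg = load_config(config)
    os.makedirs(outdir, exist_ok=True)
    p = lambda name: os.path.join(outdir, name)
    stage_counts: dict = {}

    # --- simulate -----------------------------------------------------------
    truth = sim.simulate_truth(scfg)
    call_sets = sim.emit_platform_calls(truth, scfg)
    snps, registry = sim.simulate_linked_snps(truth, scfg)
    bundle = sim.synthetic_annotation_bundle(truth, scfg)
    all_calls = [c for a in sim.ALGORITHMS for c in call_sets[a]]
    for a in sim.ALGORITHMS:
        write_cnv_calls(call_sets[a], p(f"calls_{a}.tsv"))
    pd.DataFrame(
        [
            {"sample": s.sample_id, "subpopulation": s.subpopulation, "ancestry_fraction": s.ancestry_fraction}
            for s in truth.samples
        ]
    ).to_csv(p("samples.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "locus_id": l.locus_id,
                "chrom": l.interval.chrom,
                "start": l.interval.start + 1,
                "end": l.interval.end,
                "direction": l.direction,
                **{f"af_{sp}": l.af[sp] for sp in sorted(l.af)},
            }
            for l in truth.loci
        ]
    ).to_csv(p("truth_loci.tsv"), sep="\t", index=False)
    write_genotype_vcf(snps, p("snps.vcf"))
    stage_counts["simulate"] = {
        "samples": len(truth.samples),
        "loci": len(truth.loci),
        "true_cnvs": len(truth.cnvs),
        "raw_calls": len(all_calls),
        "snps": len(snps.snp_ids),
    }

    # --- integrate ----------------------------------------------------------
    if resume and os.path.exists(p("final_cnvs.tsv")):
        final = read_final_cnvs(p("final_cnvs.tsv"))
        report = None
    else:
        final, report = cons.integrate(all_calls, pcfg)
        _final_cnvs_frame(final).to_csv(p("final_cnvs.tsv"), sep="\t", index=False)
        report.to_tsv(p("funnel.tsv"))
        with open(p("excluded_samples.txt"), "w") as fh:
            fh.write("\n".join(report.excluded_samples) + ("\n" if report.excluded_samples else ""))
    stage_counts["integrate"] = {
        "samples_kept": len(final),
        "final_cnvs": sum(len(v) for v in final.values()),
    }

    # --- CNVR merge ---------------------------------------------------------
    subpop_of = {s.sample_id: s.subpopulation for s in truth.samples}
    subpop_sizes = {
        sp: sum(1 for sid in final if subpop_of[sid] == sp)
        for sp in sorted(set(subpop_of.values()))
    }
    cnvrs_by_subpop: dict[str, list] = {}
    for sp in sorted(subpop_sizes):
        cnvs_sp = [c for sid, cl in final.items() if subpop_of[sid] == sp for c in cl]
        cnvrs_by_subpop[sp] = cnvr_mod.merge_to_cnvrs(cnvs_sp, sp, subpop_sizes[sp])
    all_cnvrs = [r for sp in sorted(cnvrs_by_subpop) for r in cnvrs_by_subpop[sp]]
    write_cnvr_table(
        all_cnvrs, p("cnvrs.tsv"), subpop_sizes, pcfg.freq_bins, pcfg.common_cnvr_threshold
    )
    summaries = cnvr_mod.summarize_by_class(final, cnvrs_by_subpop)
    for name, df in summaries.items():
        df.to_csv(p(f"summary_{name}.tsv"), sep="\t", index=False)
    stage_counts["cnvr"] = {
        "cnvrs": len(all_cnvrs),
        **{
            f"polymorphic_{sp}": cnvr_mod.find_polymorphic(cnvrs_by_subpop[sp])[1]["polymorphic"]
            for sp in sorted(cnvrs_by_subpop)
        },
    }

    # --- annotate -----------------------------------------------------------
    annotated, ann_counts = ann.annotate_all(all_cnvrs, bundle)
    ann_counts.to_csv(p("annotation_counts.tsv"), sep="\t", index=False)
    stage_counts["annotate"] = {
        "genic": int(ann_counts["genic"].sum()) if len(ann_counts) else 0,
        "novel": int(ann_counts["novel"].sum()) if len(ann_counts) else 0,
    }

    # --- stats --------------------------------------------------------------
    counts_by_subpop_class: dict[str, dict[str, list[float]]] = defaultdict(dict)
    per_sample_tbl = summaries["per_sample"].set_index("sample")
    for cls in CnClass:
        for sp in sorted(subpop_sizes):
            vals = [
                float(per_sample_tbl.loc[sid, f"n_{cls.value}"])
                for sid in sorted(final)
                if subpop_of[sid] == sp
            ]
            counts_by_subpop_class[cls.value][sp] = vals
    dens_rows, anova_rows = [], []
    for cls in CnClass:
        groups = counts_by_subpop_class[cls.value]
        for sp, vals in groups.items():
            if len(vals) >= 2 and len(set(vals)) > 1:
                d = st.density_curve(vals, group=sp, variable=f"count_cn{cls.value}")
                dens_rows += [
                    {"variable": d.variable, "group": sp, "x": float(x), "density": float(y)}
                    for x, y in zip(d.grid[::16], d.density[::16])
                ]
        if all(len(v) >= 2 for v in groups.values()):
            tk = st.anova_tukey(groups)
            for _, r in tk.iterrows():
                anova_rows.append({"cn": cls.value, **r.to_dict()})
    pd.DataFrame(dens_rows).to_csv(p("density_curves.tsv"), sep="\t", index=False)
    anova_df = pd.DataFrame(anova_rows)
    anova_df.to_csv(p("anova_tukey.tsv"), sep="\t", index=False)
    pca = st.cnv_pca(final, all_cnvrs)
    pca.round(6).to_csv(p("pca_coords.tsv"), sep="\t")
    # cytoband burden vs the synthetic reference catalogue
    ref_counts: dict[str, int] = defaultdict(int)
    for iv, _, res in bundle.reference_cnvrs:
        if res == "high":
            for band in ann.assign_cytoband(iv, bundle.cytobands):
                ref_counts[band] += 1
    total_ref = sum(1 for _, _, res in bundle.reference_cnvrs if res == "high")
    enr_frames = []
    for sp in sorted(cnvrs_by_subpop):
        counts_sp: dict[str, int] = defaultdict(int)
        for a in annotated:
            if a.cnvr.subpopulation == sp:
                for band in a.cytobands:
                    counts_sp[band] += 1
        res = st.cytoband_enrichment(
            dict(counts_sp), len(cnvrs_by_subpop[sp]), dict(ref_counts), max(total_ref, 1),
            alpha=pcfg.enrichment_alpha,
        )
        df = st.enrichment_table(res)
        df.insert(0, "subpopulation", sp)
        enr_frames.append(df)
    enrichment = pd.concat(enr_frames, ignore_index=True) if enr_frames else pd.DataFrame()
    enrichment.to_csv(p("cytoband_enrichment.tsv"), sep="\t", index=False)
    stage_counts["stats"] = {
        "anova_rows": len(anova_df),
        "enrichment_significant": int(enrichment["significant"].sum()) if len(enrichment) else 0,
    }

    # --- tagging ------------------------------------------------------------
    deletions = tag.select_common_deletions(final, all_cnvrs, pcfg.min_deletion_carriers)
    snp_index = {sid: i for i, sid in enumerate(snps.snp_ids)}
    array_idx = np.array(
        sorted(snp_index[s] for s in registry.array_subset_snp_ids if s in snp_index), dtype=int
    )
    # deletion vectors are over all simulated samples; restrict to kept ones
    kept = sorted(final)
    kept_mask = np.array([sid in set(kept) for sid in snps.sample_ids])
    dels_kept = []
    for d in deletions:
        order = [d.sample_ids.index(s) for s in kept]
        dels_kept.append(
            tag.DeletionGenotypeVector(d.deletion_id, d.interval, d.carrier_status[order], kept)
        )
    snps_kept = dataclasses.replace(
        snps,
        sample_ids=kept,
        dosages=snps.dosages[:, [snps.sample_ids.index(s) for s in kept]],
    )
    tag_table = tag.tag_all(
        dels_kept, snps_kept, {"wgs_full": None, "array_subset": array_idx}, pcfg.tag_window_bp
    )
    tag_table.to_csv(p("tag_table.tsv"), sep="\t", index=False)
    genic_dels = {
        d.deletion_id
        for d in dels_kept
        if any(
            g.interval.chrom == d.interval.chrom
            and min(g.interval.end, d.interval.end) > max(g.interval.start, d.interval.start)
            for g in bundle.genes
        )
    }
    tag_summary = tag.tagging_summary(tag_table, genic_deletions=genic_dels)
    tag_summary.to_csv(p("tag_summary.tsv"), sep="\t", index=False)
    stage_counts["tagging"] = {
        "common_deletions": len(dels_kept),
        "planted_tags": len(registry.tags),
    }

    manifest = RunManifest(
        seed=scfg.rng_seed,
        config={"pipeline": dataclasses.asdict(pcfg), "simulation": dataclasses.asdict(scfg)},
        stage_counts=stage_counts,
        output_digests={},
    )
    artifacts = {
        "truth": truth,
        "call_sets": call_sets,
        "snps": snps,
        "registry": registry,
        "bundle": bundle,
        "final": final,
        "report": report,
        "cnvrs_by_subpop": cnvrs_by_subpop,
        "annotated": annotated,
        "annotation_counts": ann_counts,
        "summaries": summaries,
        "anova": anova_df,
        "pca": pca,
        "enrichment": enrichment,
        "tag_table": tag_table,
        "tag_summary": tag_summary,
        "manifest": manifest,
        "outdir": outdir,
    }
    write_report(artifacts, p("report.txt"))
    manifest.output_digests = {
        f: _sha256(p(f)) for f in sorted(os.listdir(outdir)) if f != "manifest.json"
    }
    manifest.write(p("manifest.json"))
    return artifacts


def write_report(artifacts: dict, path: str) -> None:
    """Human-readable run summary: funnel, class summary, annotation,
    tagging thresholds and enrichment hits."""
    lines = []
    manifest: RunManifest = artifacts["manifest"]
    lines.append("# Population CNV pipeline report")
    lines.append(f"seed: {manifest.seed}")
    lines.append("")
    lines.append("## Integration funnel")
    for stage, counts in manifest.stage_counts.items():
        lines.append(f"  {stage}: " + ", ".join(f"{k}={v}" for k, v in counts.items()))
    n_final = sum(len(v) for v in artifacts["final"].values())
    lines.append(f"  total final CNVs: {n_final}")
    lines.append("")
    lines.append("## Per-class cohort summary")
    cohort = artifacts["summaries"]["cohort"]
    lines.append(cohort.to_string(index=False) if len(cohort) else "  (no CNVs)")
    lines.append("")
    lines.append("## Functional annotation counts")
    ann_counts = artifacts["annotation_counts"]
    lines.append(ann_counts.to_string(index=False) if len(ann_counts) else "  (no CNVRs)")
    lines.append("")
    lines.append("## Deletion tagging")
    ts = artifacts["tag_summary"]
    lines.append(ts.to_string(index=False) if len(ts) else "  (no common deletions)")
    lines.append("")
    lines.append("## Cytoband enrichment (significant)")
    enr = artifacts["enrichment"]
    sig = enr[enr["significant"]] if len(enr) else enr
    lines.append(sig.to_string(index=False) if len(sig) else "  none at configured alpha")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
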
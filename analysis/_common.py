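"""Shared state builder for the numbered analysis scripts.

Every script drives one pipeline stage over the same seeded synthetic
cohort (97 samples: 57/20/20 across the three subpopulations, the study
scale).  Stages are recomputed deterministically from the seed rather than
deserialized, so each script is runnable on its own; the tables each script
writes under results/ are the record of what it found.
"""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from cnvpop import simulate as sim
from cnvpop.consensus import integrate
from cnvpop.cnvr import merge_to_cnvrs
from cnvpop.core import PipelineConfig

SEED = 7
RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")


def outdir(name: str) -> str:
    d = os.path.join(RESULTS, name)
    os.makedirs(d, exist_ok=True)
    return d


def cohort(seed: int = SEED):
    cfg = sim.SimConfig(rng_seed=seed)
    truth = sim.simulate_truth(cfg)
    call_sets = sim.emit_platform_calls(truth, cfg)
    return cfg, truth, call_sets


def integrated(seed: int = SEED):
    cfg, truth, call_sets = cohort(seed)
    calls = [c for a in sim.ALGORITHMS for c in call_sets[a]]
    final, report = integrate(calls, PipelineConfig(rng_seed=seed))
    return cfg, truth, call_sets, final, report


def merged(seed: int = SEED):
    cfg, truth, call_sets, final, report = integrated(seed)
    subpop_of = {s.sample_id: s.subpopulation for s in truth.samples}
    sizes = {
        sp: sum(1 for sid in final if subpop_of[sid] == sp) for sp in ("Q1", "Q2", "Q3")
    }
    cnvrs_by_subpop = {}
    for sp in ("Q1", "Q2", "Q3"):
        cnvs_sp = [c for sid, v in final.items() if subpop_of[sid] == sp for c in v]
        cnvrs_by_subpop[sp] = merge_to_cnvrs(cnvs_sp, sp, sizes[sp])
    return cfg, truth, final, report, subpop_of, sizes, cnvrs_by_subpop
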
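import numpy as np
import pytest

from cnvpop.core import CnClass, CnvCall, GenomicInterval


def mk_call(
    sample="s1",
    algorithm="cnmops",
    chrom="1",
    start=1000,
    end=2000,
    cn=CnClass.HET_DEL,
    n_units=5,
):
    from cnvpop.core import ALGORITHM_PLATFORM

    return CnvCall(
        sample_id=sample,
        platform=ALGORITHM_PLATFORM[algorithm],
        algorithm=algorithm,
        interval=GenomicInterval(chrom, start, end),
        cn=cn,
        n_units=n_units,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_cohort():
    """A small noisy synthetic cohort shared across tests (fixed seed)."""
    from cnvpop import simulate as sim

    cfg = sim.SimConfig(
        n_samples={"Q1": 20, "Q2": 10, "Q3": 10},
        n_deletion_loci=60,
        n_duplication_loci=40,
        n_polymorphic_loci=6,
        rng_seed=123,
    )
    truth = sim.simulate_truth(cfg)
    call_sets = sim.emit_platform_calls(truth, cfg)
    return cfg, truth, call_sets


@pytest.fixture(scope="session")
def noiseless_cohort():
    from cnvpop import simulate as sim

    cfg = sim.noiseless_config(
        n_samples={"Q1": 20, "Q2": 10, "Q3": 10},
        n_deletion_loci=60,
        n_duplication_loci=40,
        n_polymorphic_loci=6,
        rng_seed=321,
    )
    truth = sim.simulate_truth(cfg)
    call_sets = sim.emit_platform_calls(truth, cfg)
    return cfg, truth, call_sets
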
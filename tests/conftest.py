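import numpy as np
import pytest

from panrecover._seq import substream
from panrecover.pipeline import PipelineConfig, run_pipeline
from panrecover.simulate import (Population, SimulationConfig, SimulationTruth,
                                 derive_donor, derive_reference, simulate_ancestor)


@pytest.fixture(scope="session")
def small_sim():
    """Compact genome with planted deletions and one 1%-diverged donor."""
    cfg = SimulationConfig(ancestor_length=150_000, n_deletions=8,
                           deletion_length_range=(500, 4000),
                           donor_divergences=[0.01],
                           populations=[Population(6, 0.5)],
                           coverage=8, seed=11)
    ancestor = simulate_ancestor(cfg)
    reference, truth = derive_reference(ancestor, cfg)
    donor = derive_donor(ancestor, 0.01, cfg.seed, species="Donor.r1", truth=truth)
    return cfg, ancestor, reference, donor, truth


@pytest.fixture(scope="session")
def small_pipeline():
    """Full pipeline on a small two-population cohort."""
    rng = substream(11, "fixture-frequencies")
    freqs = rng.choice([0.1, 0.5, 0.9], size=8).tolist()
    cfg = PipelineConfig(sim=SimulationConfig(
        ancestor_length=150_000, n_deletions=8, deletion_length_range=(500, 4000),
        donor_divergences=[0.01], populations=[Population(6, freqs)],
        coverage=10, read_error_rate=0.01, seed=11))
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def standard_pipeline():
    """The standard benchmark: 1 Mb ancestor, 30 planted deletions
    (0.5-20 kb), one donor at 1% divergence, 20 diploid individuals at 10x
    with per-segment frequencies drawn from {0.1, 0.5, 0.9}."""
    rng = substream(1, "fixture-frequencies")
    freqs = rng.choice([0.1, 0.5, 0.9], size=30).tolist()
    cfg = PipelineConfig(sim=SimulationConfig(
        ancestor_length=1_000_000, n_deletions=30,
        deletion_length_range=(500, 20_000), donor_divergences=[0.01],
        populations=[Population(20, freqs)], coverage=10,
        read_error_rate=0.01, seed=1))
    return run_pipeline(cfg)
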
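import numpy as np
import pytest

from ernakit import PWMotif, SimulationConfig, generate, run_memory

_BASE = {"A": 0, "C": 1, "G": 2, "T": 3}


def pwm_from_consensus(consensus: str, name: str, strength: float = 0.85) -> PWMotif:
    m = np.full((len(consensus), 4), (1 - strength) / 3)
    for i, b in enumerate(consensus):
        m[i, _BASE[b]] = strength
    return PWMotif(name, m)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Scaled-down simulation for fast unit tests (400 kb, 16 enhancers)."""
    return SimulationConfig(
        genome_size=400_000,
        n_genes=12,
        n_enhancers=16,
        n_super=4,
        depth=60_000,
        n_replicates=3,
        n_down=4,
        n_up=3,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate(small_config)


@pytest.fixture(scope="session")
def small_run(small_dataset):
    ds = small_dataset
    return run_memory(
        ds.genes,
        ds.sample_reads,
        ds.condition_of,
        ds.h3k27ac_islands,
        ds.chrom_sizes,
        rnapii_by_condition=ds.rnapii_peaks,
        super_enhancers=ds.super_enhancers,
    )


@pytest.fixture(scope="session")
def default_runs():
    """Five seed-swept end-to-end runs at the default study conditions."""
    runs = []
    for seed in (17, 18, 19, 20, 21):
        ds = generate(SimulationConfig(seed=seed))
        res = run_memory(
            ds.genes,
            ds.sample_reads,
            ds.condition_of,
            ds.h3k27ac_islands,
            ds.chrom_sizes,
            rnapii_by_condition=ds.rnapii_peaks,
            super_enhancers=ds.super_enhancers,
        )
        runs.append((ds, res))
    return runs
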
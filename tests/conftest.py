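from __future__ import annotations

import numpy as np
import pytest

from genomesurvey import simulate


@pytest.fixture(scope="session")
def small_diploid():
    """A small diploid host with repeats; shared across tests."""
    config = simulate.SimulationConfig(
        host_length=60_000,
        host_gc=0.37,
        snp_rate=0.005,
        repeat_fraction=0.3,
        coverage=40.0,
        base_error_rate=0.002,
        seed=11,
    )
    haps, truth = simulate.simulate_host_genome(config)
    return config, haps, truth


@pytest.fixture(scope="session")
def contaminated_readset(small_diploid):
    """Host + one high-GC contaminant at 5% read abundance."""
    config, haps, truth = small_diploid
    contaminant = simulate.simulate_contaminant_genome(12_000, 0.65, seed=77)
    sources = [
        simulate.ReadSource("host", list(haps)),
        simulate.ReadSource("contaminant", [contaminant], abundance=0.05),
    ]
    readset = simulate.simulate_reads(sources, config)
    return readset, contaminant, truth


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join("ACGT"[i] for i in rng.choice(4, size=length, p=probs))
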
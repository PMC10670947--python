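"""Shared fixtures: seeded RNGs and small simulated genome sets."""

import numpy as np
import pytest

from sineortho.simulate import SimulationConfig, random_dna, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_pair():
    """A small 2-genome simulation with every pairwise locus class."""
    cfg = SimulationConfig(seed=11, n_loci={"PP": 5, "PM": 3, "MP": 3,
                                            "multimapper": 2, "edge_truncated": 1})
    genomes, truth, consensus = simulate(cfg)
    return cfg, genomes, truth, consensus


@pytest.fixture(scope="session")
def default_run():
    """The default-condition pairwise run (50 PP + 30 PM + 30 MP, 5%
    divergence, seed 1) shared by the slower checks."""
    from sineortho.pipeline import run_pairwise

    cfg = SimulationConfig(seed=1)
    genomes, truth, consensus = simulate(cfg)
    result = run_pairwise(genomes["A"], genomes["B"], consensus, "A", "B")
    return cfg, genomes, truth, consensus, result


def plant(host: str, insert: str, pos: int) -> str:
    """Overwrite host[pos:pos+len(insert)] with the insert sequence."""
    assert pos + len(insert) <= len(host)
    return host[:pos] + insert + host[pos + len(insert):]
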
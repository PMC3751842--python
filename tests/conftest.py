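import numpy as np
import pytest

from plastomics import simulate as sim


@pytest.fixture(scope="session")
def full_sim():
    """Study-scale simulation shared across test modules (seed 7)."""
    cfg = sim.default_config()
    genomes, truth = sim.simulate(cfg, seed=7)
    return cfg, genomes, truth


@pytest.fixture(scope="session")
def demo_sim():
    """Reduced-scale simulation for cheap end-to-end checks."""
    cfg = sim.demo_config(0.2)
    genomes, truth = sim.simulate(cfg, seed=11)
    return cfg, genomes, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


def random_dna(rng, n, p_at=0.5):
    p = np.array([p_at / 2, (1 - p_at) / 2, (1 - p_at) / 2, p_at / 2])
    return "".join("ACGT"[i] for i in rng.choice(4, size=n, p=p))


@pytest.fixture(scope="session")
def full_wga(full_sim):
    from plastomics import divergence as dv

    cfg, genomes, truth = full_sim
    wga, _ = dv.build_whole_genome_alignment(
        genomes, truth.structures, taxa=sorted(genomes)
    )
    return wga
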
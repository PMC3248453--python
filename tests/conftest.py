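import numpy as np
import pytest

from ltrcensus import (DegradationParams, SimulationConfig,
                       build_element_template, default_profiles,
                       default_templates, implant_elements)


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def gypsy_template():
    return build_element_template("Gypsy", True, 300, rng_seed=1)


@pytest.fixture(scope="session")
def copia_template():
    return build_element_template("Copia", False, 300, rng_seed=2)


@pytest.fixture(scope="session")
def small_genome():
    """200 kb genome with 3 intact copies of each default template."""
    cfg = SimulationConfig(background_len=200_000, copies_per_template=3, seed=5)
    genome, truth = implant_elements(cfg)
    return cfg, genome, truth


def random_dna(n: int, seed: int, gc: float = 0.48) -> str:
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join("ACGT"[i] for i in rng.choice(4, size=n, p=p))
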
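import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

from stressmix import ChemicalPanel

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")
from stressmix.simulate import CultureParams, GeneratorSpec


@pytest.fixture
def panel3() -> ChemicalPanel:
    return ChemicalPanel(("A", "B", "C"))


@pytest.fixture
def panel8() -> ChemicalPanel:
    return ChemicalPanel(tuple("ABCDEFGH"))


@pytest.fixture
def small_spec(panel3) -> GeneratorSpec:
    """3-chemical experiment with a planted pairwise antagonism."""
    return GeneratorSpec(
        panel=panel3,
        cultures={"c1": CultureParams(capacity=1.0, rate=0.4, inoculum=0.01)},
        single_effects={"A": 0.5, "B": 0.7, "C": 0.9},
        interaction_terms={("A", "B"): 2.0},
        n_replicates=4,
        n_controls=10,
        noise_sd=0.01,
        seed=7,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_g_lattice(panel_size: int, rng: np.random.Generator) -> dict[int, float]:
    """Random positive G over all non-empty subsets (log-normal around 1)."""
    return {
        m: float(np.exp(rng.normal(0.0, 0.5)))
        for m in range(1, 1 << panel_size)
    }
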
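import numpy as np
import pytest

import strimpute as si


def parents_panel(sim: si.SimulatedQuads) -> si.HaplotypePanel:
    """Truth-phased panel over the parent samples of a quad simulation."""
    parents = [s for s in sim.truth.samples if s.endswith(("father", "mother"))]
    return sim.truth.subset_samples(parents)


@pytest.fixture(scope="session")
def base_config() -> si.SimulationConfig:
    return si.SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def founder_panel(base_config) -> si.HaplotypePanel:
    return si.simulate_founder_haplotypes(base_config)


@pytest.fixture(scope="session")
def quad_sim(founder_panel, base_config) -> si.SimulatedQuads:
    return si.simulate_quads(
        founder_panel, 40, seed=8, recomb_switch_rate=base_config.recomb_switch_rate
    )


@pytest.fixture(scope="session")
def reference_panel(quad_sim) -> si.HaplotypePanel:
    return parents_panel(quad_sim)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
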
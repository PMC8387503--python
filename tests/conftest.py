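import numpy as np
import pytest

from trophoniche.mixing_model import SourceDistribution
from trophoniche.synthetic_data import GroupSpec, Scenario, SourceSpec


@pytest.fixture(scope="session")
def k3_specs() -> list[SourceSpec]:
    """Three well-separated sources at realistic forage-prey values."""
    return [
        SourceSpec("arctic_krill", -18.7, 0.3, 9.3, 0.6, 28),
        SourceSpec("herring", -17.9, 0.9, 12.7, 0.6, 40),
        SourceSpec("northern_krill", -19.5, 0.5, 10.7, 0.4, 110),
    ]


@pytest.fixture(scope="session")
def k3_sources(k3_specs) -> list[SourceDistribution]:
    return [
        SourceDistribution(s.name, (s.mu_c, s.mu_n), (s.sd_c, s.sd_n), s.n) for s in k3_specs
    ]


def make_k3_scenario(k3_specs, truth=(0.7, 0.2, 0.1), n=30, seed=7) -> Scenario:
    return Scenario(
        sources=tuple(k3_specs),
        groups=(GroupSpec("g1", "pre", tuple(truth), n),),
        process_sd_extra=(0.0, 0.0),
        seed=seed,
    )


@pytest.fixture(scope="session")
def k3_scenario(k3_specs) -> Scenario:
    return make_k3_scenario(k3_specs)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
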
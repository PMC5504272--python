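import numpy as np
import pytest

from energylandscape import (
    MEMParams,
    PlantedCohortConfig,
    build_cohort,
    build_landscape,
    planted_params,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def td_params():
    return planted_params("td_like")


@pytest.fixture(scope="session")
def asd_params():
    return planted_params("asd_like")


@pytest.fixture(scope="session")
def td_landscape(td_params):
    return build_landscape(td_params)


@pytest.fixture(scope="session")
def toy_k2():
    """K=2 landscape with energies {00: 0, 01: 2, 10: 3, 11: -1}.

    Minima {00, 11}; basin(11) = {11, 01, 10}; the minima merge at the
    barrier energy 2 (through pattern 01).
    """
    from energylandscape.landscape import EnergyLandscape

    return EnergyLandscape(k=2, energies=np.array([0.0, 2.0, 3.0, -1.0]))


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced synthetic cohort for IO/pipeline plumbing tests."""
    return build_cohort(
        PlantedCohortConfig(n_td=4, n_asd=4, n_timepoints=120, master_seed=7)
    )


def random_params(k: int, rng, scale: float = 0.5) -> MEMParams:
    J = rng.uniform(-scale, scale, (k, k))
    J = 0.5 * (J + J.T)
    np.fill_diagonal(J, 0.0)
    return MEMParams(h=rng.uniform(-scale, scale, k), J=J)
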
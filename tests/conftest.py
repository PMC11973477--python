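import numpy as np
import pytest

from macropka import (
    FreeEnergyTable,
    SiteInteractionModel,
    load_reference_dataset,
    surrogate_free_energies,
)

WATER_XYZ = """3
charge=0 water
O    0.000000    0.000000    0.117300
H    0.000000    0.757200   -0.469200
H    0.000000   -0.757200   -0.469200
"""


@pytest.fixture
def water_xyz(tmp_path):
    path = tmp_path / "water.xyz"
    path.write_text(WATER_XYZ)
    return path


@pytest.fixture(scope="session")
def benchmark_obs():
    """The packaged 32-pair experimental/computed benchmark."""
    return load_reference_dataset("table1")


@pytest.fixture
def tetra_model():
    """Noise-free 4-site surrogate with distinct intrinsic pKa."""
    return SiteInteractionModel(intrinsic_pk=[9.0, 6.0, 8.0, 3.0])


@pytest.fixture
def interacting_model():
    """3-site surrogate with pairwise protonation penalties."""
    eps = np.array([[0.0, 1.5, 0.5], [1.5, 0.0, 2.0], [0.5, 2.0, 0.0]])
    return SiteInteractionModel(intrinsic_pk=[9.0, 6.0, 8.0], interaction=eps)


@pytest.fixture
def interacting_table(interacting_model):
    return surrogate_free_energies(interacting_model)


def random_state_energies(rng: np.random.Generator, n_sites: int) -> dict:
    """Arbitrary state-function energies over the full hypercube."""
    import itertools

    return {
        "".join(bits): float(rng.normal(0.0, 50.0))
        for bits in itertools.product("01", repeat=n_sites)
    }
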
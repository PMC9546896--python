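import numpy as np
import pytest

from tslopt.crlb import sample_params
from tslopt.models import default_box
from tslopt.scheduler import TSLGrid, paper_grid


@pytest.fixture(scope="session")
def grid() -> TSLGrid:
    return paper_grid()


@pytest.fixture(scope="session")
def toy_grid() -> TSLGrid:
    """A tiny grid on which exhaustive enumeration is instant."""
    return TSLGrid(np.array([0.5, 2.0, 5.0, 12.0, 25.0, 40.0, 55.0]))


@pytest.fixture(scope="session")
def bi_box():
    return default_box("bi")


@pytest.fixture(scope="session")
def stretched_box():
    return default_box("stretched")


@pytest.fixture(scope="session")
def bi_samples_small(bi_box):
    return sample_params(bi_box, 20, seed=7)


@pytest.fixture(scope="session")
def stretched_samples_small(stretched_box):
    return sample_params(stretched_box, 20, seed=7)


def random_theta(model: str, n: int, seed: int) -> np.ndarray:
    """Uniform draws from the default box with amplitude free in [0.2, 2]."""
    box = default_box(model)
    rng = np.random.default_rng(seed)
    theta = rng.uniform(box.lower, box.upper, size=(n, box.n_params))
    theta[:, 0] = rng.uniform(0.2, 2.0, size=n)
    return theta
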
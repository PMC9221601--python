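import numpy as np
import pytest

from dvhlasso.dvh import DoseGrid, StructureMask
from dvhlasso.synthesis import CohortSpec, make_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-parameter synthetic cohort shared across read-only tests."""
    return make_cohort(CohortSpec(seed=11))


def random_phantom(seed: int, shape=(24, 20, 18), max_dose: float = 70.0):
    """A seeded random dose grid with a random nonempty mask."""
    rng = np.random.default_rng(seed)
    values = rng.uniform(0.0, max_dose, size=shape)
    mask = rng.random(shape) < 0.6
    if not mask.any():
        mask.flat[0] = True
    return DoseGrid(values), StructureMask(mask)
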
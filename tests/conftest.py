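import numpy as np
import pytest

from cephalomorph import (
    LANDMARK_NAMES,
    SEX_PROPORTION_MEANS,
    realize_proportions,
    validate_landmark_set,
)


def random_landmark_set(rng, scale=100.0, specimen_id="rand"):
    """A random valid (non-degenerate) 18-landmark configuration."""
    pts = rng.normal(scale=scale, size=(18, 3))
    return validate_landmark_set(
        {name: pts[i] for i, name in enumerate(LANDMARK_NAMES)},
        specimen_id=specimen_id,
    )


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230618)


@pytest.fixture
def male_scaffold():
    """Canonical noiseless realization of the male normative proportions."""
    return realize_proportions(SEX_PROPORTION_MEANS["male"], specimen_id="m0", sex="male")
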
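import numpy as np
import pytest

from aneugrowth.synthetic import generate_dome


@pytest.fixture(scope="session")
def hemisphere_dome():
    """Exact hemispherical dome, radius 2.5 mm (irregularity off)."""
    return generate_dome(height=2.5, neck_ratio=1.0, irregularity=0.0, lobulations=0, subdivisions=4, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rigid_motion(rng):
    """Random rotation matrix + translation vector."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = rng.normal(scale=5.0, size=3)
    return R, t
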
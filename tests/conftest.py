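import numpy as np
import pytest

from trajpca.io import Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def random_trajectory(rng):
    """12 frames of 5 unit-mass atoms deforming smoothly at full rank."""
    base = rng.uniform(-1.5, 1.5, size=(5, 3))
    drift = rng.normal(scale=0.08, size=(12, 5, 3))
    coords = base[None] + np.cumsum(drift, axis=0)
    return Trajectory(("X",) * 5, coords)


@pytest.fixture
def diatomic_xyz(tmp_path):
    p = tmp_path / "diatomic.xyz"
    p.write_text(
        "2\nframe 0\nH 0.0 0.0 0.0\nH 0.0 0.0 0.74\n"
        "2\nframe 1\nH 0.0 0.0 0.0\nH 0.0 0.0 0.80\n"
    )
    return p
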
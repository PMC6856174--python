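import numpy as np
import pytest

from rlbpseg.fusion import AtlasSet, FusionConfig
from rlbpseg.synthetic import PhantomSpec, make_atlas_set, make_phantom
from rlbpseg.volume_io import LabelMap, Volume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ramp_volume():
    """3x3x3 volume whose intensity equals its flat C-order index."""
    return Volume(np.arange(27, dtype=float).reshape(3, 3, 3))


@pytest.fixture(scope="session")
def small_spec():
    """A small phantom problem used across fusion/baseline tests."""
    return PhantomSpec(
        shape=(24, 24, 24),
        semi_axes=(7.0, 6.0, 5.5),
        n_atlases=4,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_problem(small_spec):
    target, truth = make_phantom(small_spec)
    atlases = make_atlas_set(small_spec)
    return target, truth, atlases


@pytest.fixture(scope="session")
def small_cfg(small_spec):
    # small feature dimension / patch radius keep the unit tests fast
    return FusionConfig(n_atlases=small_spec.n_atlases, L=50, r_p=2, seed=3)


def random_label_pair(rng, shape=(10, 10, 10)):
    """Two overlapping random blob label maps, both nonempty with nonempty
    boundaries (smooth noise thresholded at different levels)."""
    from scipy import ndimage

    field = ndimage.gaussian_filter(rng.normal(size=shape), 1.5)
    a = field > np.quantile(field, 0.7)
    b = ndimage.gaussian_filter(field + 0.3 * rng.normal(size=shape), 1.0)
    b = b > np.quantile(b, 0.72)
    if not a.any() or not b.any():  # pragma: no cover - quantile guarantees content
        raise AssertionError("degenerate random label pair")
    return a.astype(np.uint8), b.astype(np.uint8)
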
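import numpy as np
import pytest

import taxvision as tv


@pytest.fixture(scope="session")
def superordinate_set():
    """100 textures (50 artificial, 50 natural) at the default study conditions."""
    return tv.gen_superordinate_set(tv.SyntheticConfig(n_per_class=50, seed=7))


@pytest.fixture(scope="session")
def basic_set():
    """100 binary silhouettes (50 animal, 50 plant)."""
    return tv.gen_basic_silhouette_set(tv.SyntheticConfig(n_per_class=50, seed=11))


@pytest.fixture(scope="session")
def subordinate_set():
    """240 textured images: 12 fine classes, 6 under each basic class."""
    return tv.gen_subordinate_set(
        tv.SyntheticConfig(n_per_class=20, seed=5), classes_per_basic=6
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def blob_mask(rng):
    """An irregular but nonempty 48x48 test mask (a few overlapping disks)."""
    from skimage.draw import disk

    mask = np.zeros((48, 48), dtype=bool)
    for _ in range(4):
        c = rng.uniform(12, 36, 2)
        r = rng.uniform(4, 10)
        rr, cc = disk(c, r, shape=mask.shape)
        mask[rr, cc] = True
    return mask
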
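import numpy as np
import pytest

from afconn.atlas import ROIAtlas, default_atlas


def make_atlas(n_pairs: int) -> ROIAtlas:
    """Small programmatic atlas: left block then right block, pairs aligned."""
    names, hemis, pids, labels = [], [], [], []
    for side, hemi in (("L", "left"), ("R", "right")):
        for p in range(n_pairs):
            names.append(f"{side}-roi{p + 1}")
            hemis.append(hemi)
            pids.append(p + 1)
            labels.append((1000 if side == "L" else 2000) + p + 1)
    return ROIAtlas(
        names=tuple(names),
        hemispheres=tuple(hemis),
        pair_ids=tuple(pids),
        label_values=tuple(labels),
    )


@pytest.fixture(scope="session")
def dk_atlas():
    return default_atlas()


@pytest.fixture
def atlas2():
    return make_atlas(2)


@pytest.fixture
def atlas4():
    return make_atlas(4)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_symmetric_z(n, rng, scale=0.5):
    """Random symmetric Fisher-z matrix with masked diagonal."""
    a = rng.normal(0, scale, size=(n, n))
    z = (a + a.T) / 2
    np.fill_diagonal(z, 0.0)
    return z
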
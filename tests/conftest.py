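import numpy as np
import pytest

from epispread.network import BrainNetwork, RoiTable


def make_rois(n: int, rng_seed: int = 0, box: float = 100.0) -> RoiTable:
    rng = np.random.default_rng(rng_seed)
    return RoiTable(
        roi_ids=np.arange(1, n + 1),
        labels=tuple(f"R{i}" for i in range(1, n + 1)),
        hemispheres=tuple(["left"] * n),
        centroids=rng.uniform(0, box, (n, 3)),
    )


def make_net(w, rng_seed: int = 0, theta: float = 1.0) -> BrainNetwork:
    w = np.asarray(w, dtype=float)
    return BrainNetwork(weights=w, rois=make_rois(w.shape[0], rng_seed), theta=theta)


def chain_net(n: int, weight: float = 0.5) -> BrainNetwork:
    w = np.zeros((n, n))
    for i in range(n - 1):
        w[i, i + 1] = w[i + 1, i] = weight
    return make_net(w)


def random_symmetric(n: int, rng_seed: int = 0, density: float = 1.0) -> BrainNetwork:
    rng = np.random.default_rng(rng_seed)
    w = rng.uniform(0.01, 1.0, (n, n))
    if density < 1.0:
        mask = rng.random((n, n)) < density
        w = np.where(mask, w, 0.0)
    w = np.triu(w, k=1)
    w = w + w.T
    return make_net(w, rng_seed)


@pytest.fixture
def rois6():
    return make_rois(6)
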
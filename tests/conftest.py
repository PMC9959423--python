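import numpy as np
import pytest

import fluoroseg as fs
from fluoroseg.model_selection import CSConfig


# desk-scale study conditions: per-class pixel proportions 10:10:5:2.5:4.5,
# cuckoo search over [20, 120] clusters with 10 nests
DESK_N_PER_CLASS = (400, 400, 200, 100, 180)
DESK_CS = dict(n_nests=10, bounds=(20, 120), t_max=3, seed=1)


@pytest.fixture(scope="session")
def desk_pixels():
    X, y = fs.sample_labeled_pixels(DESK_N_PER_CLASS, seed=1)
    Xv, yv = fs.sample_labeled_pixels(DESK_N_PER_CLASS, seed=2)
    return X, y, Xv, yv


@pytest.fixture(scope="session")
def trained_model(desk_pixels):
    """Cuckoo-search-trained prototype set on desk-scale synthetic pixels."""
    X, y, Xv, yv = desk_pixels
    result = fs.run_cuckoo_search(X, y, CSConfig(**DESK_CS), val_data=(Xv, yv))
    assert result.prototypes is not None
    return result


@pytest.fixture(scope="session")
def fixture_suite():
    images, manifest = fs.make_fixture_suite(seed=3)
    return images, manifest


def well_separated_blobs(seed=0, n_per_class=200, n_classes=5, sigma=0.02):
    """Five tight Gaussian blobs at mutually distant corners of the unit cube."""
    rng = np.random.default_rng(seed)
    centers = np.array([
        [0.1, 0.1, 0.1, 0.1, 0.1, 0.1],
        [0.9, 0.9, 0.9, 0.9, 0.9, 0.9],
        [0.9, 0.1, 0.9, 0.1, 0.9, 0.1],
        [0.1, 0.9, 0.1, 0.9, 0.1, 0.9],
        [0.5, 0.5, 0.9, 0.1, 0.5, 0.9],
    ])[:n_classes]
    X = np.vstack([rng.normal(c, sigma, size=(n_per_class, 6)) for c in centers])
    y = np.repeat(np.arange(n_classes), n_per_class)
    return X, y, centers
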
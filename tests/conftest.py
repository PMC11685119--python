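import numpy as np
import pytest

from eegdann.dataset import FeatureDataset
from eegdann.layout_features import BandScheme, ElectrodeLayout, build_adjacency


@pytest.fixture(scope="session")
def layout():
    return ElectrodeLayout.default()


@pytest.fixture(scope="session")
def scheme():
    return BandScheme()


@pytest.fixture(scope="session")
def adjacency(layout):
    return build_adjacency(layout, "knn", 4)


def make_random_dataset(layout, adjacency, n_subjects=2, windows_per_subject=12,
                        n_classes=3, seed=0, class_shift=1.0):
    """A small in-memory feature dataset with a linear class signal, for
    model-level tests that do not need the raw-signal pipeline."""
    rng = np.random.default_rng(seed)
    de, labels, subjects = [], [], []
    for s in range(n_subjects):
        for w in range(windows_per_subject):
            k = w % n_classes
            base = rng.standard_normal((len(layout), 5))
            base[:10, k % 5] += class_shift  # class-dependent offset
            de.append(base)
            labels.append(k)
            subjects.append(f"S{s:02d}")
    return FeatureDataset(np.stack(de), np.array(labels), np.array(subjects),
                          layout, adjacency)


@pytest.fixture
def random_dataset(layout, adjacency):
    return make_random_dataset(layout, adjacency)
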
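import numpy as np
import pytest

from eegfuse.features import FeaturePair
from eegfuse.graph import ElectrodeLayout, build_graph, builtin_layout


@pytest.fixture(scope="session")
def graph32():
    return build_graph(builtin_layout("deap32"))


@pytest.fixture(scope="session")
def tiny_layout():
    """4-electrode square layout for fast model tests."""
    coords = np.array(
        [[1.0, 0, 0], [0, 1.0, 0], [-1.0, 0, 0], [0, -1.0, 0]]
    )
    return ElectrodeLayout(["A", "B", "C", "D"], coords)


@pytest.fixture(scope="session")
def tiny_graph(tiny_layout):
    return build_graph(tiny_layout, edge_fraction=0.5)


def make_separable_features(
    rng, n_windows=96, n_channels=4, n_bands=5, t_steps=8, class_sep=3.0
):
    """FeaturePair whose DE features are linearly separable by class and
    whose time input carries the class in its per-channel mean level."""
    labels = np.arange(n_windows) % 4
    rng.shuffle(labels)
    centers = rng.standard_normal((4, n_channels, n_bands)) * class_sep
    de = centers[labels] + 0.3 * rng.standard_normal((n_windows, n_channels, n_bands))
    tcenters = rng.standard_normal((4, n_channels, 1)) * class_sep
    time = tcenters[labels] + 0.3 * rng.standard_normal(
        (n_windows, n_channels, t_steps)
    )
    return FeaturePair(
        de=de, time=time, labels=labels, channel_names=["A", "B", "C", "D"]
    )
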
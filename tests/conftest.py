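import numpy as np
import pytest

from waveseg.segmentation import WaveParams
from waveseg.synthetic import mini_params, mini_reference, mini_scene

SQ2 = 1.0 / np.sqrt(2.0)
#: posteroventral reference direction in (row, col) components
R_LATERAL = np.array([SQ2, -SQ2])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def lateral_params():
    """Lateral-projection thresholds with the matching dorsal axis."""
    return WaveParams(dorsal_axis=-R_LATERAL)


def canonical_series(length=30, t_v=10, n_v=5, n_d=5, speed=2.0):
    """The hand-traceable two-phase series: n_v frames along the
    reference at ``speed``, then n_d frames exactly opposite."""
    series = np.zeros((length, 2))
    series[t_v : t_v + n_v] = speed * R_LATERAL
    series[t_v + n_v : t_v + n_v + n_d] = -speed * R_LATERAL
    return series


@pytest.fixture(scope="session")
def demo_scene():
    return mini_scene(seed=7)


@pytest.fixture(scope="session")
def demo_segmentation(demo_scene):
    from waveseg.segmentation import segment_field

    records, labels = segment_field(demo_scene.fields, mini_reference(), mini_params())
    return records, labels
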
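import numpy as np
import pytest

from temposig import SyntheticSpec, TemporalMatrix, generate_clustered_timecourses

TIME_POINTS = np.array([1.0, 3.0, 5.0, 7.0, 10.0, 14.0])


@pytest.fixture
def rng():
    return np.random.default_rng(20200603)


@pytest.fixture
def small_matrix(rng):
    """20 x 6 matrix with scattered missing cells, ids V01..V20."""
    values = rng.normal(size=(20, 6))
    mask = rng.random((20, 6)) < 0.15
    mask[:, 0] = False  # keep >= 1 observed everywhere trivially
    values[mask] = np.nan
    return TemporalMatrix(values, TIME_POINTS,
                          [f"V{i:02d}" for i in range(1, 21)],
                          {"log_base": "2"})


@pytest.fixture
def clustered_data():
    """Synthetic 5-cluster time courses with ground truth (no spikes)."""
    spec = SyntheticSpec(m=200, snr=4.0, missing_rate=0.0,
                         spike_noise_fraction=0.0, seed=11)
    return generate_clustered_timecourses(spec)
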
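import numpy as np
import pytest

from dynfc import synthetic
from dynfc.windows import RoiTimeSeries, WindowParams, sliding_window_fc


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down cohort for fast structural tests."""
    return synthetic.GeneratorConfig(
        n_per_group=4, n_regions=20, n_timepoints=60, seed=7
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return synthetic.generate_cohort_arrays(small_config)


def make_windows(x: np.ndarray, pid: str = "sub", wl: int = 10, step: int = 1):
    labels = [f"R{i + 1:03d}" for i in range(x.shape[1])]
    return sliding_window_fc(
        RoiTimeSeries(pid, x, labels), WindowParams(wl, step)
    )


@pytest.fixture(scope="session")
def random_windows(rng):
    """One participant's windowed FC from unstructured noise."""
    return make_windows(rng.standard_normal((60, 12)))
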
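import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import lamline as L

settings.register_profile(
    "ci",
    max_examples=50,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def paradigm():
    """The standard block paradigm: 1 s pre / 4 s stim / 15 s post, 32 epochs,
    sampled every 100 ms."""
    return L.StimParadigm(pre_s=1.0, stim_s=4.0, post_s=15.0, n_epochs=32, tr_ms=100.0)


@pytest.fixture
def depth_grid():
    """40 bins x 50 um spanning 0-2 mm of cortex, bin centres."""
    return (np.arange(40) + 0.5) * 0.05


@pytest.fixture
def l4_spec(depth_grid):
    """Ground truth: 10 % response peaked at 0.9 mm (layer 4), no noise."""
    amp = L.make_amplitude_profile(
        "l4_peak", 10.0, depth_grid, peak_depth_mm=0.9, width_mm=0.4
    )
    return L.LaminarResponseSpec(
        amplitude_profile=amp.values, baseline_profile=100.0, seed=11
    )
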
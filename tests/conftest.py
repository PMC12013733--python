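import numpy as np
import pytest

from vo2fit import BreathSeries, SimSpec, simulate_series
from vo2fit.models import BiParams, eval_bi
from vo2fit.simulate import REPRESENTATIVE_TRUTH


@pytest.fixture(scope="session")
def truth() -> BiParams:
    return REPRESENTATIVE_TRUTH


@pytest.fixture(scope="session")
def noisy_series(truth):
    """Representative noisy 15-min recovery (irregular breaths, SD 120)."""
    series, _ = simulate_series(SimSpec(truth=truth, seed=11))
    return series


@pytest.fixture(scope="session")
def grid_series(truth):
    """Noiseless truth curve on a uniform 1-s grid over [0, 900] s."""
    t = np.arange(0.0, 901.0)
    return BreathSeries(t=t, vo2=eval_bi(truth, t), unit_mode="absolute",
                        meta={"synthetic": True, "noise_sd": 0.0})
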
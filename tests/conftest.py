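import numpy as np
import pytest

from awia import BeatSpec, WiaConfig, simulate_beat
from awia.simulate import default_forward_shape


@pytest.fixture
def forward_beat():
    """Noiseless forward-only beat factory with physiological velocity
    amplitude (peak U ~ 1 m/s). Returns (signal, truth)."""

    def make(c_true=4.0, period=0.78, amplitude=1.0, dt_out=0.030, **kw):
        spec = BeatSpec(
            c_true=c_true,
            period=period,
            dt_out=dt_out,
            forward_wavelets=default_forward_shape(period, amplitude),
            **kw,
        )
        return simulate_beat(spec)

    return make


@pytest.fixture
def no_smooth_config():
    return WiaConfig(smooth_window=1)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
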
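import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from tubeheart import synthgen as sg


@pytest.fixture
def wt_spec():
    return sg.preset_spec("wt_young", seed=1, noise_sd=0.0)


@pytest.fixture
def wt_noisy_spec():
    return sg.preset_spec("wt_young", seed=1)


@pytest.fixture
def wt_recording(wt_spec):
    gt = sg.make_beat_schedule(wt_spec)
    trace = sg.render_diameter_trace(gt, wt_spec)
    return gt, trace


@pytest.fixture
def zero_variance_spec():
    return sg.preset_spec(
        "wt_young", seed=0, duration_s=8.5,
        di_dist=(0.6, 0.0), si_dist=(0.25, 0.0), noise_sd=0.0,
    )


def make_linear_ap(rest=-40.0, peak=10.0, repol_s=0.100, rate=2000.0,
                   pre_s=1.0, post_s=1.0):
    """Instantaneous upstroke at t=pre_s, linear return to rest over repol_s."""
    from tubeheart.core import VoltageTrace

    n = int(round((pre_s + repol_s + post_s) * rate))
    t = np.arange(n) / rate
    v = np.full(n, rest)
    in_decay = (t >= pre_s) & (t < pre_s + repol_s)
    v[in_decay] = peak + (rest - peak) * (t[in_decay] - pre_s) / repol_s
    return VoltageTrace(t=t, v=v, rate=rate)
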
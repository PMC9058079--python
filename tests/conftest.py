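import numpy as np
import pytest

from tiltwalk import events as ev
from tiltwalk import synthgait as sg

FS = 100.0

NOISE_FREE = {"gyro": 0.0, "accel": 0.0, "pressure": 0.0}


def noise_free_config(seed=0, **kw):
    kw.setdefault("walk_duration_s", 60.0)
    kw.setdefault("n_segments", 3)
    return sg.SimConfig(seed=seed, noise_sd=dict(NOISE_FREE), **kw)


@pytest.fixture(scope="session")
def trial_led_nf():
    """Noise-free LED trial shared across detection tests."""
    return sg.simulate_trial(noise_free_config(seed=11), "LED")


@pytest.fixture(scope="session")
def trial_led_noisy():
    return sg.simulate_trial(
        sg.SimConfig(seed=12, walk_duration_s=60.0, n_segments=3), "LED"
    )


def foot_events(trace, foot):
    sm = ev.lowpass(trace.channels["gyro_sag"], FS)
    return ev.extract_gait_events(sm, FS, foot)


@pytest.fixture(scope="session")
def fixture_study(tmp_path_factory):
    """Default bundled synthetic study (4 subjects x 4 conditions x 2 reps)."""
    from tiltwalk.pipeline_io import make_fixture

    out = tmp_path_factory.mktemp("fixture_study")
    return make_fixture(out, seed=7)
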
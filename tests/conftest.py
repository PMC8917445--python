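import numpy as np
import pytest

import fastkin as fk


@pytest.fixture(scope="session")
def small_trial_set():
    """270 startle trials at the study's responder fraction (~1/3)."""
    return fk.simulate_fast_start_trials(
        fk.FastStartSimParams(n_fish=90, trials_per_fish=3, seed=11)
    )


@pytest.fixture(scope="session")
def disjoint_trial_set():
    """Trials whose responder/non-responder peak speeds cannot overlap."""
    params = fk.FastStartSimParams(
        n_fish=60,
        trials_per_fish=1,
        responder_fraction=0.4,
        responder_peak_speed=fk.NormalSpec(200.0, 12.0),
        nonresponder_peak_speed=fk.NormalSpec(15.0, 3.0),
        seed=21,
    )
    return fk.simulate_fast_start_trials(params)


@pytest.fixture(scope="session")
def feeding_session():
    return fk.simulate_feeding_session(fk.FeedingSimParams(seed=5))


@pytest.fixture(scope="session")
def layout_3x3():
    return fk.make_layout("3x3", px_per_mm=4.0)


@pytest.fixture()
def circle_track():
    """Uniform circular motion R=10 mm, omega=2 rad/s at 353 Hz."""
    dt = 1.0 / 353.0
    t = np.arange(0.0, 1.0, dt)
    n = len(t)
    return fk.Track(
        fish_id="circle",
        dish_id="d",
        frames=np.arange(n),
        time_s=t,
        x_mm=10.0 * np.cos(2.0 * t),
        y_mm=10.0 * np.sin(2.0 * t),
        valid=np.ones(n, dtype=bool),
    )
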
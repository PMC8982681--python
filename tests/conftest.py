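import numpy as np
import pytest

import gaitsense as gs


def quiet(config: gs.RunConfig) -> gs.RunConfig:
    """Copy of a run config with every sensor noise source switched off."""
    return config.model_copy(
        update={
            "cw": config.cw.model_copy(update={"noise_sd": 0.0}),
            "uwb": config.uwb.model_copy(
                update={"noise_sd": 0.0, "clutter_amplitude": 0.0}
            ),
            "thermal": config.thermal.model_copy(update={"noise_sd": 0.0}),
            "mocap": config.mocap.model_copy(update={"positional_noise_sd": 0.0}),
            "gaitrite": config.gaitrite.model_copy(update={"spatial_sd": 0.0}),
        }
    )


def constant_velocity_trajectory(
    speed: float,
    start_pos: float,
    duration: float,
    sample_rate: float = 1000.0,
) -> gs.Trajectory:
    """Single-walk trajectory at constant signed speed (no ramps, no dwells)."""
    n = int(round(duration * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    return gs.Trajectory(
        sample_rate=sample_rate,
        times=t,
        position=start_pos + speed * t,
        velocity=np.full(n, speed),
        walk_index=np.zeros(n, dtype=int),
    )


@pytest.fixture(scope="session")
def default_config() -> gs.RunConfig:
    return gs.load_config(None)


@pytest.fixture(scope="session")
def quiet_config(default_config) -> gs.RunConfig:
    return quiet(default_config)


@pytest.fixture(scope="session")
def normal_profile() -> gs.SpeedProfile:
    return gs.build_speed_profile("normal", 1.0, 0.5)


@pytest.fixture(scope="session")
def slow_profile() -> gs.SpeedProfile:
    return gs.build_speed_profile("slow", 0.6, 0.5)


@pytest.fixture(scope="session")
def normal_trial_quiet(quiet_config, normal_profile):
    return gs.simulate_trial(quiet_config, normal_profile, 0, 11)


@pytest.fixture(scope="session")
def slow_trial_quiet(quiet_config, slow_profile):
    return gs.simulate_trial(quiet_config, slow_profile, 0, 12)


@pytest.fixture(scope="session")
def normal_trial_noisy(default_config, normal_profile):
    return gs.simulate_trial(default_config, normal_profile, 0, 13)
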
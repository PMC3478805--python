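import numpy as np
import pytest

import navdrop as nd


@pytest.fixture(scope="session")
def default_sensor():
    return nd.SensorModel()


@pytest.fixture(scope="session")
def bench_model(default_sensor):
    """Calibration fitted to a noiseless bench sweep of the default sensor."""
    return nd.fit_calibration(nd.simulate_calibration_sweep(default_sensor))


@pytest.fixture(scope="session")
def noiseless_trial():
    """60-step noiseless walking trial, deterministic."""
    return nd.generate_trial(nd.GaitProfile(n_steps=60, seed=42))


@pytest.fixture(scope="session")
def noisy_trial():
    """60-step trial with one capacitance quantum of sensor noise and
    half a pixel of marker noise (0.1 mm at the default 0.2 mm/px scale)."""
    return nd.generate_trial(
        nd.GaitProfile(n_steps=60, seed=7, noise_cap_pf=0.13,
                       noise_nh_mm=0.5 * nd.gait_sim.MM_PER_PX)
    )


@pytest.fixture(scope="session")
def noiseless_report(noiseless_trial, bench_model):
    return nd.analyze_validate(
        noiseless_trial.strain, noiseless_trial.markers, bench_model
    )


def truth_merge(report, trial):
    """Per-step estimates joined to the simulator's truth record."""
    return report.per_step.merge(trial.truth, on="step")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
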
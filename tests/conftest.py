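import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_montage():
    return ["C3", "C1", "Cz", "C2", "C4", "FCz", "HEO", "VEO"]


@pytest.fixture(scope="session")
def noise_epochs(small_montage):
    """Stationary white-noise epochs, condition 1, all four classes."""
    from sclmi.paradigm import condition_timing
    from sclmi.preprocessing import EpochArray

    timing = condition_timing(1)
    rng = np.random.default_rng(7)
    fs = 200.0
    lo, hi = timing.epoch_window_s
    n = int((hi - lo) * fs)
    labels = list(np.repeat(["RRR", "RLR", "LFL", "FRL"], 3))
    data = rng.standard_normal((len(labels), len(small_montage), n))
    times = lo + np.arange(n) / fs
    return EpochArray(data, times, labels, fs, list(small_montage), timing)


@pytest.fixture(scope="session")
def tiny_run():
    """One small simulated recording shared across tests (condition 1)."""
    from sclmi.generator import GeneratorParams, simulate_recording
    from sclmi.paradigm import make_schedule

    schedule = make_schedule(1, 2, 3)
    params = GeneratorParams(fs_raw=200.0, seed=3)
    recording, truth = simulate_recording(schedule, params)
    return schedule, params, recording, truth
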
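import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from axocouple.mea_io import ElectrodeMap, Recording, SpikeTrain


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_map():
    return ElectrodeMap.grid(3, 3)


def make_train(electrode, times, amplitudes=None):
    times = np.asarray(times, dtype=float)
    if amplitudes is None:
        amplitudes = np.full(times.size, -40.0)
    return SpikeTrain(electrode, times, np.asarray(amplitudes, dtype=float))


def make_recording(trains, emap=None, duration=None):
    trains = {t.electrode: t for t in trains}
    if emap is None:
        emap = ElectrodeMap.grid(3, 3)
    if duration is None:
        duration = max(
            (t.times[-1] for t in trains.values() if t.n_spikes), default=0.0
        )
    return Recording(trains, emap, duration=duration)


@pytest.fixture
def train_factory():
    return make_train


@pytest.fixture
def recording_factory():
    return make_recording


def brute_force_ccg_counts(ref_times, target_times, window_ms):
    """O(n·m) oracle: count all (ref, target) pairs with Δt in the window."""
    lo, hi = window_ms
    n = 0
    deltas = []
    for r in ref_times:
        for t in target_times:
            d = (t - r) * 1e3
            if lo <= d <= hi:
                n += 1
                deltas.append(d)
    return n, sorted(deltas)
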
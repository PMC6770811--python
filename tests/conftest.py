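import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from spikephys import BurstCriteria, SpikeTrain

settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def bursty_random_train(rng) -> SpikeTrain:
    """Random train whose ISI mixture straddles the burst-criterion
    boundaries (short intra-burst-like, ~100 ms, and long intervals)."""
    n = int(rng.integers(5, 120))
    kind = rng.integers(0, 3, n)
    isis = np.where(
        kind == 0, rng.exponential(0.15, n),
        np.where(kind == 1, rng.uniform(0.0005, 0.015, n),
                 rng.uniform(0.07, 0.13, n)))
    ts = np.cumsum(isis)
    return SpikeTrain(ts, 0.0, float(ts[-1]) + 0.01)


def oracle_bursts(timestamps, t_start, criteria: BurstCriteria):
    """Independent brute-force burst scanner.

    Formulated via maximal runs of consecutive short ISIs rather than the
    production scan: a maximal run of ISIs <= max_intra_isi_s is a burst
    iff the interval preceding its first spike (from the previous spike,
    or from t_start) is >= min_silent_s.  Returns (onset, n_spikes,
    silent_period) tuples.
    """
    ts = list(map(float, timestamps))
    n = len(ts)
    out = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and ts[j + 1] - ts[j] <= criteria.max_intra_isi_s:
            j += 1
        if j > i:
            gap = ts[i] - (ts[i - 1] if i > 0 else t_start)
            if gap >= criteria.min_silent_s:
                out.append((ts[i], j - i + 1, gap))
        i = j + 1
    return out


def poisson_train(rate_hz, duration_s, rng, t_start=0.0) -> SpikeTrain:
    """Homogeneous Poisson train on [t_start, t_start + duration_s]."""
    n = int(rng.poisson(rate_hz * duration_s))
    ts = np.sort(rng.uniform(t_start, t_start + duration_s, n))
    ts = ts[np.concatenate(([True], np.diff(ts) > 0))]
    return SpikeTrain(ts, t_start, t_start + duration_s)
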
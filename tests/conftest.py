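import numpy as np
import pytest

from pedimpact.signals import TimeSeriesChannel


@pytest.fixture
def rng():
    return np.random.default_rng(20240125)


@pytest.fixture
def channel_factory():
    def make(values, dt=0.1, units="g", **kwargs):
        values = np.asarray(values, dtype=float)
        times = np.arange(len(values)) * dt
        return TimeSeriesChannel(times, values, units, **kwargs)
    return make


def hic_brute_force(accel):
    """O(n^2) exhaustive HIC window search; the independent oracle.

    Uses the same trapezoid running integral and second-based duration factor
    as the production code but enumerates every sample pair directly.
    """
    t, a = accel.times, accel.values
    dt = t[1] - t[0]
    cum = np.concatenate([[0.0], np.cumsum((a[1:] + a[:-1]) * 0.5 * dt)])
    best, best_t1, best_t2 = 0.0, t[0], t[0]
    n = len(a)
    for i in range(n - 1):
        spans = t[i + 1:] - t[i]
        stop = int(np.searchsorted(spans, 15.0 + 1e-9, side="right"))
        if stop == 0:
            continue
        spans = spans[:stop]
        means = (cum[i + 1:i + 1 + stop] - cum[i]) / spans
        vals = (spans / 1000.0) * means**2.5
        j = int(np.argmax(vals))
        val = float(vals[j])
        if val > best or (val == best and t[i] < best_t1):
            best, best_t1, best_t2 = val, float(t[i]), float(t[i + 1 + j])
    return best, best_t1, best_t2
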
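import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def match_events(true_times, detected_times, tol_s=0.005):
    """Greedy one-to-one matching; returns (n_matched, recall, precision)."""
    true_times = np.asarray(true_times)
    detected_times = np.asarray(detected_times)
    used = np.zeros(detected_times.size, dtype=bool)
    matched = 0
    for t in true_times:
        if detected_times.size == 0:
            break
        d = np.abs(detected_times - t)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= tol_s:
            used[j] = True
            matched += 1
    recall = matched / true_times.size if true_times.size else 1.0
    precision = matched / detected_times.size if detected_times.size else 1.0
    return matched, recall, precision
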
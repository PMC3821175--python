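"""Shared helpers for the test suite."""

import numpy as np
import pytest


def match_events(truth_times_ms, detected_times_ms, tol_ms=2.0):
    """Greedy one-to-one matching of detected to ground-truth event times.

    Returns the number of true positives; each detected event can match at
    most one ground-truth event within ``tol_ms``.
    """
    truth = np.asarray(truth_times_ms, dtype=float)
    det = np.asarray(detected_times_ms, dtype=float)
    used = np.zeros(det.size, dtype=bool)
    tp = 0
    for t in truth:
        if det.size == 0:
            break
        d = np.abs(det - t)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= tol_ms:
            used[j] = True
            tp += 1
    return tp


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
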
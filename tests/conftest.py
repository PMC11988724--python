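import numpy as np
import pytest

from promotif import (SimulationConfig, build_log_odds, gen_pwm,
                      load_paper_fixtures)


@pytest.fixture(scope="session")
def paper_fixture():
    return load_paper_fixtures()


@pytest.fixture(scope="session")
def sharp_pwm():
    """Degenerate motif: one allowed base per column, unique consensus."""
    return build_log_odds(gen_pwm(6, seed=1, sharpness=1.0))


@pytest.fixture()
def blob_config():
    """Four well-separated 6-d clusters (default centers sit >= 17x the
    unit spread apart, separated in every variable)."""
    return SimulationConfig(seed=7)


def brute_force_sw(a: str, b: str, match=2.0, mismatch=-1.0, gap=-2.0) -> float:
    """Reference Smith-Waterman score by direct dynamic programming."""
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i, j] = max(0.0, H[i - 1, j - 1] + s, H[i - 1, j] + gap,
                          H[i, j - 1] + gap)
            best = max(best, H[i, j])
    return best
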
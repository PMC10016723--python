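import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from finseq import load_published_sl50_table

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def trout_profiles():
    """The packaged published SL50 table: (fin, event) -> SL50Profile."""
    return load_published_sl50_table()


def profile_loglik(sizes, states, mu, log_b):
    """Logistic log-likelihood at location mu and log-slope log_b,
    written independently of the fitting code."""
    b = np.exp(log_b)
    z = b * (np.asarray(sizes) - mu)
    # log sigma(z) = -log(1+exp(-z)) computed stably
    lp = -np.logaddexp(0.0, -z)
    lq = -np.logaddexp(0.0, z)
    s = np.asarray(states)
    return float(np.sum(s * lp + (1 - s) * lq))


def grid_search_sl50(sizes, states, step=1e-3):
    """Independent brute-force MLE of SL50: profile the likelihood over a
    location grid (inner 1-D search over the slope), coarse-to-fine down
    to ``step`` mm."""
    from scipy.optimize import minimize_scalar

    def prof(mu):
        r = minimize_scalar(lambda lb: -profile_loglik(sizes, states, mu, lb),
                            bounds=(-6.0, 6.0), method="bounded",
                            options={"xatol": 1e-10})
        return -r.fun

    lo, hi = float(np.min(sizes)), float(np.max(sizes))
    best = None
    for width in (0.2, 0.01, step):
        grid = np.arange(lo, hi + width / 2, width)
        vals = [prof(m) for m in grid]
        best = grid[int(np.argmax(vals))]
        lo, hi = best - 1.5 * width, best + 1.5 * width
    return float(best)
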
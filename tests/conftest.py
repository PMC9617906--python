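import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def true_constants():
    from activegel.synthetic import TRUE_CONSTANTS

    return TRUE_CONSTANTS


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)


def brute_force_mode(p, branch, refine: int = 2001):
    """Independent grid-argmax oracle for the most unstable mode.

    Coarse logarithmic sweep over nine decades of wavenumber followed by a
    fine linear refinement around the coarse maximum; never uses the
    closed-form q* / sigma* expressions.
    """
    from activegel.mechanics import (
        growth_rate_in_plane,
        growth_rate_out_of_plane,
    )

    rate = growth_rate_in_plane if branch == "in_plane" \
        else growth_rate_out_of_plane
    coarse = np.geomspace(1e-6, 1e3, 20_000)
    sigma = rate(p, coarse)
    k = int(np.argmax(sigma))
    if sigma[k] <= 0:
        return None
    lo = coarse[max(k - 2, 0)]
    hi = coarse[min(k + 2, coarse.size - 1)]
    fine = np.linspace(lo, hi, refine)
    sig_fine = rate(p, fine)
    j = int(np.argmax(sig_fine))
    return float(fine[j]), float(sig_fine[j])
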
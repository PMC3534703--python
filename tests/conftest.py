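import numpy as np
import pytest
from scipy import special

from aafburden import ExposureProfile, StratumKey, default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


def make_profile(sex="men", p_abstainer=0.2, p_former=0.2, mean_gpd=20.0,
                 race="White", age_band="35-44", cap=150.0,
                 binge_prevalence=0.3, binge_occasions=20.0, k=None):
    """Convenience constructor for a single-stratum exposure profile."""
    p_current = 1.0 - p_abstainer - p_former
    if abs(p_current) < 1e-9:  # guard float dust when abstainer+former fills the cell
        p_current = 0.0
        p_abstainer = 1.0 - p_former
    return ExposureProfile.from_moments(
        StratumKey(race, age_band, sex), p_abstainer, p_former, p_current,
        mean_gpd, k=k, cap=cap, binge_prevalence=binge_prevalence,
        binge_occasions=binge_occasions)


def sample_truncated_gamma(rng, shape, scale, cap, n):
    """Exact draws from a gamma truncated (and renormalized) on (0, cap]."""
    g_cap = special.gammainc(shape, cap / scale)
    u = rng.random(n) * g_cap
    return special.gammaincinv(shape, u) * scale


def mc_chronic_numerator(rng, profile, rr, rr_former, n=1_000_000):
    """Monte-Carlo evaluation of the chronic AAF numerator.

    ``rr`` is a vectorized dose-response function; the same formula as the
    quadrature path, evaluated by simulation.
    """
    x = sample_truncated_gamma(rng, profile.gamma_shape, profile.gamma_scale,
                               profile.cap, n)
    return (profile.p_former * (rr_former - 1.0)
            + profile.p_current * float(np.mean(rr(x) - 1.0)))
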
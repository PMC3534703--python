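import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aafburden import (
    ConfigurationError,
    EstimationError,
    StratumKey,
    apply_coverage_correction,
    category_prevalence,
    compute_coverage,
    estimate_prevalences,
    fit_consumption_density,
    survey_per_capita,
)
from aafburden.exposure import profiles_from_frame, profiles_to_frame

from conftest import make_profile, sample_truncated_gamma

KEY = StratumKey("White", "35-44", "men")


def microdata(statuses, weights=None, grams=None):
    n = len(statuses)
    return pd.DataFrame({
        "race": KEY.race, "age_band": KEY.age_band, "sex": KEY.sex,
        "status": statuses,
        "grams_per_day": grams if grams is not None else [0.0] * n,
        "binge_occasions": [0.0] * n,
        "weight": weights if weights is not None else [1.0] * n,
    })


class TestPrevalences:
    def test_all_current(self):
        md = microdata(["current"] * 5, grams=[10.0] * 5)
        assert estimate_prevalences(md, KEY) == (0.0, 0.0, 1.0)

    def test_unweighted_counting(self):
        md = microdata(["lifetime_abstainer", "lifetime_abstainer", "former", "current"])
        assert estimate_prevalences(md, KEY) == (0.5, 0.25, 0.25)

    def test_weighted_proportions(self):
        md = microdata(["lifetime_abstainer", "lifetime_abstainer", "former", "current"],
                       weights=[1, 1, 1, 3])
        p = estimate_prevalences(md, KEY)
        assert p == pytest.approx((2 / 6, 1 / 6, 3 / 6))

    def test_empty_stratum_names_it(self):
        md = microdata(["current"])
        with pytest.raises(EstimationError, match="Black"):
            estimate_prevalences(md, StratumKey("Black", "35-44", "men"))


class TestGammaFit:
    def test_men_default_moment_algebra(self):
        shape, scale, sd = fit_consumption_density(20.0, "men")
        assert sd == pytest.approx(23.42)
        assert shape == pytest.approx(1 / 1.171**2)
        assert scale == pytest.approx(20 * 1.171**2)
        assert shape * scale == pytest.approx(20.0, abs=1e-9)

    def test_k_one_is_exponential(self):
        shape, scale, _ = fit_consumption_density(10.0, k=1.0)
        assert shape == pytest.approx(1.0)
        assert scale == pytest.approx(10.0)

    def test_density_moments_numerically(self):
        # untruncated gamma with these parameters must have mean 20, SD 23.42
        rng = np.random.default_rng(0)
        shape, scale, sd = fit_consumption_density(20.0, "men")
        x = rng.gamma(shape, scale, 2_000_000)
        assert np.mean(x) == pytest.approx(20.0, rel=0.005)
        assert np.std(x) == pytest.approx(sd, rel=0.005)

    @given(mean=st.floats(0.5, 120.0), k=st.floats(0.5, 2.0))
    @settings(max_examples=50, derandomize=True)
    def test_moment_identity(self, mean, k):
        shape, scale, sd = fit_consumption_density(mean, k=k)
        assert shape * scale == pytest.approx(mean, abs=1e-9)
        assert np.sqrt(shape) * scale == pytest.approx(sd, rel=1e-9)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ConfigurationError):
            fit_consumption_density(0.0, "men")


def one_stratum_population(n=1000.0):
    return pd.DataFrame([{"race": KEY.race, "age_band": KEY.age_band,
                          "sex": KEY.sex, "population": n}])


class TestPerCapita:
    def test_unit_round_trip(self):
        prof = make_profile(p_abstainer=0.0, p_former=0.0,
                            mean_gpd=789.24 / 365, binge_prevalence=0.0)
        assert survey_per_capita([prof], one_stratum_population()) == pytest.approx(1.0)

    def test_coverage_53_percent(self):
        # survey-implied 4.6375 L against the 8.75 L reference
        mean = 4.6375 * 789.24 / 365 / 0.6  # P_current = 0.6
        prof = make_profile(p_abstainer=0.25, p_former=0.15, mean_gpd=mean)
        adj = compute_coverage([prof], one_stratum_population(), 8.75, target=None)
        assert adj.coverage == pytest.approx(0.53, abs=1e-9)

    def test_coverage_inversion_2005(self):
        # coverage 49.7% of 9.5 L implies 4.7215 L survey per-capita
        mean = 0.497 * 9.5 * 789.24 / 365 / 0.6
        prof = make_profile(p_abstainer=0.25, p_former=0.15, mean_gpd=mean)
        adj = compute_coverage([prof], one_stratum_population(), 9.5, target=None)
        assert adj.survey_per_capita_l == pytest.approx(4.7215, abs=1e-4)

    def test_missing_population_row(self):
        prof = make_profile()
        pop = one_stratum_population().assign(race="Black")
        with pytest.raises(EstimationError):
            survey_per_capita([prof], pop)


class TestCoverageCorrection:
    def test_fixed_point(self):
        prof = make_profile(mean_gpd=30.0)
        pop = one_stratum_population()
        reference = survey_per_capita([prof], pop) / 0.8
        shifted, adj = apply_coverage_correction([prof], pop, reference, 0.8)
        assert adj.upshift_factor == pytest.approx(1.0)
        assert shifted[0] == prof

    def test_factor_from_low_coverage(self):
        mean = 0.497 * 9.5 * 789.24 / 365 / 0.6
        prof = make_profile(p_abstainer=0.25, p_former=0.15, mean_gpd=mean)
        _, adj = apply_coverage_correction([prof], one_stratum_population(), 9.5, 0.8)
        assert adj.upshift_factor == pytest.approx(0.8 / 0.497, rel=1e-9)

    def test_conservation_and_prevalence_invariance(self):
        profs = [make_profile(mean_gpd=18.0),
                 make_profile(sex="women", mean_gpd=9.0, p_abstainer=0.3)]
        pop = pd.DataFrame([
            {"race": "White", "age_band": "35-44", "sex": "men", "population": 900.0},
            {"race": "White", "age_band": "35-44", "sex": "women", "population": 1100.0},
        ])
        shifted, adj = apply_coverage_correction(profs, pop, 9.5, 0.8)
        assert survey_per_capita(shifted, pop) == pytest.approx(0.8 * 9.5, rel=1e-6)
        for before, after in zip(profs, shifted):
            assert after.p_current == before.p_current
            assert after.p_former == before.p_former
            assert after.binge_prevalence == before.binge_prevalence
            # gamma refitted around the shifted mean
            assert after.gamma_shape * after.gamma_scale == pytest.approx(
                after.mean_gpd, abs=1e-9)

    def test_disabled_correction_is_identity(self):
        prof = make_profile(mean_gpd=25.0)
        shifted, adj = apply_coverage_correction([prof], one_stratum_population(),
                                                 9.5, target=None)
        assert adj.upshift_factor == 1.0
        assert shifted[0] == prof

    def test_bad_target_rejected(self):
        with pytest.raises(ConfigurationError):
            apply_coverage_correction([make_profile()], one_stratum_population(),
                                      9.5, target=2.0)


class TestCategoryPrevalence:
    def test_no_drinkers(self):
        prof = make_profile(p_abstainer=0.6, p_former=0.4, mean_gpd=0.0)
        assert np.all(category_prevalence(prof, (0.0,)) == 0.0)

    def test_total_mass(self):
        prof = make_profile(p_abstainer=0.3, p_former=0.1)
        assert category_prevalence(prof, (0.0,)).sum() == pytest.approx(0.6)

    def test_against_sampling_oracle(self):
        rng = np.random.default_rng(7)
        prof = make_profile(p_abstainer=0.0, p_former=0.0, mean_gpd=20.0)
        got = category_prevalence(prof, (0.0, 40.0, 60.0, 100.0))
        x = sample_truncated_gamma(rng, prof.gamma_shape, prof.gamma_scale,
                                   prof.cap, 1_000_000)
        edges = [0.0, 40.0, 60.0, 100.0, np.inf]
        mc = np.histogram(x, edges)[0] / x.size
        assert np.max(np.abs(got - mc)) < 0.002

    def test_masses_sum_to_p_current(self):
        prof = make_profile(p_abstainer=0.25, p_former=0.15, mean_gpd=35.0)
        cats = category_prevalence(prof, (0.0, 20.0, 40.0, 60.0))
        assert np.all(cats >= 0)
        assert cats.sum() == pytest.approx(prof.p_current, abs=1e-6)

    def test_non_monotone_bounds_rejected(self):
        prof = make_profile()
        with pytest.raises(ConfigurationError):
            category_prevalence(prof, (0.0, 60.0, 40.0))
        with pytest.raises(ConfigurationError):
            category_prevalence(prof, (10.0, 40.0))


def test_profile_frame_round_trip():
    profs = [make_profile(), make_profile(sex="women", mean_gpd=10.0)]
    assert profiles_from_frame(profiles_to_frame(profs)) == profs


def test_profile_simplex_validated():
    with pytest.raises(ConfigurationError):
        make_profile(p_abstainer=0.8, p_former=0.4)
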
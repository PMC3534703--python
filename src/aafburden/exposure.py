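"""Per-stratum alcohol exposure: drinking-status prevalences, a gamma model
of average daily consumption among current drinkers, and the per-capita
triangulation that corrects survey undercoverage.

The exposure model follows the standard triangulation approach: drinker
consumption x (grams of pure ethanol per day) is gamma distributed with mean
mu and standard deviation sigma = k * mu, where k is a sex-specific constant
(defaults 1.171 for men, 1.258 for women).  The gamma is truncated and
renormalized on (0, C] with C the consumption cap (default 150 g/day).
Survey means are multiplied by a single upshift factor so that the
survey-implied adult per-capita consumption reaches a target fraction
(default 80%) of the recorded+unrecorded per-capita reference.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .strata import (
    DAYS_PER_YEAR,
    DEFAULT_CAP,
    DEFAULT_TARGET_COVERAGE,
    ETHANOL_G_PER_L,
    ConfigurationError,
    EstimationError,
    StratumKey,
    k_for_sex,
)

STATUS_LIFETIME_ABSTAINER = "lifetime_abstainer"
STATUS_FORMER = "former"
STATUS_CURRENT = "current"
STATUSES = (STATUS_LIFETIME_ABSTAINER, STATUS_FORMER, STATUS_CURRENT)

STRATUM_COLS = ["race", "age_band", "sex"]


def fit_consumption_density(mean: float, sex: str | None = None,
                            k: float | None = None) -> tuple[float, float, float]:
    """Gamma parameters for drinker consumption with mean ``mean`` g/day.

    The SD is tied to the mean through sigma = k * mean, so the gamma shape
    is 1/k**2 and the scale is mean * k**2.  Returns (shape, scale, sd).
    """
    if mean <= 0:
        raise ConfigurationError(f"drinker mean must be positive, got {mean}")
    if k is None:
        if sex is None:
            raise ConfigurationError("either sex or k must be given")
        k = k_for_sex(sex)
    if k <= 0:
        raise ConfigurationError(f"mean-SD constant k must be positive, got {k}")
    sd = k * mean
    shape = 1.0 / (k * k)
    scale = mean * k * k
    return shape, scale, sd


@dataclass(frozen=True)
class ExposureProfile:
    """Exposure of one stratum: status prevalences + consumption density.

    ``binge_prevalence`` is the fraction of current drinkers reporting any
    binge occasions (5+ drinks); ``binge_occasions`` is the mean occasions
    per year among those drinkers.
    """

    stratum: StratumKey
    p_abstainer: float
    p_former: float
    p_current: float
    mean_gpd: float
    sd_gpd: float
    gamma_shape: float
    gamma_scale: float
    cap: float = DEFAULT_CAP
    binge_prevalence: float = 0.0
    binge_occasions: float = 0.0

    def __post_init__(self) -> None:
        total = self.p_abstainer + self.p_former + self.p_current
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"{self.stratum}: status prevalences sum to {total}, not 1")
        if min(self.p_abstainer, self.p_former, self.p_current) < 0:
            raise ConfigurationError(f"{self.stratum}: negative prevalence")
        if self.p_current > 0:
            if self.mean_gpd <= 0 or self.sd_gpd <= 0:
                raise ConfigurationError(
                    f"{self.stratum}: drinkers present but mean/SD not positive")
            if abs(self.gamma_shape * self.gamma_scale - self.mean_gpd) > 1e-9:
                raise ConfigurationError(
                    f"{self.stratum}: gamma shape*scale != mean")

    @classmethod
    def from_moments(cls, stratum: StratumKey, p_abstainer: float, p_former: float,
                     p_current: float, mean_gpd: float, *, k: float | None = None,
                     cap: float = DEFAULT_CAP, binge_prevalence: float = 0.0,
                     binge_occasions: float = 0.0) -> "ExposureProfile":
        """Build a profile from status prevalences and the drinker mean."""
        if p_current > 0:
            shape, scale, sd = fit_consumption_density(mean_gpd, stratum.sex, k)
        else:
            mean_gpd, sd, shape, scale = 0.0, 0.0, 0.0, 0.0
        return cls(stratum, p_abstainer, p_former, p_current, mean_gpd, sd,
                   shape, scale, cap, binge_prevalence, binge_occasions)

    # -- truncated-gamma helpers ------------------------------------------

    def _dist(self):
        return stats.gamma(self.gamma_shape, scale=self.gamma_scale)

    def truncation_mass(self) -> float:
        """Untruncated gamma mass below the cap (the renormalizer)."""
        return float(self._dist().cdf(self.cap))

    def density(self, x: np.ndarray) -> np.ndarray:
        """Consumption density among drinkers, renormalized on (0, cap]."""
        x = np.asarray(x, dtype=float)
        pdf = self._dist().pdf(x) / self.truncation_mass()
        return np.where((x > 0) & (x <= self.cap), pdf, 0.0)

    def interval_mass(self, lo: float, hi: float) -> float:
        """Drinker-density mass on (lo, hi] intersected with (0, cap]."""
        dist = self._dist()
        lo = max(lo, 0.0)
        hi = min(hi, self.cap)
        if hi <= lo:
            return 0.0
        return float((dist.cdf(hi) - dist.cdf(lo)) / self.truncation_mass())


# -- estimation from microdata --------------------------------------------


def _stratum_rows(microdata: pd.DataFrame, stratum: StratumKey) -> pd.DataFrame:
    mask = ((microdata["race"] == stratum.race)
            & (microdata["age_band"] == stratum.age_band)
            & (microdata["sex"] == stratum.sex))
    return microdata.loc[mask]


def estimate_prevalences(microdata: pd.DataFrame,
                         stratum: StratumKey) -> tuple[float, float, float]:
    """Survey-weighted (abstainer, former, current) proportions for a stratum."""
    rows = _stratum_rows(microdata, stratum)
    if rows.empty:
        raise EstimationError(f"no survey rows for stratum {stratum}")
    w = rows["weight"].to_numpy(dtype=float)
    total = w.sum()
    out = []
    for status in STATUSES:
        out.append(float(w[(rows["status"] == status).to_numpy()].sum() / total))
    return tuple(out)  # type: ignore[return-value]


def estimate_profile(microdata: pd.DataFrame, stratum: StratumKey, *,
                     k: float | None = None,
                     cap: float = DEFAULT_CAP) -> ExposureProfile:
    """Estimate one stratum's full exposure profile from microdata."""
    p_abs, p_form, p_cur = estimate_prevalences(microdata, stratum)
    rows = _stratum_rows(microdata, stratum)
    drinkers = rows[rows["status"] == STATUS_CURRENT]
    mean_gpd = 0.0
    binge_prev = 0.0
    binge_occ = 0.0
    if not drinkers.empty:
        w = drinkers["weight"].to_numpy(dtype=float)
        g = drinkers["grams_per_day"].to_numpy(dtype=float)
        occ = drinkers["binge_occasions"].to_numpy(dtype=float)
        mean_gpd = float(np.average(g, weights=w))
        bingers = occ > 0
        binge_prev = float(w[bingers].sum() / w.sum())
        if bingers.any():
            binge_occ = float(np.average(occ[bingers], weights=w[bingers]))
    return ExposureProfile.from_moments(
        stratum, p_abs, p_form, p_cur, mean_gpd, k=k, cap=cap,
        binge_prevalence=binge_prev, binge_occasions=binge_occ)


def estimate_profiles(microdata: pd.DataFrame, *, k_men: float | None = None,
                      k_women: float | None = None,
                      cap: float = DEFAULT_CAP) -> list[ExposureProfile]:
    """Profiles for every stratum present in the microdata."""
    profiles = []
    for key, _ in microdata.groupby(STRATUM_COLS, sort=True):
        stratum = StratumKey(*key)
        k = {"men": k_men, "women": k_women}.get(stratum.sex)
        profiles.append(estimate_profile(microdata, stratum, k=k, cap=cap))
    return profiles


# -- per-capita triangulation ---------------------------------------------


@dataclass(frozen=True)
class CoverageAdjustment:
    """Record of one survey-vs-per-capita triangulation."""

    survey_per_capita_l: float
    reference_per_capita_l: float
    target_coverage: float | None
    upshift_factor: float

    @property
    def coverage(self) -> float:
        return self.survey_per_capita_l / self.reference_per_capita_l


def grams_per_day_to_liters_per_year(gpd: float) -> float:
    return gpd * DAYS_PER_YEAR / ETHANOL_G_PER_L


def _population_lookup(population: pd.DataFrame) -> dict[StratumKey, float]:
    return {StratumKey(r.race, r.age_band, r.sex): float(r.population)
            for r in population.itertuples()}


def survey_per_capita(profiles: Iterable[ExposureProfile],
                      population: pd.DataFrame) -> float:
    """Survey-implied adult per-capita consumption, liters of ethanol/year.

    Population-weighted mean of P_current * mean intake over strata.  The
    untruncated gamma mean is used: truncation affects risk integration,
    not the volume accounting against sales data.
    """
    pop = _population_lookup(population)
    num = 0.0
    den = 0.0
    for prof in profiles:
        if prof.stratum not in pop:
            raise EstimationError(f"no population count for stratum {prof.stratum}")
        n = pop[prof.stratum]
        num += n * prof.p_current * prof.mean_gpd
        den += n
    if den <= 0:
        raise EstimationError("total population is zero")
    return grams_per_day_to_liters_per_year(num / den)


def compute_coverage(profiles: Iterable[ExposureProfile], population: pd.DataFrame,
                     reference_per_capita_l: float,
                     target: float | None = DEFAULT_TARGET_COVERAGE) -> CoverageAdjustment:
    implied = survey_per_capita(profiles, population)
    if implied <= 0:
        raise EstimationError("survey-implied per-capita consumption is zero")
    if target is None:
        factor = 1.0
    else:
        if not 0.0 < target <= 1.5:
            raise ConfigurationError(f"target coverage {target} outside (0, 1.5]")
        factor = target * reference_per_capita_l / implied
    return CoverageAdjustment(implied, reference_per_capita_l, target, factor)


def apply_coverage_correction(
        profiles: Sequence[ExposureProfile], population: pd.DataFrame,
        reference_per_capita_l: float,
        target: float | None = DEFAULT_TARGET_COVERAGE,
) -> tuple[list[ExposureProfile], CoverageAdjustment]:
    """Upshift all drinker means by one factor so coverage hits ``target``.

    Prevalences and binge indicators are unchanged; densities are refitted
    from the shifted means.  ``target=None`` disables the correction
    (the unadjusted-consumption sensitivity branch).
    """
    adj = compute_coverage(profiles, population, reference_per_capita_l, target)
    if adj.upshift_factor == 1.0:
        return list(profiles), adj
    shifted = []
    for prof in profiles:
        if prof.p_current <= 0:
            shifted.append(prof)
            continue
        new_mean = prof.mean_gpd * adj.upshift_factor
        k = prof.sd_gpd / prof.mean_gpd
        shape, scale, sd = fit_consumption_density(new_mean, k=k)
        shifted.append(replace(prof, mean_gpd=new_mean, sd_gpd=sd,
                               gamma_shape=shape, gamma_scale=scale))
    return shifted, adj


# -- category prevalences (printed-table style) ----------------------------


def category_prevalence(profile: ExposureProfile,
                        bounds: Sequence[float]) -> np.ndarray:
    """Population prevalence of consumption categories defined by ``bounds``.

    ``bounds`` must be strictly increasing and start at 0; the final
    category is open-ended (truncated at the cap like everything else).
    Fractions sum to P_current.
    """
    b = list(bounds)
    if b[0] != 0 or any(y <= x for x, y in zip(b, b[1:])):
        raise ConfigurationError(f"category bounds must start at 0 and increase: {bounds}")
    b.append(np.inf)
    if profile.p_current <= 0:
        return np.zeros(len(b) - 1)
    masses = np.array([profile.interval_mass(lo, hi) for lo, hi in zip(b, b[1:])])
    return profile.p_current * masses


#: printed-table volume category bounds (g/day) by sex
VOLUME_BOUNDS = {"men": (0.0, 40.0, 60.0, 100.0), "women": (0.0, 20.0, 40.0, 60.0)}


def profiles_to_frame(profiles: Iterable[ExposureProfile]) -> pd.DataFrame:
    """Exposure profiles as a tidy table (one row per stratum)."""
    rows = []
    for p in profiles:
        rows.append({
            "race": p.stratum.race, "age_band": p.stratum.age_band,
            "sex": p.stratum.sex, "p_abstainer": p.p_abstainer,
            "p_former": p.p_former, "p_current": p.p_current,
            "mean_gpd": p.mean_gpd, "sd_gpd": p.sd_gpd,
            "gamma_shape": p.gamma_shape, "gamma_scale": p.gamma_scale,
            "cap": p.cap, "binge_prevalence": p.binge_prevalence,
            "binge_occasions": p.binge_occasions,
        })
    return pd.DataFrame(rows)


def profiles_from_frame(df: pd.DataFrame) -> list[ExposureProfile]:
    out = []
    for r in df.itertuples():
        out.append(ExposureProfile(
            StratumKey(r.race, r.age_band, r.sex), r.p_abstainer, r.p_former,
            r.p_current, r.mean_gpd, r.sd_gpd, r.gamma_shape, r.gamma_scale,
            r.cap, r.binge_prevalence, r.binge_occasions))
    return out
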
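"""Synthetic survey microdata, mortality, population, and life tables.

The generator emulates the statistical structure the pipeline assumes in
real inputs: a stratified survey with trinomial drinking status
(lifetime abstainer / former / current), gamma-distributed daily ethanol
intake among current drinkers with SD tied to the mean by the sex-specific
constant, and binge drinking as a Bernoulli indicator with zero-truncated
Poisson occasion counts.  Mortality counts can be planted with known
attributable fractions (count = baseline / (1 - AAF)), so the whole
pipeline can be validated by recovery.

Default stratum prevalences come from the packaged consumption-indicator
table (the survey's published lifetime-abstainer and former-drinker
percentages by race, age, and sex); drinker means, binge parameters,
population counts, and the life table are synthetic choices documented in
docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .exposure import (
    STATUS_CURRENT,
    STATUS_FORMER,
    STATUS_LIFETIME_ABSTAINER,
    ExposureProfile,
    fit_consumption_density,
)
from .risk import Registry
from .strata import (
    AGE_BANDS,
    DEFAULT_CAP,
    RACES,
    SEXES,
    ConfigurationError,
    StratumKey,
    age_band_midpoint,
    k_for_sex,
)


@dataclass(frozen=True)
class StratumParams:
    """Ground-truth exposure parameters for one synthetic stratum."""

    stratum: StratumKey
    p_abstainer: float
    p_former: float
    mean_gpd: float
    binge_prevalence: float = 0.0     # fraction of current drinkers
    binge_rate: float = 0.0           # Poisson occasions/year among bingers
    n: int = 1000                     # survey rows
    population: float = 1_000_000.0   # population count

    @property
    def p_current(self) -> float:
        return 1.0 - self.p_abstainer - self.p_former

    def validate(self) -> None:
        if not (0 <= self.p_abstainer <= 1 and 0 <= self.p_former <= 1):
            raise ConfigurationError(f"{self.stratum}: prevalences outside [0, 1]")
        if self.p_abstainer + self.p_former > 1 + 1e-12:
            raise ConfigurationError(
                f"{self.stratum}: abstainer + former prevalence exceeds 1")
        if self.p_current > 0 and self.mean_gpd <= 0:
            raise ConfigurationError(
                f"{self.stratum}: drinkers present but mean consumption <= 0")
        if not 0 <= self.binge_prevalence <= 1:
            raise ConfigurationError(f"{self.stratum}: binge prevalence outside [0, 1]")
        if self.n < 1:
            raise ConfigurationError(f"{self.stratum}: sample size < 1")


@dataclass(frozen=True)
class SyntheticConfig:
    strata: tuple[StratumParams, ...]
    per_capita_l: float = 9.5    # reference adult per-capita, liters ethanol/year
    seed: int = 0
    cap: float = DEFAULT_CAP
    variable_weights: bool = False

    def validate(self) -> None:
        for sp in self.strata:
            sp.validate()

    def with_sample_size(self, n: int) -> "SyntheticConfig":
        return replace(self, strata=tuple(replace(sp, n=n) for sp in self.strata))


def _zero_truncated_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Poisson conditioned on >= 1 (binge-positive drinkers report >= 1 occasion)."""
    out = rng.poisson(lam, size)
    zeros = out == 0
    while zeros.any():
        out[zeros] = rng.poisson(lam, int(zeros.sum()))
        zeros = out == 0
    return out


def generate_survey(config: SyntheticConfig,
                    seed: int | None = None) -> pd.DataFrame:
    """Survey microdata: one row per respondent, reproducible given seed."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    frames = []
    for sp in config.strata:
        n = sp.n
        status = rng.choice(
            np.array([STATUS_LIFETIME_ABSTAINER, STATUS_FORMER, STATUS_CURRENT]),
            size=n, p=[sp.p_abstainer, sp.p_former, sp.p_current])
        grams = np.zeros(n)
        occasions = np.zeros(n)
        cur = status == STATUS_CURRENT
        ncur = int(cur.sum())
        if ncur:
            shape, scale, _ = fit_consumption_density(sp.mean_gpd, sp.stratum.sex)
            grams[cur] = rng.gamma(shape, scale, ncur)
            bingers = np.zeros(n, dtype=bool)
            bingers[cur] = rng.random(ncur) < sp.binge_prevalence
            nb = int(bingers.sum())
            if nb:
                occasions[bingers] = _zero_truncated_poisson(rng, sp.binge_rate, nb)
        weight = (rng.lognormal(0.0, 0.3, n) if config.variable_weights
                  else np.ones(n))
        frames.append(pd.DataFrame({
            "race": sp.stratum.race, "age_band": sp.stratum.age_band,
            "sex": sp.stratum.sex, "status": status, "grams_per_day": grams,
            "binge_occasions": occasions, "weight": weight,
        }))
    return pd.concat(frames, ignore_index=True)


def true_profiles(config: SyntheticConfig) -> list[ExposureProfile]:
    """Exposure profiles implied by the generator's ground-truth parameters.

    The binge occasion mean is the zero-truncated Poisson mean
    lambda / (1 - e^{-lambda}), matching what estimation from the microdata
    recovers.
    """
    out = []
    for sp in config.strata:
        lam = sp.binge_rate
        occ = lam / (1.0 - math.exp(-lam)) if lam > 0 else 0.0
        out.append(ExposureProfile.from_moments(
            sp.stratum, sp.p_abstainer, sp.p_former, sp.p_current,
            sp.mean_gpd if sp.p_current > 0 else 0.0, cap=config.cap,
            binge_prevalence=sp.binge_prevalence, binge_occasions=occ))
    return out


def generate_population(config: SyntheticConfig) -> pd.DataFrame:
    return pd.DataFrame([{
        "race": sp.stratum.race, "age_band": sp.stratum.age_band,
        "sex": sp.stratum.sex, "population": sp.population,
    } for sp in config.strata])


def generate_lifetable(age_bands: tuple[str, ...] = AGE_BANDS) -> pd.DataFrame:
    """Synthetic remaining life expectancy by sex and age band.

    Linear decline from a sex-specific level at birth-equivalent age,
    evaluated at the band midpoint: decreasing in age, women above men.
    """
    level = {"men": 76.0, "women": 81.0}
    rows = []
    for sex in SEXES:
        for band in age_bands:
            mid = age_band_midpoint(band)
            rows.append({"sex": sex, "age_band": band,
                         "life_expectancy": level[sex] - 0.9 * mid})
    return pd.DataFrame(rows)


def generate_mortality(config: SyntheticConfig, aaf_truth: pd.DataFrame,
                       baseline: float | pd.DataFrame = 1000.0,
                       wholly_causes: set[str] | frozenset[str] = frozenset()) -> pd.DataFrame:
    """Mortality counts with planted attributable fractions.

    Each (stratum, cause) count is baseline / (1 - AAF), rounded, so that
    AAF x count reproduces the planted attributable deaths.  ``baseline``
    is either a scalar alcohol-free count for every cell or a frame with a
    ``baseline`` column keyed like ``aaf_truth``.  Causes listed in
    ``wholly_causes`` carry AAF = 1 and get ``baseline`` deaths directly
    (every death attributable); AAF >= 1 anywhere else is an error.
    """
    keys = ["race", "age_band", "sex", "cause"]
    df = aaf_truth[keys + ["aaf"]].copy()
    if df.duplicated(keys).any():
        raise ConfigurationError("duplicate (stratum, cause) rows in aaf_truth")
    if isinstance(baseline, pd.DataFrame):
        df = df.merge(baseline[keys + ["baseline"]], on=keys, validate="one_to_one")
    else:
        df["baseline"] = float(baseline)
    wholly = df["cause"].isin(wholly_causes)
    if (df.loc[~wholly, "aaf"] >= 1.0).any():
        bad = df.loc[~wholly & (df["aaf"] >= 1.0), keys]
        raise ConfigurationError(
            "cannot plant AAF >= 1 for non-wholly-attributable causes:\n"
            + bad.to_string(index=False))
    df["deaths"] = 0
    df.loc[wholly, "deaths"] = df.loc[wholly, "baseline"].round().astype(int)
    df.loc[~wholly, "deaths"] = (
        df.loc[~wholly, "baseline"] / (1.0 - df.loc[~wholly, "aaf"])
    ).round().astype(int)
    if (df["deaths"] < 0).any():
        raise ConfigurationError("negative death count generated")
    return df[keys + ["deaths"]]


# -- default study-shaped configuration ------------------------------------

#: synthetic drinker means (g/day) by sex and age band
DEFAULT_MEANS = {
    "men": {"15-24": 26.0, "25-34": 24.0, "35-44": 23.0, "45-54": 22.0, "55-64": 18.0},
    "women": {"15-24": 13.0, "25-34": 11.0, "35-44": 11.0, "45-54": 10.0, "55-64": 8.0},
}
#: synthetic binge parameters by sex: (prevalence among drinkers, occasions/year)
DEFAULT_BINGE = {"men": (0.35, 26.0), "women": (0.15, 12.0)}
#: synthetic population counts by race (per age-sex cell), ~2005 US proportions
DEFAULT_POPULATIONS = {"White": 16_000_000.0, "Black": 2_500_000.0,
                       "Asian/Pacific Islander": 900_000.0,
                       "Native American": 300_000.0}


def _table1_prevalences() -> dict[StratumKey, tuple[float, float]]:
    with resources.files("aafburden.data").joinpath("table1.csv").open() as fh:
        t1 = pd.read_csv(fh)
    t1 = t1[t1.age.isin(AGE_BANDS)]
    out: dict[StratumKey, tuple[float, float]] = {}
    for (race, age, sex), grp in t1.groupby(["race", "age", "sex"]):
        vals = dict(zip(grp.measure, grp.percent))
        out[StratumKey(race, age, sex)] = (
            vals["lifetime_abstainers"] / 100.0, vals["former_drinkers"] / 100.0)
    return out


def default_config(n_per_stratum: int = 1000, seed: int = 0) -> SyntheticConfig:
    """All 40 (race x age band x sex) strata with published status prevalences."""
    prev = _table1_prevalences()
    strata = []
    for race in RACES:
        for band in AGE_BANDS:
            for sex in SEXES:
                key = StratumKey(race, band, sex)
                p_abs, p_form = prev[key]
                bp, br = DEFAULT_BINGE[sex]
                strata.append(StratumParams(
                    key, p_abs, p_form, DEFAULT_MEANS[sex][band], bp, br,
                    n=n_per_stratum, population=DEFAULT_POPULATIONS[race]))
    return SyntheticConfig(tuple(strata), seed=seed)


def planted_aafs(config: SyntheticConfig, registry: Registry,
                 causes: list[str] | None = None) -> pd.DataFrame:
    """Ground-truth AAFs from the generator parameters and a registry."""
    from .aaf import compute_aafs  # local import: aaf does not depend on this module

    return compute_aafs(true_profiles(config), registry, causes)


def write_all(config: SyntheticConfig, outdir: str | Path,
              aaf_truth: pd.DataFrame | None = None,
              baseline: float = 1000.0) -> dict[str, Path]:
    """Write survey/population/lifetable (and mortality if AAFs given) CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    survey = generate_survey(config)
    for name, frame in [("survey", survey),
                        ("population", generate_population(config)),
                        ("lifetable", generate_lifetable())]:
        paths[name] = outdir / f"{name}.csv"
        frame.to_csv(paths[name], index=False)
    if aaf_truth is not None:
        mortality = generate_mortality(config, aaf_truth, baseline)
        paths["mortality"] = outdir / "mortality.csv"
        mortality.to_csv(paths["mortality"], index=False)
    return paths
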
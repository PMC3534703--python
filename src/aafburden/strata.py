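"""Shared stratum identity, constants, and exception types.

Every stage of the pipeline operates on population cells identified by a
(race, age band, sex) triple.  Age bands partition 15–64 into five 10-year
bands; race labels are opaque keys matching the four census categories used
in the source mortality data.
"""

from __future__ import annotations

from typing import NamedTuple


class StratumKey(NamedTuple):
    """Identity of one (race, age band, sex) population cell."""

    race: str
    age_band: str
    sex: str


RACES = ("White", "Black", "Asian/Pacific Islander", "Native American")
AGE_BANDS = ("15-24", "25-34", "35-44", "45-54", "55-64")
SEXES = ("men", "women")

#: grams of pure ethanol in one liter
ETHANOL_G_PER_L = 789.24
#: days per year used for per-capita conversions
DAYS_PER_YEAR = 365.0

#: mean-to-SD ratio of drinker consumption, by sex (SD = k * mean)
K_MEN = 1.171
K_WOMEN = 1.258
#: upper integration / consumption cap in grams of ethanol per day
DEFAULT_CAP = 150.0
#: default target coverage for the per-capita triangulation
DEFAULT_TARGET_COVERAGE = 0.80
#: continuous-time discount rate for years of life lost
DEFAULT_DISCOUNT_RATE = 0.03


def k_for_sex(sex: str) -> float:
    if sex == "men":
        return K_MEN
    if sex == "women":
        return K_WOMEN
    raise ConfigurationError(f"unknown sex label {sex!r}; expected 'men' or 'women'")


def age_band_midpoint(band: str) -> float:
    """Midpoint in years of an 'lo-hi' age band (bands are inclusive)."""
    try:
        lo, hi = band.split("-")
        return (float(lo) + float(hi) + 1.0) / 2.0
    except ValueError as exc:
        raise ConfigurationError(f"malformed age band {band!r}") from exc


def age_band_start(band: str) -> float:
    try:
        return float(band.split("-")[0])
    except ValueError as exc:
        raise ConfigurationError(f"malformed age band {band!r}") from exc


class AafBurdenError(Exception):
    """Base class for pipeline errors."""


class ConfigurationError(AafBurdenError):
    """Invalid configuration (prevalence simplex, bounds, targets, ...)."""


class EstimationError(AafBurdenError):
    """Estimation impossible for a stratum (e.g. no survey rows)."""


class RegistryError(AafBurdenError):
    """Risk registry malformed or incomplete for the requested causes."""


class NumericalError(AafBurdenError):
    """Quadrature failed its internal cross-check."""
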
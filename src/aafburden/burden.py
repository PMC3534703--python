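"""Attributable deaths, discounted years of life lost, aggregation, and
direct standardization — application of the attributable fractions to
mortality data.

Attributable deaths in a (stratum, cause) cell are AAF x total deaths, kept
signed: net-protective causes subtract from the burden.  PYLL per death is
the remaining life expectancy of the stratum discounted at a continuous
rate r (default 3%/year): (1 - exp(-r L)) / r.  Margins are always sums of
unrounded cells; percent columns are recomputed from summed numerators and
denominators, never averaged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .aaf import compute_aafs
from .exposure import apply_coverage_correction, estimate_profiles
from .risk import Registry
from .strata import (
    DEFAULT_DISCOUNT_RATE,
    DEFAULT_TARGET_COVERAGE,
    ConfigurationError,
    EstimationError,
)

CELL_KEYS = ["race", "age_band", "sex", "cause"]
VALUE_COLS = ["deaths", "attrib_deaths", "total_pyll", "attrib_pyll"]


@dataclass(frozen=True)
class DiscountSpec:
    """Discounting and publication-rounding conventions.

    ``continuous`` selects e^{-rt} discounting (the convention of burden
    studies); the discrete-annual alternative uses (1+r)^{-t}.  Published
    tables round deaths to integers and PYLL to the nearest 10; internal
    arithmetic is never rounded.
    """

    rate: float = DEFAULT_DISCOUNT_RATE
    continuous: bool = True
    deaths_decimals: int = 0
    pyll_nearest: int = 10

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ConfigurationError(f"discount rate must be >= 0, got {self.rate}")


def attributable_deaths(aaf: float, deaths: float) -> float:
    """Signed attributable count: AAF x deaths."""
    if deaths < 0:
        raise ConfigurationError(f"death count must be >= 0, got {deaths}")
    return aaf * deaths


def discounted_pyll(life_expectancy: float, rate: float = DEFAULT_DISCOUNT_RATE,
                    continuous: bool = True) -> float:
    """Discounted years of life lost per death with remaining expectancy L.

    Continuous: (1 - e^{-rL}) / r;  discrete annual: (1 - (1+r)^{-L}) / r;
    r = 0 degenerates to L in both.  Always <= L, equality iff r = 0.
    """
    L = life_expectancy
    if L < 0:
        raise ConfigurationError(f"life expectancy must be >= 0, got {L}")
    if rate == 0:
        return L
    if continuous:
        return (1.0 - math.exp(-rate * L)) / rate
    return (1.0 - (1.0 + rate) ** (-L)) / rate


def _life_lookup(lifetable: pd.DataFrame) -> dict[tuple[str, str], float]:
    return {(r.sex, r.age_band): float(r.life_expectancy)
            for r in lifetable.itertuples()}


def compute_burden(mortality: pd.DataFrame, aafs: pd.DataFrame,
                   lifetable: pd.DataFrame,
                   discount: DiscountSpec = DiscountSpec()) -> pd.DataFrame:
    """Per-cell burden table from mortality counts and attributable fractions.

    Cells present in the mortality file but missing from the AAF table raise;
    the registry must resolve every cause upstream.
    """
    merged = mortality.merge(aafs[CELL_KEYS + ["aaf"]], on=CELL_KEYS,
                             how="left", validate="one_to_one")
    if merged["aaf"].isna().any():
        missing = merged.loc[merged["aaf"].isna(), CELL_KEYS].drop_duplicates()
        raise EstimationError(
            "no AAF for mortality cells:\n" + missing.to_string(index=False))
    life = _life_lookup(lifetable)
    ypd = []
    for r in merged.itertuples():
        key = (r.sex, r.age_band)
        if key not in life:
            raise EstimationError(f"no life-expectancy row for {key}")
        ypd.append(discounted_pyll(life[key], discount.rate, discount.continuous))
    merged["pyll_per_death"] = ypd
    merged["attrib_deaths"] = merged["aaf"] * merged["deaths"]
    merged["total_pyll"] = merged["deaths"] * merged["pyll_per_death"]
    merged["attrib_pyll"] = merged["aaf"] * merged["total_pyll"]
    return merged


def aggregate(burden: pd.DataFrame, by: Sequence[str]) -> pd.DataFrame:
    """Sum burden cells over ``by`` and recompute percent-attributable.

    Percents come from summed numerators over summed denominators (never
    averaged percentages).  An empty ``by`` gives the single grand total.
    """
    by = list(by)
    cols = [c for c in VALUE_COLS if c in burden.columns]
    if by:
        out = burden.groupby(by, sort=True, as_index=False)[cols].sum()
    else:
        out = burden[cols].sum().to_frame().T
    if {"deaths", "attrib_deaths"} <= set(out.columns):
        out["pct_attrib_deaths"] = np.where(
            out["deaths"] > 0, 100.0 * out["attrib_deaths"] / out["deaths"], np.nan)
    if {"total_pyll", "attrib_pyll"} <= set(out.columns):
        out["pct_attrib_pyll"] = np.where(
            out["total_pyll"] > 0, 100.0 * out["attrib_pyll"] / out["total_pyll"], np.nan)
    return out


def standardized_rate(burden: pd.DataFrame, population: pd.DataFrame,
                      standard_population: pd.DataFrame,
                      value_col: str = "attrib_deaths",
                      group_cols: Sequence[str] = ("race",)) -> pd.DataFrame:
    """Directly standardized rates per 100,000 by ``group_cols``.

    Stratum-specific rates (value / population, by age band and sex within
    each group) are weighted by the standard population's age-sex structure.
    """
    group_cols = list(group_cols)
    strata_cols = ["age_band", "sex"]
    std = standard_population.groupby(strata_cols, as_index=False)["population"].sum()
    std_total = std["population"].sum()
    if std_total <= 0:
        raise ConfigurationError("standard population is empty")
    std = std.rename(columns={"population": "std_pop"})

    counts = burden.groupby(group_cols + strata_cols, as_index=False)[value_col].sum()
    pop = population.groupby(group_cols + strata_cols, as_index=False)["population"].sum()
    merged = counts.merge(pop, on=group_cols + strata_cols, how="left")
    if merged["population"].isna().any():
        missing = merged.loc[merged["population"].isna(), group_cols + strata_cols]
        raise EstimationError(
            "no population for strata:\n" + missing.to_string(index=False))
    zero = merged["population"] <= 0
    if (zero & (merged[value_col] != 0)).any():
        raise EstimationError("zero population stratum with nonzero counts")
    merged["rate"] = np.where(zero, 0.0, merged[value_col] / merged["population"])
    merged = merged.merge(std, on=strata_cols, how="left")
    if merged["std_pop"].isna().any():
        raise EstimationError("standard population missing age-sex strata")
    merged["weighted"] = merged["rate"] * merged["std_pop"] / std_total
    out = merged.groupby(group_cols, as_index=False)["weighted"].sum()
    out = out.rename(columns={"weighted": "rate_per_100k"})
    out["rate_per_100k"] *= 100_000.0
    return out


def round_published(burden: pd.DataFrame,
                    discount: DiscountSpec = DiscountSpec()) -> pd.DataFrame:
    """Apply the publication rounding rules (deaths to integers, PYLL to 10s)."""
    out = burden.copy()
    for col in ("deaths", "attrib_deaths"):
        if col in out:
            out[col] = out[col].round(discount.deaths_decimals)
    for col in ("total_pyll", "attrib_pyll"):
        if col in out:
            out[col] = (out[col] / discount.pyll_nearest).round() * discount.pyll_nearest
    return out


def run_pipeline(survey: pd.DataFrame, mortality: pd.DataFrame,
                 population: pd.DataFrame, lifetable: pd.DataFrame,
                 registry: Registry, reference_per_capita_l: float,
                 target_coverage: float | None = DEFAULT_TARGET_COVERAGE,
                 discount: DiscountSpec = DiscountSpec()) -> dict:
    """Survey microdata to burden table in one call.

    Returns a dict with the estimated (and coverage-corrected) profiles, the
    coverage adjustment record, the AAF table, the per-cell burden table and
    standardized attributable-death and PYLL rates by race.
    """
    profiles = estimate_profiles(survey, cap=registry.cap)
    profiles, adjustment = apply_coverage_correction(
        profiles, population, reference_per_capita_l, target_coverage)
    aafs = compute_aafs(profiles, registry,
                        causes=list(dict.fromkeys(mortality["cause"])))
    cells = compute_burden(mortality, aafs, lifetable, discount)
    cells["bucket"] = cells["cause"].map(
        {label: cg.bucket for label, cg in registry.causes.items()})
    rates = standardized_rate(cells, population, population, "attrib_deaths")
    pyll_rates = standardized_rate(cells, population, population, "attrib_pyll")
    return {
        "profiles": profiles,
        "coverage": adjustment,
        "aafs": aafs,
        "burden": cells,
        "death_rates": rates.rename(columns={"rate_per_100k": "deaths_per_100k"}),
        "pyll_rates": pyll_rates.rename(columns={"rate_per_100k": "pyll_per_100k"}),
    }
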
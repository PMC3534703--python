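"""Publication-style tables, figures, and the internal-consistency audit.

``audit_paper_tables`` recomputes every margin of the published mortality
and PYLL tables from their printed cells — race-block sums, age-band sums,
cause-group sums, percent-attributable cells, and the headline totals
quoted in the running text — and compares them with the printed values.
Counts must agree exactly; percentages are compared after rounding to one
decimal place (the tables' print precision), with the raw recomputed value
kept in the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .exposure import VOLUME_BOUNDS, ExposureProfile, category_prevalence
from .strata import AafBurdenError, RACES

TOT = "All causes of death (total)"
ATT = "All causes of death (alcohol attributable)"
PCT = "All causes of death (% alcohol attributable)"
INJURY_CAUSES = ("Unintentional injuries", "Intentional injuries",
                 "Underdetermined intent")

#: headline values printed in the running text (not recoverable from the
#: table margins alone), used as expected values for the text-vs-table checks
PUBLISHED_TEXT = {
    "deaths_injury_total": 36_622.0,
    "deaths_injury_men": 33_485.0,
    "deaths_injury_women": 3_137.0,
    "pyll_injury_pct_of_all": 7.2,
}


def fixture_path(name: str) -> Path:
    """Path to a packaged fixture CSV (table1/table2/table3)."""
    return Path(str(resources.files("aafburden.data").joinpath(f"{name}.csv")))


@dataclass(frozen=True)
class ConsistencyCheck:
    name: str
    expected: float
    computed: float
    tolerance: float = 0.0
    detail: str = ""

    @property
    def passed(self) -> bool:
        return abs(self.computed - self.expected) <= self.tolerance + 1e-12


@dataclass
class ConsistencyReport:
    checks: list[ConsistencyCheck] = field(default_factory=list)

    def add(self, check: ConsistencyCheck) -> None:
        if any(c.name == check.name for c in self.checks):
            raise AafBurdenError(f"duplicate consistency check {check.name!r}")
        self.checks.append(check)

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def failures(self) -> list[ConsistencyCheck]:
        return [c for c in self.checks if not c.passed]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "check": c.name, "expected": c.expected, "computed": c.computed,
            "tolerance": c.tolerance, "passed": c.passed, "detail": c.detail,
        } for c in self.checks])

    def __getitem__(self, name: str) -> ConsistencyCheck:
        for c in self.checks:
            if c.name == name:
                return c
        raise KeyError(name)


def _load_table(path: str | Path, value: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"race", "cause", "sex", "age", value}
    if not required <= set(df.columns):
        raise AafBurdenError(f"fixture {path} missing columns {required - set(df.columns)}")
    df[value] = df[value].astype(float)
    return df


def _cell(df: pd.DataFrame, value: str, race: str, cause: str, sex: str, age: str) -> float:
    sub = df[(df.race == race) & (df.cause == cause) & (df.sex == sex) & (df.age == age)]
    if len(sub) != 1:
        raise AafBurdenError(f"fixture cell ({race}, {cause}, {sex}, {age}) not unique")
    return float(sub[value].iloc[0])


def _max_deviation(pairs: Iterable[tuple[str, float, float]]) -> tuple[float, str]:
    worst, where = 0.0, ""
    for label, expected, computed in pairs:
        d = abs(computed - expected)
        if d > worst:
            worst, where = d, label
    return worst, where


def _audit_one(df: pd.DataFrame, value: str, tag: str, report: ConsistencyReport) -> None:
    causes = [c for c in df.cause.unique() if c not in (TOT, ATT, PCT)]
    ages = sorted(a for a in df.age.unique() if a != "15-64")
    cols = [("men", a) for a in ages + ["15-64"]] + \
           [("women", a) for a in ages + ["15-64"]] + [("total", "15-64")]

    # headline totals: Total block vs sum over race blocks
    for label, sex in [("total", "total"), ("men", "men"), ("women", "women")]:
        printed = _cell(df, value, "Total", ATT, sex, "15-64")
        summed = sum(_cell(df, value, r, ATT, sex, "15-64") for r in RACES)
        report.add(ConsistencyCheck(f"{tag}_attributable_{label}", printed, summed))
        tot_printed = _cell(df, value, "Total", TOT, sex, "15-64")
        tot_summed = sum(_cell(df, value, r, TOT, sex, "15-64") for r in RACES)
        pct_printed = _cell(df, value, "Total", PCT, sex, "15-64")
        report.add(ConsistencyCheck(f"{tag}_pct_attributable_{label}", pct_printed,
                                    round(100.0 * summed / tot_summed, 1)))

    # per-race percent attributable, recomputed from the block's own cells
    for race in RACES:
        att = _cell(df, value, race, ATT, "total", "15-64")
        tot = _cell(df, value, race, TOT, "total", "15-64")
        printed = _cell(df, value, race, PCT, "total", "15-64")
        slug = race.lower().replace("/", "_").replace(" ", "_")
        report.add(ConsistencyCheck(f"{tag}_pct_attributable_{slug}", printed,
                                    round(100.0 * att / tot, 1)))

    # race-block additivity per column (the overall block prints only the
    # all-cause rows, so those are the recomputable margins)
    pairs = []
    for cause in (TOT, ATT):
        for sex, age in cols:
            printed = _cell(df, value, "Total", cause, sex, age)
            summed = sum(_cell(df, value, r, cause, sex, age) for r in RACES)
            pairs.append((f"{cause}/{sex}/{age}", printed, summed))
    worst, where = _max_deviation(pairs)
    report.add(ConsistencyCheck(f"{tag}_race_margin_consistency", 0.0, worst, detail=where))

    # age-band additivity within each block
    pairs = []
    for race in ["Total"] + list(RACES):
        for cause in (TOT, ATT):
            for sex in ("men", "women"):
                summed = sum(_cell(df, value, race, cause, sex, a) for a in ages)
                printed = _cell(df, value, race, cause, sex, "15-64")
                pairs.append((f"{race}/{cause}/{sex}", printed, summed))
            both = (_cell(df, value, race, cause, "men", "15-64")
                    + _cell(df, value, race, cause, "women", "15-64"))
            pairs.append((f"{race}/{cause}/men+women",
                          _cell(df, value, race, cause, "total", "15-64"), both))
    worst, where = _max_deviation(pairs)
    report.add(ConsistencyCheck(f"{tag}_age_margin_consistency", 0.0, worst, detail=where))

    # cause-group additivity: cause rows sum to the all-cause attributable row
    pairs = []
    for race in RACES:
        for sex, age in cols:
            summed = sum(_cell(df, value, race, c, sex, age) for c in causes)
            printed = _cell(df, value, race, ATT, sex, age)
            pairs.append((f"{race}/{sex}/{age}", printed, summed))
    worst, where = _max_deviation(pairs)
    report.add(ConsistencyCheck(f"{tag}_cause_margin_consistency", 0.0, worst, detail=where))

    # every percent cell vs its recomputation (rounded to print precision)
    pairs = []
    for race in ["Total"] + list(RACES):
        for sex, age in cols:
            att = _cell(df, value, race, ATT, sex, age)
            tot = _cell(df, value, race, TOT, sex, age)
            printed = _cell(df, value, race, PCT, sex, age)
            pairs.append((f"{race}/{sex}/{age}", printed, round(100.0 * att / tot, 1)))
    worst, where = _max_deviation(pairs)
    report.add(ConsistencyCheck(f"{tag}_pct_cells_match", 0.0, worst, detail=where))

    # injury margins quoted in the running text
    inj = {sex: sum(_cell(df, value, r, c, sex, "15-64")
                    for r in RACES for c in INJURY_CAUSES)
           for sex in ("men", "women", "total")}
    if tag == "deaths":
        report.add(ConsistencyCheck("deaths_injury_total",
                                    PUBLISHED_TEXT["deaths_injury_total"], inj["total"]))
        report.add(ConsistencyCheck("deaths_injury_men",
                                    PUBLISHED_TEXT["deaths_injury_men"], inj["men"]))
        report.add(ConsistencyCheck("deaths_injury_women",
                                    PUBLISHED_TEXT["deaths_injury_women"], inj["women"]))
    else:
        all_pyll = _cell(df, value, "Total", TOT, "total", "15-64")
        report.add(ConsistencyCheck("pyll_injury_pct_of_all",
                                    PUBLISHED_TEXT["pyll_injury_pct_of_all"],
                                    round(100.0 * inj["total"] / all_pyll, 1)))


def audit_paper_tables(table2: str | Path | None = None,
                       table3: str | Path | None = None) -> ConsistencyReport:
    """Recompute and verify every margin of the published burden tables."""
    t2 = _load_table(table2 or fixture_path("table2"), "deaths")
    t3 = _load_table(table3 or fixture_path("table3"), "pyll")
    report = ConsistencyReport()
    _audit_one(t2, "deaths", "deaths", report)
    _audit_one(t3, "pyll", "pyll", report)
    return report


# -- rendering -------------------------------------------------------------

_AGE_ORDER = ["15-24", "25-34", "35-44", "45-54", "55-64"]


def _wide_block(cells: pd.DataFrame, value_col: str) -> pd.DataFrame:
    """Pivot one race block to the published men/women x age layout."""
    rows = {}
    for cause, grp in cells.groupby("cause", sort=True):
        row = {}
        for sex in ("men", "women"):
            sub = grp[grp.sex == sex]
            for age in _AGE_ORDER:
                row[f"{sex} {age}"] = float(sub.loc[sub.age_band == age, value_col].sum())
            row[f"{sex} 15-64"] = float(sub[value_col].sum())
        row["total"] = float(grp[value_col].sum())
        rows[cause] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def render_burden_tables(burden: pd.DataFrame, outdir: str | Path,
                         value_col: str = "attrib_deaths",
                         stem: str = "deaths") -> dict[str, Path]:
    """Write published-style wide tables (CSV + plain text) per race block.

    Each block carries the cause rows plus all-cause total, attributable,
    and percent-attributable rows; percents to one decimal, recomputed from
    the same cells that fill the table.
    """
    if burden.empty:
        raise AafBurdenError("empty burden table")
    total_col = {"attrib_deaths": "deaths", "attrib_pyll": "total_pyll"}[value_col]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    blocks = []
    for race in ["Total"] + sorted(burden.race.unique()):
        cells = burden if race == "Total" else burden[burden.race == race]
        blk = _wide_block(cells, value_col)
        totals = _wide_block(cells, total_col).sum(axis=0)
        att = blk.sum(axis=0)
        blk.loc[TOT] = totals
        blk.loc[ATT] = att
        blk.loc[PCT] = (100.0 * att / totals).round(1)
        blk.insert(0, "race", race)
        blocks.append(blk)
    wide = pd.concat(blocks)
    wide.index.name = "cause"
    paths = {"csv": outdir / f"{stem}_table.csv", "txt": outdir / f"{stem}_table.txt"}
    wide.to_csv(paths["csv"])
    paths["txt"].write_text(wide.round(1).to_string() + "\n")
    return paths


def render_exposure_table(profiles: Sequence[ExposureProfile],
                          outdir: str | Path) -> Path:
    """Consumption-indicator table: status prevalences + volume categories."""
    rows = []
    for p in profiles:
        bounds = VOLUME_BOUNDS[p.stratum.sex]
        cats = category_prevalence(p, bounds)
        row = {
            "race": p.stratum.race, "age_band": p.stratum.age_band,
            "sex": p.stratum.sex,
            "lifetime_abstainers_pct": 100.0 * p.p_abstainer,
            "former_drinkers_pct": 100.0 * p.p_former,
        }
        edges = [*bounds, None]
        for i, mass in enumerate(cats):
            lo, hi = edges[i], edges[i + 1]
            label = f"vol_{lo:g}_{hi:g}_pct" if hi is not None else f"vol_{lo:g}_plus_pct"
            row[label] = 100.0 * mass
        rows.append(row)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "exposure_table.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def plot_standardized_rates(rates: pd.DataFrame, outpath: str | Path,
                            value_col: str = "rate_per_100k",
                            title: str = "Standardized rate per 100,000") -> Path:
    """Bar chart of standardized rates by race (one bar per group)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(rates.iloc[:, 0].astype(str), rates[value_col])
    ax.set_ylabel(title)
    ax.tick_params(axis="x", rotation=20)
    fig.tight_layout()
    outpath = Path(outpath)
    fig.savefig(outpath, dpi=150)
    plt.close(fig)
    return outpath
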
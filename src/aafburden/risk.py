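"""Registry of cause-of-death groups and dose-response relative-risk functions.

Each cause group carries an ICD-10 range tag, a reporting bucket
(communicable / noncommunicable / injury) and the method used to turn
exposure into an attributable fraction:

* ``chronic``  — continuous RR(x) integrated over the consumption density;
* ``ihd``      — ischemic-heart-disease style: non-binge drinkers follow a
  protective curve, binge drinkers a detrimental curve floored at RR=1;
* ``injury``   — categorical RRs over (volume category x binge status) cells;
* ``hiv``      — a single nonadherence RR above a daily-volume threshold;
* ``wholly_attributable`` — AAF fixed at 1 (ICD codes naming alcohol).

RR functional forms: ``log_linear`` (log RR is a polynomial in dose with no
constant term), ``piecewise_linear_spline`` (log RR linearly interpolated
between knots, flat beyond the last), and ``constant``.

The registry shipped with the package (``data/risk_registry.yaml``) contains
ILLUSTRATIVE coefficients with the right qualitative shapes; it is meant for
synthetic experiments and as a schema example, not as meta-analytic truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .strata import DEFAULT_CAP, SEXES, RegistryError

METHODS = ("chronic", "ihd", "injury", "hiv", "wholly_attributable")
BUCKETS = ("communicable", "noncommunicable", "injury")
FORMS = ("log_linear", "piecewise_linear_spline", "constant")

#: roles a risk function can play within a cause
ROLE_MAIN = "main"
ROLE_PROTECTIVE = "protective"   # ihd: non-binge drinkers
ROLE_DETRIMENTAL = "detrimental"  # ihd: binge drinkers


@dataclass(frozen=True)
class CauseGroup:
    label: str
    icd10: str
    bucket: str
    method: str
    protective_ok: bool = False

    def __post_init__(self) -> None:
        if self.bucket not in BUCKETS:
            raise RegistryError(f"{self.label}: unknown bucket {self.bucket!r}")
        if self.method not in METHODS:
            raise RegistryError(f"{self.label}: unknown AAF method {self.method!r}")


@dataclass(frozen=True)
class RiskFunction:
    """Dose-response RR(x) for one (cause, sex), plus the former-drinker RR."""

    cause: str
    sex: str
    form: str
    coefficients: tuple[float, ...] = ()
    knots: tuple[float, ...] = ()
    rr_former: float = 1.0
    role: str = ROLE_MAIN

    def __post_init__(self) -> None:
        if self.form not in FORMS:
            raise RegistryError(f"{self.cause}/{self.sex}: unknown form {self.form!r}")
        if self.rr_former < 0:
            raise RegistryError(f"{self.cause}/{self.sex}: rr_former < 0")
        if self.form == "piecewise_linear_spline":
            if len(self.knots) != len(self.coefficients) or len(self.knots) < 2:
                raise RegistryError(
                    f"{self.cause}/{self.sex}: spline needs matching knots/values")
            if self.knots[0] != 0 or self.coefficients[0] != 0:
                raise RegistryError(
                    f"{self.cause}/{self.sex}: spline must anchor log RR(0)=0")
        if self.form == "constant" and len(self.coefficients) != 1:
            raise RegistryError(f"{self.cause}/{self.sex}: constant form needs one value")


def rr_at(rf: RiskFunction, x, cap: float = DEFAULT_CAP):
    """Evaluate RR at dose x g/day (scalar or array); doses above cap use cap.

    RR(0) = 1 for every form: the constant form applies its value only to
    positive doses (drinker density has no mass at 0).
    """
    scalar = np.isscalar(x)
    x = np.minimum(np.asarray(x, dtype=float), cap)
    if np.any(x < 0):
        raise ValueError("dose must be non-negative")
    if rf.form == "log_linear":
        logrr = np.zeros_like(x)
        for j, beta in enumerate(rf.coefficients, start=1):
            logrr += beta * x ** j
        out = np.exp(logrr)
    elif rf.form == "piecewise_linear_spline":
        logrr = np.interp(x, rf.knots, rf.coefficients)
        out = np.exp(logrr)
    else:  # constant
        out = np.where(x > 0, rf.coefficients[0], 1.0)
    return float(out) if scalar else out


@dataclass
class Registry:
    """Validated collection of cause groups and their risk parameters."""

    causes: dict[str, CauseGroup] = field(default_factory=dict)
    functions: dict[tuple[str, str, str], RiskFunction] = field(default_factory=dict)
    #: per-cause HIV parameters: {"threshold_gpd": float, "rr_nonadherent": {sex: rr}}
    hiv_params: dict[str, dict] = field(default_factory=dict)
    #: per-(cause, sex) injury cell RRs: {"nonbinge": [...], "binge": [...]}
    injury_cells: dict[tuple[str, str], dict[str, list[float]]] = field(default_factory=dict)
    cap: float = DEFAULT_CAP

    def add_cause(self, cause: CauseGroup) -> None:
        if cause.label in self.causes:
            raise RegistryError(f"duplicate cause label {cause.label!r}")
        self.causes[cause.label] = cause

    def add_function(self, rf: RiskFunction) -> None:
        key = (rf.cause, rf.sex, rf.role)
        if key in self.functions:
            raise RegistryError(f"duplicate risk function for {key}")
        self.functions[key] = rf

    def function_for(self, cause: str, sex: str, role: str = ROLE_MAIN) -> RiskFunction:
        try:
            return self.functions[(cause, sex, role)]
        except KeyError:
            raise RegistryError(f"no {role} risk function for {cause!r}/{sex}") from None

    def resolve(self, cause_labels: Iterable[str]) -> None:
        """Check that every mortality cause is computable; raise listing gaps."""
        missing: list[str] = []
        for label in dict.fromkeys(cause_labels):
            if label not in self.causes:
                missing.append(label)
                continue
            method = self.causes[label].method
            for sex in SEXES:
                if method == "chronic" and (label, sex, ROLE_MAIN) not in self.functions:
                    missing.append(f"{label} [{sex} chronic RR]")
                elif method == "ihd":
                    for role in (ROLE_PROTECTIVE, ROLE_DETRIMENTAL):
                        if (label, sex, role) not in self.functions:
                            missing.append(f"{label} [{sex} {role} RR]")
                elif method == "injury" and (label, sex) not in self.injury_cells:
                    missing.append(f"{label} [{sex} injury cells]")
                elif method == "hiv" and label not in self.hiv_params:
                    missing.append(f"{label} [hiv params]")
        if missing:
            raise RegistryError("unresolved causes: " + "; ".join(missing))

    def validate_shapes(self) -> None:
        """RR finite/positive on [0, cap]; protection only where flagged."""
        grid = np.linspace(0.0, self.cap, 301)
        for (cause, sex, role), rf in self.functions.items():
            rr = rr_at(rf, grid, self.cap)
            if not np.all(np.isfinite(rr)) or np.any(rr <= 0):
                raise RegistryError(f"{cause}/{sex}/{role}: RR not finite-positive on [0, cap]")
            protective = bool(np.any(rr < 1.0 - 1e-12))
            if protective and role == ROLE_MAIN and not self.causes[cause].protective_ok:
                raise RegistryError(
                    f"{cause}/{sex}: RR < 1 on part of the domain but the cause "
                    "is not flagged protective_ok")

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        causes = []
        for cg in self.causes.values():
            entry: dict = {"label": cg.label, "icd10": cg.icd10, "bucket": cg.bucket,
                           "method": cg.method, "protective_ok": cg.protective_ok}
            funcs = [rf for rf in self.functions.values() if rf.cause == cg.label]
            if funcs:
                entry["functions"] = [
                    {"sex": rf.sex, "role": rf.role, "form": rf.form,
                     "coefficients": list(rf.coefficients),
                     **({"knots": list(rf.knots)} if rf.knots else {}),
                     "rr_former": rf.rr_former}
                    for rf in funcs]
            if cg.label in self.hiv_params:
                entry["hiv"] = self.hiv_params[cg.label]
            cells = {sex: self.injury_cells[(cg.label, sex)]
                     for sex in SEXES if (cg.label, sex) in self.injury_cells}
            if cells:
                entry["injury_cells"] = cells
            causes.append(entry)
        return {"cap": self.cap, "causes": causes}

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def registry_from_dict(doc: Mapping) -> Registry:
    reg = Registry(cap=float(doc.get("cap", DEFAULT_CAP)))
    for entry in doc.get("causes", []):
        cg = CauseGroup(entry["label"], entry.get("icd10", ""), entry["bucket"],
                        entry["method"], bool(entry.get("protective_ok", False)))
        reg.add_cause(cg)
        for f in entry.get("functions", []):
            reg.add_function(RiskFunction(
                cause=cg.label, sex=f["sex"], form=f["form"],
                coefficients=tuple(float(c) for c in f.get("coefficients", [])),
                knots=tuple(float(k) for k in f.get("knots", [])),
                rr_former=float(f.get("rr_former", 1.0)),
                role=f.get("role", ROLE_MAIN)))
        if "hiv" in entry:
            reg.hiv_params[cg.label] = dict(entry["hiv"])
        for sex, cells in entry.get("injury_cells", {}).items():
            reg.injury_cells[(cg.label, sex)] = {
                "nonbinge": [float(v) for v in cells["nonbinge"]],
                "binge": [float(v) for v in cells["binge"]]}
    reg.validate_shapes()
    return reg


def load_registry(path: str | Path) -> Registry:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise RegistryError(f"registry file {path} is not a mapping")
    return registry_from_dict(doc)


def default_registry() -> Registry:
    """The packaged illustrative registry (synthetic experiments only)."""
    with resources.files("aafburden.data").joinpath("risk_registry.yaml").open() as fh:
        return registry_from_dict(yaml.safe_load(fh))
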
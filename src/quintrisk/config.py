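"""Disease configuration: risk factors, relative risks, vaccines and treatment.

A disease is described by up to four ordered risk factors per outcome
(morbidity and mortality are configured separately), a set of vaccines with
efficacies scaled by the fraction of cases attributable to the targeted
agent, and a treatment efficacy proxied downstream by care-seeking.

Relative risks are marginal risk ratios: the ratio of the outcome
probability at a factor level to the probability at the factor's reference
level (index 0), averaged over the other factors.  The bundled YAML configs
carry the published vaccine and treatment efficacies but only *illustrative*
relative-risk magnitudes; real analyses must supply their own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import yaml

Outcome = Literal["case", "death"]

DISEASES = ("diarrhoea", "pneumonia", "measles")

MAX_FACTORS = 4  # per outcome; larger lattices are computationally intractable
MAX_LEVELS = 3


@dataclass(frozen=True)
class RiskFactorSpec:
    """An ordered risk factor with per-level marginal relative risks.

    Level index 0 is the reference (absent / least severe) level; higher
    indices are more severe.  ``rr_case`` / ``rr_death`` give the relative
    risk of acquiring, respectively dying from, the disease at each level;
    a factor used for only one outcome may leave the other ``None``.
    """

    name: str
    levels: tuple[str, ...]
    rr_case: tuple[float, ...] | None = None
    rr_death: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not (2 <= len(self.levels) <= MAX_LEVELS):
            raise ValueError(
                f"factor {self.name!r}: needs 2-{MAX_LEVELS} levels, got {len(self.levels)}"
            )
        for which in ("case", "death"):
            rr = getattr(self, f"rr_{which}")
            if rr is None:
                continue
            _validate_rr(self.name, which, rr, len(self.levels))

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def rr(self, outcome: Outcome) -> tuple[float, ...]:
        rr = self.rr_case if outcome == "case" else self.rr_death
        if rr is None:
            raise ValueError(f"factor {self.name!r} has no {outcome} relative risks")
        return rr


def _validate_rr(name: str, which: str, rr: Sequence[float], n_levels: int) -> None:
    if len(rr) != n_levels:
        raise ValueError(f"factor {name!r}: rr_{which} length {len(rr)} != {n_levels} levels")
    if rr[0] != 1.0:
        raise ValueError(f"factor {name!r}: rr_{which}[0] must equal 1, got {rr[0]}")
    arr = np.asarray(rr, dtype=float)
    if np.any(arr < 1.0):
        raise ValueError(f"factor {name!r}: rr_{which} values must be >= 1")
    if np.any(np.diff(arr) < 0):
        raise ValueError(f"factor {name!r}: rr_{which} must be nondecreasing with severity")


@dataclass(frozen=True)
class VaccineSpec:
    """A vaccine with efficacy against the targeted agent.

    ``attributable_fraction`` is the proportion of the disease's cases caused
    by the agent the vaccine targets (1.0 for measles vaccine against
    measles); the effective efficacy against all-cause disease is
    ``attributable_fraction * efficacy``.
    """

    name: str
    efficacy: float
    efficacy_ui: tuple[float, float]
    attributable_fraction: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.efficacy_ui
        if not (0.0 <= lo <= self.efficacy <= hi <= 1.0):
            raise ValueError(
                f"vaccine {self.name!r}: need 0 <= ui_low <= efficacy <= ui_high <= 1, "
                f"got {lo}, {self.efficacy}, {hi}"
            )
        if not (0.0 <= self.attributable_fraction <= 1.0):
            raise ValueError(
                f"vaccine {self.name!r}: attributable_fraction must be in [0,1]"
            )


@dataclass(frozen=True)
class TreatmentSpec:
    efficacy: float
    efficacy_ui: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.efficacy_ui
        if not (0.0 <= lo <= self.efficacy <= hi <= 1.0):
            raise ValueError("treatment: need 0 <= ui_low <= efficacy <= ui_high <= 1")


@dataclass(frozen=True)
class DiseaseSpec:
    """Full per-disease configuration."""

    disease: str
    case_factors: tuple[RiskFactorSpec, ...]
    death_factors: tuple[RiskFactorSpec, ...]
    vaccines: tuple[VaccineSpec, ...] = field(default_factory=tuple)
    treatment: TreatmentSpec | None = None

    def __post_init__(self) -> None:
        if self.disease not in DISEASES:
            raise ValueError(f"unknown disease {self.disease!r}; expected one of {DISEASES}")
        for which, factors in (("case", self.case_factors), ("death", self.death_factors)):
            if len(factors) > MAX_FACTORS:
                raise ValueError(
                    f"{self.disease}: at most {MAX_FACTORS} {which} factors allowed, "
                    f"got {len(factors)}"
                )
            for f in factors:
                f.rr(which)  # raises if the outcome's rr vector is missing

    def factors_for(self, outcome: Outcome) -> tuple[RiskFactorSpec, ...]:
        return self.case_factors if outcome == "case" else self.death_factors

    def factor_names(self, outcome: Outcome) -> list[str]:
        return [f.name for f in self.factors_for(outcome)]

    @property
    def all_factor_names(self) -> list[str]:
        names = [f.name for f in self.case_factors]
        names += [f.name for f in self.death_factors if f.name not in names]
        return names


def _factor_from_dict(d: dict, which: Outcome) -> RiskFactorSpec:
    rr = tuple(float(x) for x in d["rr"])
    if rr and rr[0] != 1.0:
        # the reference level is 1 by definition; force it before validation
        rr = (1.0,) + rr[1:]
    kwargs = {"rr_case": rr} if which == "case" else {"rr_death": rr}
    return RiskFactorSpec(name=d["name"], levels=tuple(d["levels"]), **kwargs)


def load_disease_config(path: str | Path) -> DiseaseSpec:
    """Load and validate a disease configuration from YAML (or JSON).

    Expected keys: ``disease``, ``case_factors``, ``death_factors`` (lists of
    ``{name, levels, rr}``), ``vaccines`` (list of ``{name, efficacy, ui,
    attributable_fraction}``) and ``treatment`` (``{efficacy, ui}``).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        case_factors = tuple(_factor_from_dict(d, "case") for d in raw["case_factors"])
        death_factors = tuple(_factor_from_dict(d, "death") for d in raw["death_factors"])
        vaccines = tuple(
            VaccineSpec(
                name=v["name"],
                efficacy=float(v["efficacy"]),
                efficacy_ui=tuple(float(x) for x in v["ui"]),
                attributable_fraction=float(v.get("attributable_fraction", 1.0)),
            )
            for v in raw.get("vaccines", [])
        )
        treatment = None
        if "treatment" in raw and raw["treatment"] is not None:
            t = raw["treatment"]
            treatment = TreatmentSpec(
                efficacy=float(t["efficacy"]),
                efficacy_ui=tuple(float(x) for x in t["ui"]),
            )
        return DiseaseSpec(
            disease=raw["disease"],
            case_factors=case_factors,
            death_factors=death_factors,
            vaccines=vaccines,
            treatment=treatment,
        )
    except KeyError as exc:
        raise ValueError(f"disease config {path}: missing key {exc}") from exc


def bundled_config_path(disease: str) -> Path:
    """Path to the bundled illustrative configuration for a disease."""
    if disease not in DISEASES:
        raise ValueError(f"unknown disease {disease!r}")
    ref = resources.files("quintrisk") / "configs" / f"{disease}.yaml"
    return Path(str(ref))


def load_bundled_config(disease: str) -> DiseaseSpec:
    return load_disease_config(bundled_config_path(disease))
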
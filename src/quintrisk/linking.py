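"""Linking morbidity and mortality: three approaches to quintile deaths.

A. direct: fit the ensemble on the mortality risk factors and adjust for
   immunization and treatment coverage.
B. case-risk-based: fit on the morbidity risk factors, then apply both
   immunization and treatment coverage; reported but excluded from the
   headline average.
C. extrapolated: take the expected cases (immunization-adjusted by
   default) and scale them by the quintile under-5 mortality differential.

The headline ("main analysis") gradient is the renormalized average of the
normalized gradients from approaches A and C.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DiseaseSpec, Outcome
from .coverage import treatment_multipliers, vaccine_multipliers
from .io import ChildTable, CoverageTable, U5MRTable
from .linsys import add_anchor, build_marginal_equations
from .optimize import SolutionEnsemble, sample_ensemble
from .profiles import ProfileTable, dominance_order, enumerate_profiles, tabulate_counts
from .report import QuintileGradient, main_analysis, normalize_gradient, quintile_risks

__all__ = [
    "QuintileDeaths",
    "FittedOutcome",
    "fit_outcome",
    "deaths_direct",
    "deaths_from_case_risks",
    "deaths_extrapolated",
    "expected_cases",
    "gradient_from_deaths",
    "main_analysis",
]

DEFAULT_ANCHOR_RISK = 0.05


@dataclass
class QuintileDeaths:
    """Expected deaths per quintile, per ensemble replicate."""

    replicates: np.ndarray  # K x 5
    pop: np.ndarray  # weighted children per quintile
    approach: str  # 'A', 'B' or 'C'

    @property
    def deaths(self) -> np.ndarray:
        """Across-replicate mean deaths per quintile."""
        return self.replicates.mean(axis=0)


@dataclass
class FittedOutcome:
    """An ensemble fitted for one outcome, with its profile table."""

    profiles: ProfileTable
    ensemble: SolutionEnsemble
    pop: np.ndarray


def fit_outcome(
    spec: DiseaseSpec,
    children: ChildTable,
    outcome: Outcome,
    k: int = 1000,
    seed: int = 0,
    *,
    anchor_risk: float | None = DEFAULT_ANCHOR_RISK,
) -> FittedOutcome:
    """Run profiles -> linear system -> constrained ensemble for one outcome."""
    factors = spec.factors_for(outcome)
    sub = children.restrict([f.name for f in factors])
    profiles = tabulate_counts(sub, enumerate_profiles(factors))
    order = dominance_order(profiles)
    system = build_marginal_equations(profiles, outcome)
    if anchor_risk is not None:
        system = add_anchor(system, anchor_risk)
    ensemble = sample_ensemble(system, order, k=k, seed=seed)
    return FittedOutcome(profiles, ensemble, sub.quintile_weights())


def _sample_efficacies(
    spec: DiseaseSpec, k: int, rng: np.random.Generator
) -> tuple[list[dict[str, float]], np.ndarray]:
    """Per-replicate vaccine and treatment efficacies from Beta distributions
    moment-matched to the configured 95% uncertainty intervals."""

    def draw(mean: float, lo: float, hi: float) -> np.ndarray:
        sd = (hi - lo) / 3.92
        var = min(sd * sd, 0.999 * mean * (1 - mean)) if 0 < mean < 1 else 0.0
        if var <= 0:
            return np.full(k, mean)
        nu = mean * (1 - mean) / var - 1.0
        return rng.beta(mean * nu, (1 - mean) * nu, size=k)

    per_vaccine = {
        v.name: draw(v.efficacy, *v.efficacy_ui) for v in spec.vaccines
    }
    overrides = [
        {name: float(vals[r]) for name, vals in per_vaccine.items()} for r in range(k)
    ]
    if spec.treatment is not None:
        treat = draw(spec.treatment.efficacy, *spec.treatment.efficacy_ui)
    else:
        treat = np.zeros(k)
    return overrides, treat


def _replicate_deaths(
    fitted: FittedOutcome,
    spec: DiseaseSpec,
    coverage: CoverageTable,
    *,
    immunization: bool,
    treatment: bool,
    sample_efficacy_ui: bool = False,
    seed: int = 0,
) -> np.ndarray:
    """K x 5 expected outcome counts, coverage-adjusted per replicate."""
    p = fitted.ensemble.solutions  # K x J
    counts = fitted.profiles.counts  # J x 5
    base = p @ counts  # K x 5 expected outcomes before coverage
    k = base.shape[0]
    if not (immunization or treatment):
        return base
    if sample_efficacy_ui:
        rng = np.random.default_rng([seed, 7919])
        overrides, treat_eff = _sample_efficacies(spec, k, rng)
        mult = np.ones_like(base)
        for r in range(k):
            if immunization:
                mult[r] *= vaccine_multipliers(
                    spec.vaccines, coverage, efficacy_overrides=overrides[r]
                )
            if treatment:
                mult[r] *= treatment_multipliers(
                    spec, coverage, efficacy_override=float(treat_eff[r])
                )
        return base * mult
    mult = np.ones(5)
    if immunization:
        mult = mult * vaccine_multipliers(spec.vaccines, coverage)
    if treatment:
        mult = mult * treatment_multipliers(spec, coverage)
    return base * mult[None, :]


def deaths_direct(
    spec: DiseaseSpec,
    children: ChildTable,
    coverage: CoverageTable,
    k: int = 1000,
    seed: int = 0,
    *,
    anchor_risk: float | None = DEFAULT_ANCHOR_RISK,
    sample_efficacy_ui: bool = False,
) -> QuintileDeaths:
    """Approach A: deaths computed independently of cases, from the
    mortality risk factors, with immunization and treatment applied."""
    fitted = fit_outcome(spec, children, "death", k=k, seed=seed, anchor_risk=anchor_risk)
    reps = _replicate_deaths(
        fitted, spec, coverage,
        immunization=True, treatment=True,
        sample_efficacy_ui=sample_efficacy_ui, seed=seed,
    )
    return QuintileDeaths(reps, fitted.pop, approach="A")


def deaths_from_case_risks(
    spec: DiseaseSpec,
    children: ChildTable,
    coverage: CoverageTable,
    k: int = 1000,
    seed: int = 0,
    *,
    anchor_risk: float | None = DEFAULT_ANCHOR_RISK,
    sample_efficacy_ui: bool = False,
) -> QuintileDeaths:
    """Approach B: fit on the morbidity risk factors, then apply both
    immunization and treatment coverage."""
    fitted = fit_outcome(spec, children, "case", k=k, seed=seed, anchor_risk=anchor_risk)
    reps = _replicate_deaths(
        fitted, spec, coverage,
        immunization=True, treatment=True,
        sample_efficacy_ui=sample_efficacy_ui, seed=seed,
    )
    return QuintileDeaths(reps, fitted.pop, approach="B")


def expected_cases(
    spec: DiseaseSpec,
    children: ChildTable,
    coverage: CoverageTable,
    k: int = 1000,
    seed: int = 0,
    *,
    anchor_risk: float | None = DEFAULT_ANCHOR_RISK,
    adjusted: bool = True,
    sample_efficacy_ui: bool = False,
) -> QuintileDeaths:
    """Expected cases per quintile from the morbidity ensemble.

    With ``adjusted`` (default) immunization coverage is applied; treatment
    never is, since treatment averts death, not disease.
    """
    fitted = fit_outcome(spec, children, "case", k=k, seed=seed, anchor_risk=anchor_risk)
    reps = _replicate_deaths(
        fitted, spec, coverage,
        immunization=adjusted, treatment=False,
        sample_efficacy_ui=sample_efficacy_ui and adjusted, seed=seed,
    )
    return QuintileDeaths(reps, fitted.pop, approach="cases")


def deaths_extrapolated(cases: QuintileDeaths, u5mr: U5MRTable) -> QuintileDeaths:
    """Approach C: scale expected cases by the under-5 mortality differential.

    deaths[q] = cases[q] * u5mr[q] / mean(u5mr); the arbitrary overall scale
    cancels in the normalized gradient.
    """
    rates = u5mr.u5mr
    weights = rates / rates.mean()
    reps = cases.replicates * weights[None, :]
    return QuintileDeaths(reps, cases.pop, approach="C")


def gradient_from_deaths(qd: QuintileDeaths) -> QuintileGradient:
    """Normalized quintile gradient from per-replicate deaths."""
    return normalize_gradient(quintile_risks(qd.replicates, qd.pop))
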
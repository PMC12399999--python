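"""DHS-like synthetic microdata with known ground truth.

The generator emulates the structure of Demographic and Health Survey child
records: five wealth quintiles of roughly equal size, a handful of ordered
risk factors (nutrition, sanitation) whose prevalence worsens toward the
poorer quintiles, immunization coverage and care-seeking that improve with
wealth, and an under-5 mortality differential.  Outcome ground truth is a
multiplicative risk model: profile j has probability

    p[j] = p0 * prod_f rr[f][level_f(j)].

When factor levels are assigned independently of one another the
multiplicative truth satisfies the marginal relative-risk equations in
expectation, which makes end-to-end parameter recovery testable.  A
quintile-graded prevalence induces correlation between factors (both track
wealth), which is exactly the inconsistent regime the error-minimizing
estimation is designed for.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import DiseaseSpec, Outcome, RiskFactorSpec, TreatmentSpec, VaccineSpec
from .io import N_QUINTILES, ChildTable, CoverageTable, U5MRTable
from .profiles import ProfileTable, enumerate_profiles


@dataclass
class ScenarioSpec:
    """A fully specified synthetic study scenario.

    ``prevalence`` maps factor name to a 5 x L matrix: level probabilities
    per quintile (rows sum to 1).  Coverage and care-seeking follow the
    linear form clamp(base + slope * (q - 3), 0, 1), so a positive slope
    means richer quintiles are better covered.
    """

    n_children: int
    factors: tuple[RiskFactorSpec, ...]
    prevalence: dict[str, np.ndarray]
    vaccine_coverage: dict[str, tuple[float, float]] = field(default_factory=dict)
    careseek: dict[str, tuple[float, float]] = field(default_factory=dict)
    u5mr: np.ndarray = field(default_factory=lambda: np.full(N_QUINTILES, 75.0))
    p0_case: float = 0.15
    p0_death: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        self.u5mr = np.asarray(self.u5mr, dtype=float)
        for f in self.factors:
            if f.name not in self.prevalence:
                raise ValueError(f"scenario: no prevalence given for factor {f.name!r}")
            prev = np.asarray(self.prevalence[f.name], dtype=float)
            if prev.shape != (N_QUINTILES, f.n_levels):
                raise ValueError(
                    f"scenario: prevalence for {f.name!r} must be 5 x {f.n_levels}"
                )
            if np.any(prev < 0) or not np.allclose(prev.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(
                    f"scenario: prevalence rows for {f.name!r} must be nonnegative and sum to 1"
                )
            self.prevalence[f.name] = prev
        for outcome in ("case", "death"):
            p = true_profile_probabilities(self, outcome)
            if np.any(p > 1.0):
                raise ValueError(
                    f"scenario: multiplicative {outcome} truth exceeds 1 for the most "
                    "severe profile; lower p0 or the relative risks"
                )

    def disease_spec(
        self,
        disease: str = "measles",
        vaccines: tuple[VaccineSpec, ...] | None = None,
        treatment: TreatmentSpec | None = None,
    ) -> DiseaseSpec:
        """A DiseaseSpec using this scenario's factors for both outcomes."""
        if vaccines is None:
            vaccines = (VaccineSpec("mcv", 0.85, (0.83, 0.87), 1.0),)
        if treatment is None:
            treatment = TreatmentSpec(0.62, (0.52, 0.82))
        return DiseaseSpec(
            disease=disease,
            case_factors=self.factors,
            death_factors=self.factors,
            vaccines=vaccines,
            treatment=treatment,
        )


def generate_children(spec: ScenarioSpec) -> ChildTable:
    """Draw the child table: uniform quintiles, factor levels independent
    across factors within quintile, unit weights.  Deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    q = rng.integers(1, N_QUINTILES + 1, size=spec.n_children)
    data = {"quintile": q}
    for f in spec.factors:
        prev = spec.prevalence[f.name]
        levels = np.empty(spec.n_children, dtype=int)
        for qi in range(1, N_QUINTILES + 1):
            mask = q == qi
            levels[mask] = rng.choice(f.n_levels, size=int(mask.sum()), p=prev[qi - 1])
        data[f.name] = levels
    data["weight"] = np.ones(spec.n_children)
    return ChildTable(pd.DataFrame(data), tuple(f.name for f in spec.factors))


def true_profile_probabilities(spec: ScenarioSpec, outcome: Outcome) -> np.ndarray:
    """Ground-truth p[j] = p0 * prod_f rr[f][level], in enumeration order."""
    profiles = enumerate_profiles(spec.factors)
    p0 = spec.p0_case if outcome == "case" else spec.p0_death
    rr = profiles.factor_rr_matrix(outcome)
    p = np.full(profiles.n_profiles, p0)
    for k in range(len(spec.factors)):
        p *= rr[k][profiles.levels[:, k]]
    if np.any(p > 1.0):
        raise ValueError("multiplicative truth exceeds 1")
    return p


def true_overall_risk(spec: ScenarioSpec, profiles: ProfileTable, outcome: Outcome) -> float:
    """Count-weighted mean of the true profile probabilities: the natural
    anchor value for parameter-recovery experiments."""
    p = true_profile_probabilities(spec, outcome)
    n = profiles.totals
    return float(n @ p / n.sum())


def generate_tables(spec: ScenarioSpec) -> tuple[CoverageTable, U5MRTable]:
    """Coverage and under-5 mortality tables from the linear gradients."""
    q = np.arange(1, N_QUINTILES + 1)

    def ramp(base: float, slope: float) -> np.ndarray:
        return np.clip(base + slope * (q - 3), 0.0, 1.0)

    coverage = CoverageTable(
        vaccine_coverage={n: ramp(*bs) for n, bs in spec.vaccine_coverage.items()},
        careseek={n: ramp(*bs) for n, bs in spec.careseek.items()},
    )
    return coverage, U5MRTable(spec.u5mr)


def linear_prevalence(poorest: list[float], wealthiest: list[float]) -> np.ndarray:
    """5 x L prevalence interpolating linearly from quintile I to V."""
    lo = np.asarray(poorest, dtype=float)
    hi = np.asarray(wealthiest, dtype=float)
    t = np.linspace(0.0, 1.0, N_QUINTILES)[:, None]
    return (1 - t) * lo[None, :] + t * hi[None, :]


_STUNTING = RiskFactorSpec(
    "stunting", ("none", "moderate", "severe"),
    rr_case=(1.0, 1.30, 1.60), rr_death=(1.0, 1.35, 1.70),
)
_WASTING = RiskFactorSpec(
    "wasting", ("none", "moderate", "severe"),
    rr_case=(1.0, 1.25, 1.50), rr_death=(1.0, 1.40, 1.80),
)
_SANITATION = RiskFactorSpec(
    "unsafe_sanitation", ("improved", "unimproved"),
    rr_case=(1.0, 1.40), rr_death=(1.0, 1.40),
)


def consistent_scenario(n_children: int = 50_000, seed: int = 0) -> ScenarioSpec:
    """The zero-residual regime: factor levels independent of wealth.

    Prevalence is identical across quintiles, so factors are mutually
    independent and the multiplicative truth satisfies the marginal
    equations in expectation.  Moderate relative risks keep the
    non-uniqueness face of the minimizer small relative to the truth, which
    is the regime where per-profile parameter recovery is meaningful.
    """
    flat = lambda probs: np.tile(np.asarray(probs, float), (N_QUINTILES, 1))
    return ScenarioSpec(
        n_children=n_children,
        factors=(_STUNTING, _WASTING),
        prevalence={
            "stunting": flat([0.55, 0.30, 0.15]),
            "wasting": flat([0.65, 0.25, 0.10]),
        },
        vaccine_coverage={"mcv": (0.65, 0.0)},
        careseek={"diarrhoea": (0.55, 0.0), "ari": (0.60, 0.0)},
        u5mr=np.full(N_QUINTILES, 80.0),
        p0_case=0.15,
        p0_death=0.02,
        seed=seed,
    )


def gradient_scenario(n_children: int = 20_000, seed: int = 0) -> ScenarioSpec:
    """A wealth-graded scenario disadvantaging the poorer quintiles.

    Risk-factor prevalence worsens, and immunization coverage and
    care-seeking fall, toward quintile I; the under-5 mortality differential
    runs the same way.  Used for the emergent-monotonicity checks.
    """
    return ScenarioSpec(
        n_children=n_children,
        factors=(_STUNTING, _WASTING),
        prevalence={
            "stunting": linear_prevalence([0.35, 0.35, 0.30], [0.70, 0.22, 0.08]),
            "wasting": linear_prevalence([0.45, 0.35, 0.20], [0.78, 0.16, 0.06]),
        },
        vaccine_coverage={"mcv": (0.60, 0.08)},
        careseek={"diarrhoea": (0.50, 0.07), "ari": (0.55, 0.07)},
        u5mr=np.array([110.0, 95.0, 82.0, 70.0, 58.0]),
        p0_case=0.15,
        p0_death=0.02,
        seed=seed,
    )


def three_factor_scenario(n_children: int = 20_000, seed: int = 0) -> ScenarioSpec:
    """A larger lattice (3 x 3 x 2 = 18 profiles) with wealth grading."""
    return ScenarioSpec(
        n_children=n_children,
        factors=(_STUNTING, _WASTING, _SANITATION),
        prevalence={
            "stunting": linear_prevalence([0.35, 0.35, 0.30], [0.70, 0.22, 0.08]),
            "wasting": linear_prevalence([0.45, 0.35, 0.20], [0.78, 0.16, 0.06]),
            "unsafe_sanitation": linear_prevalence([0.30, 0.70], [0.85, 0.15]),
        },
        vaccine_coverage={"mcv": (0.60, 0.08)},
        careseek={"diarrhoea": (0.50, 0.07), "ari": (0.55, 0.07)},
        u5mr=np.array([110.0, 95.0, 82.0, 70.0, 58.0]),
        p0_case=0.12,
        p0_death=0.015,
        seed=seed,
    )


def write_scenario_files(spec: ScenarioSpec, outdir: str | Path) -> dict[str, Path]:
    """Write microdata, coverage and u5mr CSVs plus a ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    children = generate_children(spec)
    coverage, u5mr = generate_tables(spec)

    paths = {
        "microdata": outdir / "microdata.csv",
        "coverage": outdir / "coverage.csv",
        "u5mr": outdir / "u5mr.csv",
        "truth": outdir / "truth.json",
    }
    children.data.to_csv(paths["microdata"], index=False)

    cov_df = pd.DataFrame({"quintile": range(1, N_QUINTILES + 1)})
    for name, arr in coverage.vaccine_coverage.items():
        cov_df[f"{name}_coverage"] = arr
    for kind, arr in coverage.careseek.items():
        cov_df[f"careseek_{kind}"] = arr
    cov_df.to_csv(paths["coverage"], index=False, float_format="%.6f")

    pd.DataFrame(
        {"quintile": range(1, N_QUINTILES + 1), "u5mr_per_1000": u5mr.u5mr}
    ).to_csv(paths["u5mr"], index=False, float_format="%.6f")

    truth = {
        "seed": spec.seed,
        "n_children": spec.n_children,
        "p0_case": spec.p0_case,
        "p0_death": spec.p0_death,
        "factors": [
            {"name": f.name, "levels": list(f.levels),
             "rr_case": list(f.rr("case")), "rr_death": list(f.rr("death"))}
            for f in spec.factors
        ],
        "true_p_case": true_profile_probabilities(spec, "case").tolist(),
        "true_p_death": true_profile_probabilities(spec, "death").tolist(),
    }
    paths["truth"].write_text(json.dumps(truth, indent=2))
    return paths
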
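"""Quintile-specific coverage adjustment of expected outcomes.

Immunization reduces expected cases and deaths by the factor

    prod_v (1 - AF_v * efficacy_v * coverage_{v,q})

where AF_v is the fraction of the disease's cases attributable to the agent
vaccine v targets.  Treatment (proxied by care-seeking) further reduces
expected deaths only, by 1 - treatment_efficacy * careseek_q.  Vaccines not
in a country's programme enter with coverage zero, i.e. no reduction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import DiseaseSpec, Outcome, VaccineSpec
from .io import N_QUINTILES, CoverageTable, resolve_treatment_coverage
from .profiles import ProfileTable

# "none", "immunization", "treatment" or "immunization+treatment"
Stage = str


@dataclass
class AdjustedOutcomeTable:
    """Expected outcome counts per profile and quintile after adjustment."""

    expected: np.ndarray  # J x 5
    stage: Stage


def vaccine_multiplier(
    vaccines: Sequence[VaccineSpec],
    coverage: CoverageTable,
    q: int,
    *,
    efficacy_overrides: dict[str, float] | None = None,
) -> float:
    """Multiplicative reduction of expected outcomes in quintile q (1..5)."""
    mult = 1.0
    for v in vaccines:
        eff = (efficacy_overrides or {}).get(v.name, v.efficacy)
        cov = float(coverage.coverage_for(v.name)[q - 1])
        mult *= 1.0 - v.attributable_fraction * eff * cov
    return mult


def vaccine_multipliers(
    vaccines: Sequence[VaccineSpec],
    coverage: CoverageTable,
    *,
    efficacy_overrides: dict[str, float] | None = None,
) -> np.ndarray:
    """Vectorized :func:`vaccine_multiplier` over the five quintiles."""
    return np.array(
        [
            vaccine_multiplier(vaccines, coverage, q, efficacy_overrides=efficacy_overrides)
            for q in range(1, N_QUINTILES + 1)
        ]
    )


def treatment_multiplier(treatment_efficacy: float, careseek_q: float) -> float:
    """Reduction of expected deaths from treatment reached via care-seeking."""
    if not (0.0 <= treatment_efficacy <= 1.0 and 0.0 <= careseek_q <= 1.0):
        raise ValueError("treatment efficacy and care-seeking must be in [0,1]")
    return 1.0 - treatment_efficacy * careseek_q


def treatment_multipliers(
    spec: DiseaseSpec,
    coverage: CoverageTable,
    *,
    efficacy_override: float | None = None,
) -> np.ndarray:
    """Per-quintile treatment multipliers using the disease's care-seeking proxy."""
    eff = spec.treatment.efficacy if efficacy_override is None else efficacy_override
    careseek = resolve_treatment_coverage(coverage, spec.disease)
    return np.array([treatment_multiplier(eff, c) for c in careseek])


def apply_adjustments(
    profiles: ProfileTable,
    p: np.ndarray,
    spec: DiseaseSpec,
    coverage: CoverageTable,
    outcome: Outcome,
    *,
    immunization: bool = True,
    treatment: bool | None = None,
) -> AdjustedOutcomeTable:
    """Expected outcome counts n[j][q] * p[j], scaled by coverage multipliers.

    Immunization applies to both cases and deaths; treatment applies to
    deaths only (it averts death given disease), unless overridden.
    """
    if profiles.counts is None:
        raise ValueError("profile counts must be tabulated")
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must be in [0,1]")
    if treatment is None:
        treatment = outcome == "death"
    expected = profiles.counts * p[:, None]
    stages = []
    if immunization:
        expected = expected * vaccine_multipliers(spec.vaccines, coverage)[None, :]
        stages.append("immunization")
    if treatment:
        if spec.treatment is None:
            raise ValueError(f"{spec.disease}: no treatment block configured")
        expected = expected * treatment_multipliers(spec, coverage)[None, :]
        stages.append("treatment")
    return AdjustedOutcomeTable(expected=expected, stage="+".join(stages) or "none")
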
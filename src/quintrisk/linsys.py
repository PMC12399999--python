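"""The marginal relative-risk linear system.

Unknowns are per-profile outcome probabilities p[j].  For every factor f
and non-reference severity level l, one equation requires the weighted mean
risk among children at level l of f to equal rr[f][l] times the weighted
mean risk among children at the reference level of f:

    (1/N_{f,l}) sum_{j: lev_f(j)=l} n_j p_j
        - rr[f][l] (1/N_{f,0}) sum_{j: lev_f(j)=0} n_j p_j  =  0

where N_{f,l} is the weighted child count at level l of f.  Group means are
used (rather than raw count sums) so every equation is dimensionless and
equations for unbalanced factors carry comparable weight; multiplying all
counts by a constant leaves residuals unchanged.

An optional anchor equation fixes the overall outcome scale,
(1/N) sum_j n_j p_j = overall_risk.  The normalized quintile gradients
reported downstream are invariant to the anchor value as long as no
probability binds at the upper box bound.

With several factors the system is generically underdetermined and, on real
data, inconsistent: estimation minimizes the sum of squared residuals over
the monotonicity-constrained box (see :mod:`quintrisk.optimize`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import Outcome
from .profiles import ProfileTable

logger = logging.getLogger("quintrisk")

ANCHOR_LABEL = "anchor"


@dataclass(frozen=True)
class LinearSystem:
    """Pre-scaled equations A p = b over per-profile probabilities."""

    a: np.ndarray  # E x J
    b: np.ndarray  # E
    labels: tuple[object, ...]  # (factor, level) per marginal row, or "anchor"
    totals: np.ndarray  # weighted count per profile, used by the anchor

    @property
    def n_equations(self) -> int:
        return self.a.shape[0]

    @property
    def n_profiles(self) -> int:
        return self.a.shape[1]

    @property
    def has_anchor(self) -> bool:
        return ANCHOR_LABEL in self.labels

    @property
    def anchor_value(self) -> float | None:
        """The anchored overall risk, or None for homogeneous systems."""
        if not self.has_anchor:
            return None
        return float(self.b[self.labels.index(ANCHOR_LABEL)])


def build_marginal_equations(
    profiles: ProfileTable, outcome: Outcome = "case"
) -> LinearSystem:
    """One group-mean equation per factor and non-reference level.

    Equations whose level group (or reference group) is empty are omitted
    with a log message; an entirely empty system is an error.
    """
    if profiles.counts is None:
        raise ValueError("profile counts must be tabulated before building equations")
    n = profiles.totals
    lev = profiles.levels
    rr_per_factor = profiles.factor_rr_matrix(outcome)
    rows, labels = [], []
    for k, factor in enumerate(profiles.factors):
        rr = rr_per_factor[k]
        ref_mask = lev[:, k] == 0
        n_ref = float(n[ref_mask].sum())
        for level in range(1, factor.n_levels):
            grp_mask = lev[:, k] == level
            n_grp = float(n[grp_mask].sum())
            if n_grp == 0.0 or n_ref == 0.0:
                logger.info(
                    "omitting equation for %s level %d: empty group (n_level=%g, n_ref=%g)",
                    factor.name, level, n_grp, n_ref,
                )
                continue
            row = np.zeros(profiles.n_profiles)
            row[grp_mask] = n[grp_mask] / n_grp
            row[ref_mask] = -rr[level] * n[ref_mask] / n_ref
            rows.append(row)
            labels.append((factor.name, level))
    if not rows:
        raise ValueError("system empty: every marginal equation had an empty group")
    return LinearSystem(
        a=np.array(rows),
        b=np.zeros(len(rows)),
        labels=tuple(labels),
        totals=np.asarray(n, dtype=float),
    )


def add_anchor(system: LinearSystem, overall_risk: float) -> LinearSystem:
    """Append the scale-fixing equation mean(p weighted by n) = overall_risk."""
    if not (0.0 < overall_risk < 1.0):
        raise ValueError(f"overall_risk must be in (0,1), got {overall_risk}")
    if system.has_anchor:
        raise ValueError("anchor already present")
    total = float(system.totals.sum())
    row = (system.totals / total)[None, :]
    return LinearSystem(
        a=np.vstack([system.a, row]),
        b=np.append(system.b, overall_risk),
        labels=system.labels + (ANCHOR_LABEL,),
        totals=system.totals,
    )


def residual_objective(system: LinearSystem, p: np.ndarray) -> float:
    """Sum of squared residuals of the pre-scaled system at p."""
    p = np.asarray(p, dtype=float)
    if p.shape != (system.n_profiles,):
        raise ValueError(
            f"probability vector has shape {p.shape}, expected ({system.n_profiles},)"
        )
    r = system.a @ p - system.b
    return float(r @ r)


def implied_marginal_rr(profiles: ProfileTable, p: np.ndarray) -> dict[tuple[str, int], float]:
    """Marginal relative risks implied by a probability vector.

    For each factor and non-reference level, the ratio of the weighted mean
    risk in that level group to the reference group.  Used to check that a
    fitted solution reproduces the configured relative risks.
    """
    n = profiles.totals
    lev = profiles.levels
    out: dict[tuple[str, int], float] = {}
    for k, factor in enumerate(profiles.factors):
        ref = lev[:, k] == 0
        denom = float(n[ref] @ p[ref]) / float(n[ref].sum())
        for level in range(1, factor.n_levels):
            grp = lev[:, k] == level
            if n[grp].sum() == 0 or denom == 0.0:
                continue
            num = float(n[grp] @ p[grp]) / float(n[grp].sum())
            out[(factor.name, level)] = num / denom
    return out
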
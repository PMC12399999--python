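"""Ensemble sampling of monotonicity-constrained error minimizers.

The residual objective is a convex quadratic, but the marginal system is
generically underdetermined, so the minimizer is a face of the constraint
polytope rather than a point.  Following the estimation procedure this
module draws many random admissible starting points, runs a local
constrained minimization from each, and keeps the solutions whose objective
lies within a small relative window of the best found.  The spread of the
resulting ensemble expresses the non-uniqueness of the minimizers and feeds
the uncertainty intervals reported downstream.

Randomness is fully reproducible: a master seed plus the restart counter
determine every start.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize as sp_opt

from .linsys import LinearSystem, residual_objective
from .profiles import DominanceOrder

DOMINANCE_TOL = 1e-9
ACCEPTANCE_REL_WINDOW = 0.01
DEFAULT_P_CAP = 0.5  # start cap for homogeneous (unanchored) systems
CANONICAL_ANCHOR = 0.05
# Random starts are uniform on [0, 3*anchor].  The multiple was calibrated
# on synthetic consistent scenarios (multiplicative truth, independent
# factors) so the ensemble mean is approximately unbiased for the true
# per-profile probabilities; smaller or larger multiples bias the mean
# down, respectively up, along the non-unique minimizer face.
START_CAP_ANCHOR_MULTIPLE = 3.0


@dataclass
class SolutionEnsemble:
    """K accepted probability vectors with objectives and restart seeds."""

    solutions: np.ndarray  # K x J
    objectives: np.ndarray  # K
    seeds: np.ndarray  # K restart indices (with the master seed they replay a run)
    acceptance_rate: float = 1.0

    @property
    def k(self) -> int:
        return self.solutions.shape[0]

    def summary(self) -> dict[str, np.ndarray]:
        return summarize_ensemble(self)


def monotone_rearrange(p: np.ndarray, order: DominanceOrder) -> np.ndarray:
    """Rearrange a vector to satisfy the dominance constraints.

    Sweeps the cover edges in a fixed order (ascending profile index pairs);
    each violated edge (a dominates b but p[a] < p[b]) replaces both values
    by their midpoint.  Sweeps repeat until no violation remains; an
    already-monotone input is returned unchanged.  Values stay within the
    convex hull of the input, so box bounds are preserved.

    On chains the midpoint iteration contracts violations geometrically and
    terminates exactly once neighbouring values quantize to the same float,
    which takes on the order of the 53-bit mantissa per lattice level; the
    sweep cap is sized accordingly.
    """
    p = np.asarray(p, dtype=float).copy()
    edges = order.edges
    max_sweeps = max(64 * order.n_profiles, 256)
    for _ in range(max_sweeps):
        changed = False
        for a, b in edges:
            if p[a] < p[b]:
                mid = 0.5 * (p[a] + p[b])
                p[a] = mid
                p[b] = mid
                changed = True
        if not changed:
            return p
    raise RuntimeError(
        f"monotone rearrangement failed to settle within {max_sweeps} sweeps"
    )


def is_feasible(p: np.ndarray, order: DominanceOrder, tol: float = DOMINANCE_TOL) -> bool:
    """Exhaustive dominance check over the full comparability relation."""
    p = np.asarray(p, dtype=float)
    if np.any(p < -tol) or np.any(p > 1 + tol):
        return False
    return all(p[a] >= p[b] - tol for a, b in order.comparable_pairs())


def solve_once(
    system: LinearSystem,
    order: DominanceOrder,
    seed: int,
    *,
    master_seed: int | None = None,
    p_cap: float | None = None,
    maxiter: int = 300,
) -> tuple[np.ndarray | None, float]:
    """One random-restart constrained minimization.

    Draws a uniform start in [0, p_cap]^J, rearranges it onto the monotone
    cone, then minimizes the residual objective subject to the box [0,1] and
    the dominance inequalities (SLSQP with analytic gradients).  Returns
    ``(None, inf)`` when the solver fails to converge or the result is
    infeasible; such restarts are excluded from the ensemble.

    Anchored systems are solved in canonical units: the problem is rescaled
    so the anchor equals 0.05 (the marginal equations are homogeneous, so
    only the anchor row and the box bound change), solved there, and the
    solution scaled back.  Both the random starts and the solver path are
    then identical for every anchor value, which makes the normalized
    gradients exactly invariant to the anchor as long as no coordinate
    binds at the upper box bound.
    """
    key = [seed] if master_seed is None else [master_seed, seed]
    rng = np.random.default_rng(key)

    anchor = system.anchor_value
    scale = 1.0 if anchor is None else anchor / CANONICAL_ANCHOR
    a = system.a
    b = system.b / scale  # homogeneous rows have b=0; the anchor becomes 0.05
    upper = 1.0 / scale  # z <= 1/scale  <=>  p = scale*z <= 1

    if p_cap is not None:
        cap = p_cap / scale
    elif anchor is None:
        cap = DEFAULT_P_CAP
    else:
        cap = START_CAP_ANCHOR_MULTIPLE * CANONICAL_ANCHOR
    x0 = monotone_rearrange(
        np.minimum(cap, upper) * rng.uniform(0.0, 1.0, system.n_profiles), order
    )

    def fun(p: np.ndarray) -> float:
        r = a @ p - b
        return float(r @ r)

    def jac(p: np.ndarray) -> np.ndarray:
        return 2.0 * (a.T @ (a @ p - b))

    d = order.edge_matrix()
    constraints = []
    if d.shape[0]:
        constraints.append({"type": "ineq", "fun": lambda p: d @ p, "jac": lambda p: d})
    # First pass without the upper box bound: the relaxed problem is exactly
    # scale-invariant in the anchor.  Only when a coordinate leaves the box
    # (the regime where anchor invariance genuinely breaks) re-solve with it.
    opts = {"maxiter": maxiter, "ftol": 1e-14}
    res = sp_opt.minimize(
        fun, x0, jac=jac, method="SLSQP",
        bounds=[(0.0, None)] * system.n_profiles,
        constraints=constraints, options=opts,
    )
    if np.all(np.isfinite(res.x)) and np.max(res.x) > upper + 1e-12:
        res = sp_opt.minimize(
            fun, x0, jac=jac, method="SLSQP",
            bounds=[(0.0, upper)] * system.n_profiles,
            constraints=constraints, options=opts,
        )
    if not np.all(np.isfinite(res.x)):
        return None, np.inf
    p = np.clip(scale * res.x, 0.0, 1.0)
    # solver status flags can be noisy near degenerate faces; judge the
    # iterate on feasibility (here) and objective (acceptance window) instead
    if not is_feasible(p, order, tol=1e-7):
        return None, np.inf
    # snap tiny dominance violations left by the solver
    p = _tighten(p, order)
    return p, residual_objective(system, p)


def _tighten(p: np.ndarray, order: DominanceOrder) -> np.ndarray:
    """Remove solver-tolerance dominance violations (at most ~1e-8) exactly."""
    out = p.copy()
    # cover edges sorted so dominated (lexicographically smaller) sides settle first
    for _ in range(2):
        ok = True
        for a, bb in order.edges:
            if out[a] < out[bb]:
                mid = 0.5 * (out[a] + out[bb])
                out[a] = mid
                out[bb] = mid
                ok = False
        if ok:
            break
    return out


def sample_ensemble(
    system: LinearSystem,
    order: DominanceOrder,
    k: int = 1000,
    seed: int = 0,
    *,
    p_cap: float | None = None,
    attempt_cap: int | None = None,
) -> SolutionEnsemble:
    """Collect k error-minimizing solutions from independent random restarts.

    A restart is accepted when its objective is within a 1% relative window
    of the best objective found so far (plus an absolute 1e-12 floor for
    consistent systems); the window is re-applied whenever the best
    improves.  Restarts continue until k acceptances or the attempt cap
    (default 10*k) is reached, in which case the acceptance rate is reported
    in the error.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if attempt_cap is None:
        attempt_cap = 10 * k
    sols: list[np.ndarray] = []
    objs: list[float] = []
    restart_ids: list[int] = []
    best = np.inf
    attempts = 0
    while attempts < attempt_cap:
        p, obj = solve_once(system, order, attempts, master_seed=seed, p_cap=p_cap)
        attempts += 1
        if p is None:
            continue
        best = min(best, obj)
        sols.append(p)
        objs.append(obj)
        restart_ids.append(attempts - 1)
        accepted = _accepted_mask(np.array(objs), best)
        if int(accepted.sum()) >= k:
            sols_arr = np.array(sols)[accepted][:k]
            objs_arr = np.array(objs)[accepted][:k]
            ids_arr = np.array(restart_ids)[accepted][:k]
            return SolutionEnsemble(
                sols_arr, objs_arr, ids_arr, acceptance_rate=k / attempts
            )
    accepted = _accepted_mask(np.array(objs), best) if objs else np.array([], dtype=bool)
    rate = float(accepted.sum()) / attempts if attempts else 0.0
    raise RuntimeError(
        f"ensemble sampling: only {int(accepted.sum())} of {k} solutions accepted after "
        f"{attempts} attempts (acceptance rate {rate:.3f}); the acceptance window may be "
        "too tight or the system too hard"
    )


def _accepted_mask(objs: np.ndarray, best: float) -> np.ndarray:
    return objs <= best * (1.0 + ACCEPTANCE_REL_WINDOW) + 1e-12


def summarize_ensemble(ensemble: SolutionEnsemble) -> dict[str, np.ndarray]:
    """Per-profile mean, median and 95% percentile interval across solutions."""
    if ensemble.k < 1:
        raise ValueError("empty ensemble")
    s = ensemble.solutions
    return {
        "mean": s.mean(axis=0),
        "median": np.median(s, axis=0),
        "ui_low": np.percentile(s, 2.5, axis=0),
        "ui_high": np.percentile(s, 97.5, axis=0),
    }
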
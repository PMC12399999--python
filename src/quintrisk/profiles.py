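"""Risk profiles: enumeration, per-quintile tabulation and dominance order.

A risk profile is one severity level per risk factor; with two factors of
three levels each there are nine profiles.  Profile *a* dominates *b* when
*a* is at least as severe in every factor; the estimation step constrains
the outcome probability of *a* to be at least that of *b*.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .config import Outcome, RiskFactorSpec
from .io import N_QUINTILES, ChildTable


@dataclass
class ProfileTable:
    """Enumerated profiles with (optionally) weighted per-quintile counts.

    ``levels`` is a J x F integer matrix, one row per profile, in
    lexicographic order of level vectors.  ``counts`` is a J x 5 matrix of
    weighted child counts; ``None`` until :func:`tabulate_counts` runs.
    """

    factors: tuple[RiskFactorSpec, ...]
    levels: np.ndarray
    counts: np.ndarray | None = None

    @property
    def n_profiles(self) -> int:
        return self.levels.shape[0]

    @property
    def totals(self) -> np.ndarray:
        """Weighted count per profile, summed over quintiles."""
        if self.counts is None:
            raise ValueError("counts not tabulated yet")
        return self.counts.sum(axis=1)

    def factor_rr_matrix(self, outcome: Outcome) -> list[np.ndarray]:
        """rr[f][level] per factor, aligned with the level matrix columns."""
        return [np.asarray(f.rr(outcome), dtype=float) for f in self.factors]


def enumerate_profiles(factors: list[RiskFactorSpec] | tuple[RiskFactorSpec, ...]) -> ProfileTable:
    """Cartesian product of the factors' level indices, lexicographic order."""
    if len(factors) == 0:
        raise ValueError("at least one risk factor is required")
    if len(factors) > 4:
        raise ValueError("more than four risk factors is computationally intractable")
    grids = [range(f.n_levels) for f in factors]
    levels = np.array(list(itertools.product(*grids)), dtype=int)
    return ProfileTable(tuple(factors), levels)


def tabulate_counts(children: ChildTable, profiles: ProfileTable) -> ProfileTable:
    """Add weighted per-quintile counts: each child contributes its weight to
    exactly one (profile, quintile) cell."""
    names = [f.name for f in profiles.factors]
    lev = children.data[names].to_numpy(dtype=int)
    for k, f in enumerate(profiles.factors):
        out = (lev[:, k] < 0) | (lev[:, k] >= f.n_levels)
        if out.any():
            raise ValueError(
                f"factor {f.name!r}: level {lev[out, k][0]} outside range 0..{f.n_levels - 1}"
            )
    # profile index by mixed-radix encoding matching lexicographic enumeration
    radices = np.array([f.n_levels for f in profiles.factors])
    place = np.concatenate([np.cumprod(radices[::-1])[::-1][1:], [1]]).astype(int)
    j = lev @ place
    q = children.data["quintile"].to_numpy(dtype=int) - 1
    counts = np.zeros((profiles.n_profiles, N_QUINTILES))
    np.add.at(counts, (j, q), children.weights)
    return ProfileTable(profiles.factors, profiles.levels, counts)


@dataclass
class DominanceOrder:
    """Cover relations of the componentwise-severity partial order.

    ``edges`` lists ordered pairs (a, b): profile a dominates profile b and
    no third profile lies strictly between them (transitive reduction).
    """

    n_profiles: int
    edges: tuple[tuple[int, int], ...]
    _closure: set[tuple[int, int]] | None = field(default=None, repr=False)

    def comparable_pairs(self) -> set[tuple[int, int]]:
        """Transitive closure: all ordered pairs (a, b) with a dominating b."""
        if self._closure is None:
            g = nx.DiGraph(self.edges)
            g.add_nodes_from(range(self.n_profiles))
            self._closure = {
                (a, b) for a in g.nodes for b in nx.descendants(g, a)
            }
        return self._closure

    def edge_matrix(self) -> np.ndarray:
        """Incidence matrix D with one row per cover edge: (D p)[e] = p[a] - p[b]."""
        d = np.zeros((len(self.edges), self.n_profiles))
        for row, (a, b) in enumerate(self.edges):
            d[row, a] = 1.0
            d[row, b] = -1.0
        return d


def dominance_order(profiles: ProfileTable) -> DominanceOrder:
    """Transitive reduction of componentwise >= on the level vectors.

    The cover edges of the product order connect profiles differing by one
    severity step in exactly one factor; computed here from the full pairwise
    relation via networkx for clarity (J <= 81).
    """
    lev = profiles.levels
    j = profiles.n_profiles
    g = nx.DiGraph()
    g.add_nodes_from(range(j))
    for a in range(j):
        ge = np.all(lev >= lev[a], axis=1) & np.any(lev > lev[a], axis=1)
        for b in np.flatnonzero(ge):
            g.add_edge(int(b), int(a))  # b strictly dominates a
    reduced = nx.transitive_reduction(g)
    edges = tuple(sorted((int(a), int(b)) for a, b in reduced.edges))
    return DominanceOrder(j, edges)
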
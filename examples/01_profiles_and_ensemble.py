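"""Fit the constrained ensemble on a tiny two-factor population.

Builds the nine stunting x wasting risk profiles, tabulates a synthetic
population, constructs the marginal relative-risk equations with an anchor,
and samples 200 error-minimizing probability vectors under the dominance
monotonicity constraint.  Prints the per-profile summary and the marginal
relative risks implied by the ensemble mean: the implied values reproduce
the configured ones because every accepted solution satisfies the marginal
equations (near-)exactly.
"""

from quintrisk import (
    add_anchor,
    build_marginal_equations,
    dominance_order,
    enumerate_profiles,
    generate_children,
    implied_marginal_rr,
    sample_ensemble,
    tabulate_counts,
)
from quintrisk.synthetic import consistent_scenario, true_profile_probabilities

scenario = consistent_scenario(n_children=20_000, seed=0)
children = generate_children(scenario)

profiles = tabulate_counts(children, enumerate_profiles(scenario.factors))
order = dominance_order(profiles)
system = add_anchor(build_marginal_equations(profiles, "case"), overall_risk=0.2)

ensemble = sample_ensemble(system, order, k=200, seed=0)
summary = ensemble.summary()
truth = true_profile_probabilities(scenario, "case")

print("profile (stunting, wasting)   n      mean   [2.5%, 97.5%]   truth")
for j, lev in enumerate(profiles.levels):
    print(
        f"  {tuple(int(x) for x in lev)}              {profiles.totals[j]:7.0f}  "
        f"{summary['mean'][j]:.4f} [{summary['ui_low'][j]:.4f}, "
        f"{summary['ui_high'][j]:.4f}]  {truth[j]:.4f}"
    )
print("\nimplied marginal relative risks (ensemble mean):")
for (name, level), rr in implied_marginal_rr(profiles, summary["mean"]).items():
    print(f"  {name} level {level}: {rr:.3f}")
print(
    "\nThe anchor fixes the overall scale at 0.2; the uncertainty interval "
    "per profile\nreflects the non-uniqueness of the error-minimizing solutions."
)
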
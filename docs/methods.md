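# Methods

`quintrisk` estimates how the risk of dying from diarrhoea, pneumonia or
measles in children under five is distributed across household wealth
quintiles, from (i) child-level risk-factor microdata, (ii) per-quintile
immunization coverage and care-seeking, and (iii) a per-quintile under-5
mortality differential. The output is a *risk gradient*: five relative
risks of death, normalized so the lowest-risk quintile equals 1.

## Model

**Risk profiles.** Each disease outcome (cases or deaths) is governed by up
to four ordered risk factors (e.g. stunting, wasting, underweight, vitamin
A deficiency, unsafe sanitation), each with 2–3 severity levels, level 0
being the reference. A *profile* j is one level per factor; the lattice has
J = ∏ L_f profiles. Children are assigned to profiles; n_j is the
(survey-weighted) count in profile j and n_{jq} its split over quintiles
q = I..V. Only complete cases for the active factor set are used, because
no assumption is made about the background distribution of profiles.

**Marginal relative-risk system.** Unknowns are per-profile outcome
probabilities p_j ∈ [0,1]. For each factor f and non-reference level l, one
equation requires the count-weighted mean risk in the level-l group to be
rr_{f,l} times the mean risk in f's reference group:

    (1/N_{f,l}) Σ_{j: lev_f(j)=l} n_j p_j  −  rr_{f,l} (1/N_{f,0}) Σ_{j: lev_f(j)=0} n_j p_j = 0.

Group means (not raw sums) make every equation dimensionless, so factors
with unbalanced groups contribute comparably and the residuals are
invariant to a global rescaling of counts. Equations whose level or
reference group is empty are dropped and logged. An *anchor* equation
(1/N) Σ n_j p_j = r₀ fixes the overall scale (default r₀ = 0.05); the
normalized gradient is invariant to r₀ (see below), so its value only
matters when absolute probabilities are interpreted.

With ≥ 2 factors the system has rank ≤ 1 + Σ_f (L_f − 1) < J: it is
structurally underdetermined, and with real (correlated) data also
inconsistent. Estimation therefore minimizes the sum of squared residuals
‖Ap − b‖² over the constraint set.

**Monotonicity.** If profile a is at least as severe as b in every factor
(componentwise dominance), then p_a ≥ p_b. The dominance relation is stored
as its transitive reduction (cover edges of the product order, computed
with networkx); feasibility checks use the full transitive closure.

**Ensemble of minimizers.** The objective is convex quadratic, so every
local minimizer is global, but the minimizer is generally a *face* of the
polytope, not a point. The estimator samples that face: each restart draws
a uniform random start, makes it admissible by *monotone rearrangement*
(sweep the cover edges in a fixed order, replacing each violated pair by
its midpoint, until no violation remains — the result stays inside the
convex hull of the input and equals the input when already monotone), and
then runs SLSQP with analytic gradients under the box and dominance
constraints. Solutions within a 1% relative window of the best objective
found (plus an absolute 1e-12 floor for consistent systems) are accepted
until k = 1000 are collected (attempt cap 10k). Per-profile means, medians
and 95% percentile intervals summarize the ensemble; the intervals express
the non-uniqueness of the minimizers. The whole procedure is deterministic
given the master seed (restart i uses the PRNG stream keyed by
(master_seed, i)).

The midpoint sweep contracts violations geometrically on chains and
terminates exactly when neighbouring values quantize to the same float; the
sweep cap is sized accordingly (64·J).

**Anchor equivariance and the restart distribution.** Two choices make the
reported gradients exactly invariant to the anchor value: (1) anchored
systems are solved internally in canonical units (the problem rescaled so
the anchor equals 0.05; the marginal rows are homogeneous, so only the
anchor row and the box bound change), and the upper box bound is imposed
only if the relaxed solution actually leaves the box — so the solver path
is bit-identical for any anchor value in the non-binding regime; (2)
restarts are uniform on [0, 3·r₀]. The multiple 3 is a calibrated tuning
constant: on synthetic consistent scenarios (independent factors,
multiplicative ground truth, 2- and 3-factor lattices, several seeds) it
makes the ensemble mean approximately unbiased for the true per-profile
probabilities; smaller multiples bias the mean downward along the
non-unique face and larger ones upward. Unanchored (homogeneous) systems
use a fixed cap of 0.5.

## Coverage adjustment

Expected outcomes n_{jq}·p_j are scaled per quintile:

* immunization (cases **and** deaths): ∏_v (1 − AF_v · eff_v · cov_{v,q}),
  where AF_v is the fraction of the disease's cases attributable to the
  agent vaccine v targets (pneumococcus 33.0% and Hib 21.6% of pneumonia;
  1.0 for measles vaccine). A vaccine absent from the national programme
  enters with coverage 0, i.e. no reduction. Multiple vaccines combine
  multiplicatively, assuming disjoint aetiologies.
* treatment (deaths only): 1 − eff_T · careseek_q. Treatment averts death
  given disease, so case counts are never treatment-adjusted. Care-seeking
  proxies: diarrhoea uses diarrhoea care-seeking; pneumonia uses acute
  respiratory infection care-seeking, falling back to fever; measles uses
  the mean of the diarrhoea and ARI percentages.

Efficacies default to point estimates. An optional mode draws per-replicate
efficacies from Beta distributions moment-matched to the 95% intervals
(sd = width/3.92), propagating efficacy uncertainty into the gradient
intervals.

## Linking deaths to cases

Three simple case-fatality models:

* **A (direct):** fit the ensemble on the mortality risk factors; apply
  immunization and treatment multipliers.
* **B (case-risk-based):** fit on the morbidity risk factors; apply both
  multipliers. Reported but excluded from the headline result.
* **C (extrapolated):** take expected cases (immunization-adjusted by
  default; a `c_adjusted/c_raw` flag switches to raw) and scale by the
  under-5 mortality differential, deaths_q = cases_q · u5mr_q / mean(u5mr).
  The normalizer cancels in the gradient.

The headline (*main analysis*) gradient is the elementwise mean of the
normalized A and C gradients, renormalized so its minimum is exactly 1.

## Reporting

Per replicate r, quintile risk = deaths_{rq} / pop_q. The mean gradient is
the across-replicate mean risk divided by its minimum (set to exactly 1;
the attaining quintile is reported as the reference). Medians and 95%
percentile intervals are computed on per-replicate vectors, each divided by
its own value at the reference quintile. Quintile-level monotonicity is
never imposed — only profile-level dominance is — so a monotone gradient is
an emergent result.

## Synthetic data

The generator emulates DHS structure: five quintiles of roughly equal size
(uniform assignment), factor levels drawn independently across factors
within quintile from per-quintile prevalence vectors, unit weights, linear
coverage/care-seeking ramps clamp(base + slope·(q−3), 0, 1), and a fixed
u5mr vector. Ground truth is multiplicative: p_j = p₀ ∏_f rr_{f,lev}.

* `consistent_scenario` (default n = 50 000): prevalence constant across
  quintiles, so factors are mutually independent and the truth satisfies
  the marginal equations in expectation (zero-residual regime). Its
  relative risks are moderate (≤ 1.6 at the severe level, stunting and
  wasting at three levels, p₀ = 0.15 for cases / 0.02 for deaths): with
  moderate rr the minimizer face is small relative to the truth, which is
  the regime where per-profile parameter recovery is meaningful. Recovery
  experiments anchor at the count-weighted true overall risk, since
  absolute probabilities are only identified up to the anchor.
* `gradient_scenario` (default n = 20 000): stunting/wasting prevalence
  worsening toward quintile I (severe stunting 25% → 10% of the moderate+
  mass, interpolated linearly), mcv coverage 0.44→0.76, care-seeking
  ramps of similar size, u5mr 110→58 per 1000. Used for the emergent-
  monotonicity checks; problem sizes (n = 8 000, k = 100, 20 seeds for the
  multi-seed check) keep the default suite quick while leaving the
  acceptance statistics stable.
* `three_factor_scenario`: adds unsafe sanitation (18-profile lattice) for
  default-size (k = 1000) ensemble runs.

What the generator does **not** emulate: DHS cluster/stratum sampling
design (only weights are supported), item non-response patterns (missing
data are generated only in tests), correlated factor levels within child
beyond what the shared wealth gradient induces (a child severely wasted is
not made more likely to be stunted within quintile), and measurement error
in anthropometry or recall bias in care-seeking. Passing tests therefore
show the estimator is correct under its own assumptions, not that those
assumptions hold in real surveys.

## Numerical choices and degenerate inputs

* SLSQP with analytic objective/constraint gradients, ftol 1e-14, max 300
  iterations; non-converged or infeasible restarts are discarded (they do
  not count toward k); solver-tolerance dominance violations (≲1e-8) are
  snapped by a final midpoint pass; feasibility is enforced at 1e-9 on the
  full closure.
* Acceptance window 1% relative: for convex quadratics all converged
  restarts are global minimizers, so in practice 100% are accepted; the
  window exists to make the ensemble's definition explicit and
  reproducible.
* Empty profiles remain unknowns constrained by dominance; equations with
  empty groups are dropped. A system with no remaining equations is an
  error. Quintiles with zero population make the gradient undefined and
  raise.
* Ties in the reference quintile (exactly equal mean risks) resolve to the
  lowest quintile index via argmin.
* Percentiles use linear interpolation (numpy default).

## Known limitations

* The relative-risk magnitudes shipped in the bundled configs are
  illustrative placeholders; real analyses must supply literature-based
  values per disease and outcome.
* The model is static: no transmission dynamics or herd effects, no second
  measles-vaccine dose.
* Per-profile probabilities are set-identified, not point-identified, for
  ≥ 2 factors; the ensemble summaries depend on the restart distribution
  (calibrated as described above), and the rearrangement scheme does not
  sample the minimizer face uniformly.
* More than four factors per outcome is rejected: the lattice and the
  non-uniqueness of the minimizer grow multiplicatively.
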
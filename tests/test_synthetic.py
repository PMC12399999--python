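import numpy as np
import pytest
from scipy import stats

from quintrisk.config import RiskFactorSpec
from quintrisk.linsys import build_marginal_equations, residual_objective
from quintrisk.profiles import enumerate_profiles, tabulate_counts
from quintrisk.synthetic import (
    ScenarioSpec,
    consistent_scenario,
    generate_children,
    generate_tables,
    gradient_scenario,
    linear_prevalence,
    true_profile_probabilities,
    write_scenario_files,
)


class TestGenerateChildren:
    def test_quintiles_roughly_equal(self):
        sc = consistent_scenario(n_children=10_000, seed=0)
        children = generate_children(sc)
        counts = children.data["quintile"].value_counts()
        assert set(counts.index) == {1, 2, 3, 4, 5}
        assert np.all(np.abs(counts.to_numpy() - 2000) < 5 * np.sqrt(2000))

    def test_determinism(self):
        sc = consistent_scenario(n_children=500, seed=9)
        a = generate_children(sc).data
        b = generate_children(consistent_scenario(n_children=500, seed=9)).data
        assert a.equals(b)

    def test_seed_sensitivity(self):
        a = generate_children(consistent_scenario(500, seed=1)).data
        b = generate_children(consistent_scenario(500, seed=2)).data
        assert not a.equals(b)

    def test_degenerate_prevalence_single_profile(self):
        f = RiskFactorSpec("x", ("a", "b"), rr_case=(1.0, 2.0), rr_death=(1.0, 2.0))
        sc = ScenarioSpec(
            n_children=200, factors=(f,),
            prevalence={"x": np.tile([1.0, 0.0], (5, 1))},
            p0_case=0.1, p0_death=0.01, seed=3,
        )
        children = generate_children(sc)
        prof = tabulate_counts(children, enumerate_profiles(sc.factors))
        assert prof.counts[0].sum() == 200 and prof.counts[1].sum() == 0

    def test_level_frequencies_match_prevalence(self):
        """Goodness of fit of generated level frequencies to the scenario
        prevalence at large n."""
        sc = consistent_scenario(n_children=100_000, seed=5)
        children = generate_children(sc)
        for f in sc.factors:
            observed = children.data[f.name].value_counts().sort_index().to_numpy()
            expected = sc.prevalence[f.name][0] * len(children)
            assert stats.chisquare(observed, expected).pvalue > 0.001


class TestTruth:
    def test_null_model(self):
        f = RiskFactorSpec("x", ("a", "b"), rr_case=(1.0, 1.0), rr_death=(1.0, 1.0))
        sc = ScenarioSpec(
            n_children=10, factors=(f,), prevalence={"x": np.tile([0.5, 0.5], (5, 1))},
            p0_case=0.07, p0_death=0.01, seed=0,
        )
        np.testing.assert_allclose(true_profile_probabilities(sc, "case"), 0.07)

    def test_single_factor_multiplication(self):
        f = RiskFactorSpec("x", ("a", "b", "c"), rr_case=(1.0, 2.0, 4.0),
                          rr_death=(1.0, 2.0, 4.0))
        sc = ScenarioSpec(
            n_children=10, factors=(f,),
            prevalence={"x": np.tile([0.5, 0.3, 0.2], (5, 1))},
            p0_case=0.01, p0_death=0.001, seed=0,
        )
        np.testing.assert_allclose(
            true_profile_probabilities(sc, "case"), [0.01, 0.02, 0.04]
        )

    def test_truth_above_one_rejected(self):
        f = RiskFactorSpec("x", ("a", "b"), rr_case=(1.0, 3.0), rr_death=(1.0, 3.0))
        with pytest.raises(ValueError, match="exceeds 1"):
            ScenarioSpec(
                n_children=10, factors=(f,),
                prevalence={"x": np.tile([0.5, 0.5], (5, 1))},
                p0_case=0.5, p0_death=0.01, seed=0,
            )

    def test_truth_satisfies_marginal_equations(self):
        """Under independent factor assignment the multiplicative truth has
        (near) zero residual in the built system; exactly zero when the
        counts are product-form."""
        sc = consistent_scenario(n_children=40_000, seed=7)
        children = generate_children(sc)
        spec = sc.disease_spec()
        prof = tabulate_counts(children, enumerate_profiles(spec.case_factors))
        system = build_marginal_equations(prof, "case")
        truth = true_profile_probabilities(sc, "case")
        # residual is O(sampling noise) relative to p0^2
        assert residual_objective(system, truth) < 1e-4 * sc.p0_case ** 2


class TestGenerateTables:
    def test_flat_when_slope_zero(self):
        cov, _ = generate_tables(consistent_scenario(100, 0))
        assert np.ptp(cov.vaccine_coverage["mcv"]) == 0.0

    def test_linear_form(self):
        f = RiskFactorSpec("x", ("a", "b"), rr_case=(1.0, 1.2), rr_death=(1.0, 1.2))
        sc = ScenarioSpec(
            n_children=10, factors=(f,), prevalence={"x": np.tile([0.5, 0.5], (5, 1))},
            vaccine_coverage={"v": (0.5, 0.1)}, p0_case=0.1, p0_death=0.01, seed=0,
        )
        cov, _ = generate_tables(sc)
        np.testing.assert_allclose(cov.vaccine_coverage["v"], [0.3, 0.4, 0.5, 0.6, 0.7])

    def test_clamping_at_bounds(self):
        f = RiskFactorSpec("x", ("a", "b"), rr_case=(1.0, 1.2), rr_death=(1.0, 1.2))
        sc = ScenarioSpec(
            n_children=10, factors=(f,), prevalence={"x": np.tile([0.5, 0.5], (5, 1))},
            vaccine_coverage={"v": (0.5, 0.4)}, p0_case=0.1, p0_death=0.01, seed=0,
        )
        cov, _ = generate_tables(sc)
        expect = np.clip(0.5 + 0.4 * (np.arange(1, 6) - 3), 0, 1)
        np.testing.assert_allclose(cov.vaccine_coverage["v"], expect)

    def test_prevalence_interpolation_stays_on_simplex(self):
        prev = linear_prevalence([0.4, 0.35, 0.25], [0.7, 0.2, 0.1])
        np.testing.assert_allclose(prev.sum(axis=1), 1.0)
        assert np.all(prev >= 0)


class TestScenarioFiles:
    def test_four_files_written_and_loadable(self, tmp_path):
        from quintrisk.io import load_coverage, load_microdata, load_u5mr

        sc = gradient_scenario(n_children=400, seed=1)
        paths = write_scenario_files(sc, tmp_path)
        assert sorted(p.name for p in tmp_path.iterdir()) == [
            "coverage.csv", "microdata.csv", "truth.json", "u5mr.csv",
        ]
        spec = sc.disease_spec()
        table = load_microdata(paths["microdata"], spec)
        assert len(table) == 400
        load_coverage(paths["coverage"])
        load_u5mr(paths["u5mr"])
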
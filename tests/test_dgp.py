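import numpy as np
import pytest

from nlmrsim import (
    MODEL_REGISTRY,
    ScenarioConfig,
    generate_cohort,
    generate_empirical_standin,
    generate_error_prone_confounder,
    generate_model_cohort,
    interaction_test,
    simulation_a,
)
from nlmrsim.io import cohort_from_tsv, cohort_to_tsv


class TestMainGenerator:
    def test_all_coefficients_zero_leaves_pure_instrument_model(self):
        c = ScenarioConfig(n=100, mu=0.0, seed=1)
        coh = generate_cohort(c)
        np.testing.assert_allclose(coh.x, 0.3 * coh.g + coh.e_x)
        np.testing.assert_allclose(coh.y, coh.e_y)
        assert coh.v is None

    def test_mean_of_exposure_matches_analytic_expectation(self):
        # E[x] = 0.3*2 + 0.3*2 - 0.1*E[g]E[u] + 2 = 2.8 under independence
        c = simulation_a(n=200_000, seed=3)
        coh = generate_cohort(c)
        se = coh.x.std(ddof=1) / np.sqrt(len(coh))
        assert abs(coh.x.mean() - 2.8) < 4 * se

    def test_same_seed_is_bit_identical(self):
        c = simulation_a(n=1000, seed=5)
        a, b = generate_cohort(c), generate_cohort(c)
        for f in ("g", "u", "e_x", "e_y", "x", "y"):
            np.testing.assert_array_equal(getattr(a, f), getattr(b, f))

    def test_distributional_calibration_at_scale(self):
        c = ScenarioConfig(n=100_000, mu=2.0, sigma=1.0, seed=11)
        coh = generate_cohort(c)
        se = 1.0 / np.sqrt(c.n)
        for v in (coh.g, coh.u, coh.e_x, coh.e_y):
            assert abs(v.mean() - 2.0) < 5 * se
            assert abs(v.std(ddof=1) - 1.0) < 5 * se

    def test_exposure_and_outcome_recomputable_from_components(self):
        coh = generate_cohort(simulation_a(n=500, seed=8))
        np.testing.assert_array_equal(coh.recompute_x(), coh.x)
        np.testing.assert_array_equal(coh.recompute_y(), coh.y)
        from nlmrsim import simulation_b
        coh_b = generate_cohort(simulation_b(n=500, seed=8))
        np.testing.assert_array_equal(coh_b.recompute_x(), coh_b.x)
        np.testing.assert_array_equal(coh_b.recompute_y(), coh_b.y)


class TestModelCohorts:
    def test_linear_model_formula_on_injected_components(self):
        coh = generate_model_cohort(
            "M1", 3, _components={"g": [1, 0, -1], "u": [0, 0, 0],
                                  "e": [0, 0, 0]})
        np.testing.assert_allclose(coh.x, [0.3, 0.0, -0.3])

    def test_unknown_model_lists_valid_ids(self):
        with pytest.raises(Exception, match="M1"):
            generate_model_cohort("M99", 10)

    def test_narrow_instrument_model_has_quarter_sd(self):
        coh = generate_model_cohort("M10", 200_000, seed=4)
        sd = coh.g.std(ddof=1)
        assert abs(sd - 0.25) < 5 * 0.25 / np.sqrt(2 * len(coh))

    @pytest.mark.parametrize("model_id,partner", [
        ("M11", "e_x"), ("M13", "u"),
    ])
    def test_individual_effect_tracks_its_conditioning_variable(
            self, model_id, partner):
        # alpha = 0.3 + 0.1*t + N(0, 0.1^2) => cor(alpha, t) = 1/sqrt(2)
        coh = generate_model_cohort(model_id, 200_000, seed=6)
        r = np.corrcoef(coh.alpha, getattr(coh, partner))[0, 1]
        assert abs(r - 1 / np.sqrt(2)) < 0.01
        assert abs(coh.alpha.mean() - 0.3) < 5 * 0.15 / np.sqrt(len(coh))

    def test_mixed_conditioning_model_tracks_the_average(self):
        coh = generate_model_cohort("M12", 200_000, seed=6)
        t = (coh.e_x + coh.u) / np.sqrt(2)
        r = np.corrcoef(coh.alpha, t)[0, 1]
        assert abs(r - 1 / np.sqrt(2)) < 0.01

    @pytest.mark.parametrize("model_id", sorted(MODEL_REGISTRY))
    def test_exposure_recomputable_for_every_model(self, model_id):
        coh = generate_model_cohort(model_id, 500, seed=2)
        np.testing.assert_array_equal(coh.recompute_x(), coh.x)


class TestErrorProneConfounder:
    def test_perfect_correlation_returns_u_itself(self, rng):
        u = rng.normal(2, 1, 100)
        np.testing.assert_array_equal(
            generate_error_prone_confounder(u, 1.0, seed=0), u)

    def test_target_correlation_and_variance_are_hit(self, rng):
        u = rng.normal(2, 1, 100_000)
        ue = generate_error_prone_confounder(u, 0.8, seed=1)
        r = np.corrcoef(u, ue)[0, 1]
        assert abs(r - 0.8) < 4 * (1 - 0.8 ** 2) / np.sqrt(len(u))
        assert abs(ue.std(ddof=1) / u.std(ddof=1) - 1) < 0.02

    def test_constant_u_is_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            generate_error_prone_confounder(np.ones(10), 0.8)


class TestEmpiricalStandin:
    def test_outputs_are_standardized(self):
        coh = generate_empirical_standin(5000, heterogeneity=0.2, seed=3)
        for v in (coh.x, coh.g):
            assert abs(v.mean()) < 1e-10
            assert abs(v.std(ddof=1) - 1) < 1e-10

    def test_homogeneous_effect_recovers_slope(self):
        coh = generate_empirical_standin(100_000, heterogeneity=0.0, seed=4)
        b = np.polyfit(coh.g, coh.x, 1)[0]
        # slope on the standardized scale is beta_g / sd(x_raw)
        expected = 0.3 / coh.meta["x_scale"]
        assert abs(b - expected) < 0.02

    def test_interaction_regression_recovers_heterogeneity(self):
        coh = generate_empirical_standin(100_000, heterogeneity=0.2, seed=5)
        beta, se, p = interaction_test(coh.x, coh.g, coh.modifiers["m"])
        assert abs(beta * coh.meta["x_scale"] - 0.2) < 4 * se * coh.meta["x_scale"]

    def test_skew_flag_produces_right_skewed_exposure(self):
        from scipy.stats import skew
        coh = generate_empirical_standin(20_000, skew=True, seed=6)
        assert skew(coh.x) > 1.0
        assert abs(coh.x.std(ddof=1) - 1) < 1e-10


class TestRoundTrip:
    def test_cohort_tsv_round_trip(self, tmp_path, small_cohort):
        p = tmp_path / "cohort.tsv"
        cohort_to_tsv(small_cohort, str(p))
        back = cohort_from_tsv(str(p))
        np.testing.assert_allclose(back.x, small_cohort.x)
        np.testing.assert_allclose(back.g, small_cohort.g)
        np.testing.assert_array_equal(back.id, small_cohort.id)
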
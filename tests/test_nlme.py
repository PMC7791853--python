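"""Mixed-effects fitter tests: closed forms, limits and independent oracles."""

import numpy as np
import pytest
from scipy.stats import norm

from lamscore import (
    CohortData,
    IndividualEffects,
    PopulationParams,
    REFERENCE_PARAMS,
    SaemSettings,
    Trajectory,
    simulate_cohort,
    structural_mean,
)
from lamscore.core import decay_curve
from lamscore.nlme import (
    compare_models,
    complete_data_loglik,
    diagnostics,
    estimate_loglik,
    oracle_fit_two_stage,
    saem_fit,
)

FAST_SETTINGS = SaemSettings(n_burnin=250, n_smoothing=100, seed=5)


class TestStructuralMean:
    def test_day_zero_identity(self):
        eff = IndividualEffects("h", 1.5, -2.0, 1.3)
        assert structural_mean(eff, 0) == pytest.approx(np.exp(1.5))

    def test_reference_day_zero_score(self):
        assert structural_mean(REFERENCE_PARAMS, 0) == pytest.approx(7.92, abs=0.005)

    def test_reference_day_25_near_zero(self):
        # independent evaluation: 7.9248 * exp(-exp(-1.95) * 25**1.16)
        expected = np.exp(2.07) * np.exp(-np.exp(-1.95) * 25.0**1.16)
        assert structural_mean(REFERENCE_PARAMS, 25) == pytest.approx(expected)
        assert structural_mean(REFERENCE_PARAMS, 25) == pytest.approx(0.0206, abs=0.001)


class TestCompleteDataLoglik:
    def _setup(self):
        pop = PopulationParams(2.0, -2.0, 1.0, 0.1, 0.1, 0.1, sigma=0.5)
        eff = IndividualEffects("h1", 2.1, -1.9, 1.05)
        cohort = CohortData(
            [Trajectory("h1", np.array([0, 4]), np.array([7.0, 5.0]))]
        )
        return pop, eff, cohort

    def test_matches_scalar_hand_computation(self):
        pop, eff, cohort = self._setup()
        f = decay_curve(eff.as_array, np.array([0.0, 4.0]))
        expected = norm.logpdf(np.array([7.0, 5.0]), f, 0.5).sum() + sum(
            norm.logpdf(v, m, np.sqrt(0.1))
            for v, m in zip(eff.as_array, pop.fixed_effects)
        )
        got = complete_data_loglik(pop, [eff], cohort)
        assert got == pytest.approx(expected)

    def test_combined_error_with_b_zero_nests_additive(self):
        pop, eff, cohort = self._setup()
        additive = complete_data_loglik(pop, [eff], cohort)
        combined = complete_data_loglik(
            pop, [eff], cohort,
            error_model="additive_plus_proportional", error_params=(0.5, 0.0),
        )
        assert combined == pytest.approx(additive)

    def test_nonpositive_variance_rejected(self):
        pop, eff, cohort = self._setup()
        with pytest.raises(ValueError):
            complete_data_loglik(pop.with_(omega1=0.0), [eff], cohort)


class TestSaem:
    def test_near_deterministic_limit_recovers_fixed_effects(self):
        pop = PopulationParams(2.07, -1.95, 1.16, 0, 0, 0, sigma=0.01)
        cohort = simulate_cohort(pop, n=20, seed=3, clip=False, round_to_integer=False)
        fit = saem_fit(cohort, settings=FAST_SETTINGS)
        est = fit.estimates
        assert est.log_theta0 == pytest.approx(2.07, abs=0.05)
        assert est.log_theta1 == pytest.approx(-1.95, abs=0.05)
        assert est.theta2 == pytest.approx(1.16, abs=0.05)

    def test_agrees_with_two_stage_oracle_at_low_noise(self):
        pop = REFERENCE_PARAMS.with_(sigma=0.2)
        cohort = simulate_cohort(pop, seed=21, clip=False, round_to_integer=False)
        fit = saem_fit(cohort, settings=SaemSettings(seed=5))
        oracle = oracle_fit_two_stage(cohort)
        diff = np.abs(fit.estimates.fixed_effects - oracle.params.fixed_effects)
        assert np.all(diff < 0.2)

    def test_aic_identity_and_cv_arithmetic(self):
        cohort = simulate_cohort(n=20, seed=4)
        fit = saem_fit(cohort, settings=FAST_SETTINGS, score_col="raw_score")
        assert fit.aic == pytest.approx(-2.0 * fit.loglik_estimate + 2.0 * fit.n_params)
        assert fit.n_params == 7
        point = {**{k: v for k, v in fit.estimates.to_dict().items()}, **fit.error_params}
        for name, se in fit.standard_errors.items():
            if np.isfinite(se):
                assert fit.cv_percent[name] == pytest.approx(
                    100.0 * se / abs(point[name])
                )

    def test_degenerate_cohorts_rejected(self):
        single = CohortData([Trajectory("a", np.array([0, 4]), np.array([8, 5]))])
        with pytest.raises(ValueError, match="at least 2 horses"):
            saem_fit(single)
        constant = CohortData(
            [
                Trajectory("a", np.array([0, 4]), np.array([5, 5])),
                Trajectory("b", np.array([0, 4]), np.array([5, 5])),
            ]
        )
        with pytest.raises(ValueError, match="constant"):
            saem_fit(constant)


class TestTwoStageOracle:
    def test_noise_free_recovery_is_exact(self):
        from lamscore import sample_individual_params, simulate_trajectory

        effects = sample_individual_params(REFERENCE_PARAMS, 10, seed=1)
        cohort = CohortData(
            [
                simulate_trajectory(e, sigma=0.0, clip=False, round_to_integer=False)
                for e in effects
            ]
        )
        res = oracle_fit_two_stage(cohort)
        per = res.per_horse.set_index("horse_id")
        for e in effects:
            assert per.loc[e.horse_id, "log_theta0_i"] == pytest.approx(
                e.log_theta0_i, abs=1e-6
            )
            assert per.loc[e.horse_id, "theta2_i"] == pytest.approx(e.theta2_i, abs=1e-6)
        truth = np.array([e.as_array for e in effects])
        assert res.params.fixed_effects == pytest.approx(truth.mean(axis=0), abs=1e-6)

    def test_underdetermined_horse_skipped_with_warning(self):
        from lamscore import sample_individual_params, simulate_trajectory

        effects = sample_individual_params(REFERENCE_PARAMS, 3, seed=2)
        trajs = [
            simulate_trajectory(e, sigma=0.0, clip=False, round_to_integer=False)
            for e in effects[:2]
        ]
        trajs.append(
            simulate_trajectory(
                effects[2], days=[0, 4, 9], sigma=0.0, clip=False, round_to_integer=False
            )
        )
        with pytest.warns(UserWarning, match="visits"):
            res = oracle_fit_two_stage(CohortData(trajs))
        assert res.n_skipped == 1 and res.n_fitted == 2


class TestMarginalLoglik:
    def test_collapses_to_closed_form_without_random_effects(self):
        pop = PopulationParams(2.07, -1.95, 1.16, 0, 0, 0, sigma=0.01)
        cohort = simulate_cohort(pop, n=8, seed=6, clip=False, round_to_integer=False)
        fit = saem_fit(cohort, settings=FAST_SETTINGS)
        # omegas collapse to the fitting floor -> closed-form branch
        assert fit.loglik_mc_se == 0.0
        theta = fit.estimates.fixed_effects
        frame = cohort.to_frame()
        f = decay_curve(theta, frame["day"].to_numpy(float))
        closed = norm.logpdf(
            frame["score"].to_numpy(float), f, fit.estimates.sigma
        ).sum()
        assert fit.loglik_estimate == pytest.approx(closed)

    def test_mc_se_shrinks_with_more_samples(self):
        cohort = simulate_cohort(seed=4)
        fit = saem_fit(cohort, settings=FAST_SETTINGS, score_col="raw_score")
        se_small = np.mean(
            [estimate_loglik(fit, cohort, 400, seed=s).mc_se for s in range(4)]
        )
        se_big = np.mean(
            [estimate_loglik(fit, cohort, 1600, seed=s).mc_se for s in range(4)]
        )
        assert se_big < se_small
        assert se_small / se_big == pytest.approx(2.0, abs=0.9)  # ~ sqrt(4)

    def test_seed_spread_consistent_with_reported_se(self):
        cohort = simulate_cohort(seed=4)
        fit = saem_fit(cohort, settings=FAST_SETTINGS, score_col="raw_score")
        ests = [estimate_loglik(fit, cohort, 500, seed=s) for s in range(10)]
        spread = np.std([e.value for e in ests])
        reported = np.mean([e.mc_se for e in ests])
        assert spread < 3 * reported
        assert spread > reported / 3


class TestModelComparison:
    def test_single_candidate_table(self):
        cohort = simulate_cohort(n=15, seed=8)
        table = compare_models(
            cohort, [{"name": "only"}], settings=FAST_SETTINGS, score_col="raw_score"
        )
        assert len(table) == 1
        assert table.iloc[0]["delta_aic"] == 0.0


class TestDiagnostics:
    def test_noise_free_residuals_vanish(self):
        pop = PopulationParams(2.07, -1.95, 1.16, 0.02, 0.05, 0.02, sigma=1.0)
        from lamscore import sample_individual_params, simulate_trajectory

        effects = sample_individual_params(pop, 10, seed=1)
        cohort = CohortData(
            [
                simulate_trajectory(e, sigma=0.0, clip=False, round_to_integer=False)
                for e in effects
            ]
        )
        fit = saem_fit(cohort, settings=FAST_SETTINGS)
        diag = diagnostics(fit, cohort)
        assert np.abs(diag.table["resid_individual"]).max() < 0.05

    def test_clipped_zero_scores_flagged_as_biased(self):
        cohort = simulate_cohort(seed=11)  # clipped integer scores
        fit = saem_fit(cohort, settings=FAST_SETTINGS, score_col="score")
        diag = diagnostics(fit, cohort)
        assert diag.zero_score_bias_flagged
        assert diag.zero_score_bias != 0.0
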
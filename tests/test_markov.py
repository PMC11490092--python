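import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import psarank.markov_case_study as mcs
from psarank.psa_core import PSADomainError, compute_inb

from conftest import quiet_markov_config

DISCOUNT_SERIES_10 = 8.607686508868186  # sum_{t=0..9} 1.035^-t


class TestRatesToCycleProbabilities:
    def test_zero_rates_identity(self):
        p = mcs.rates_to_cycle_probabilities(np.zeros((4, 4)), 1.0)
        np.testing.assert_allclose(p, np.eye(4), atol=0)

    def test_half_life_exit(self):
        r = np.zeros((2, 2))
        r[0, 1] = np.log(2.0)
        p = mcs.rates_to_cycle_probabilities(r, 1.0)
        assert p[0, 1] == pytest.approx(0.5, abs=1e-12)
        assert p[0, 0] == pytest.approx(0.5, abs=1e-12)

    def test_competing_risks_split(self):
        r = np.zeros((3, 3))
        r[0, 1] = r[0, 2] = 1.0
        p = mcs.rates_to_cycle_probabilities(r, 1.0)
        total = 1.0 - np.exp(-2.0)
        assert p[0, 1] == pytest.approx(total / 2, abs=1e-12)
        assert p[0, 2] == pytest.approx(total / 2, abs=1e-12)

    def test_negative_rate_rejected(self):
        r = np.zeros((2, 2))
        r[0, 1] = -0.1
        with pytest.raises(PSADomainError):
            mcs.rates_to_cycle_probabilities(r, 1.0)

    @given(st.integers(2, 5), st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_rows_always_sum_to_one(self, size, seed):
        rates = np.random.default_rng(seed).uniform(0, 5, size=(size, size))
        p = mcs.rates_to_cycle_probabilities(rates, 0.7)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(p >= 0)


class TestRunCohort:
    def test_immortal_undiscounted(self):
        config = quiet_markov_config(horizon=10)
        trace = mcs.run_cohort(config, "A")
        assert trace.discounted_qalys == pytest.approx(10.0, abs=1e-12)
        assert trace.discounted_costs == 0.0

    def test_discount_series(self):
        config = quiet_markov_config(horizon=10, discount_rate_qalys=0.035)
        trace = mcs.run_cohort(config, "A")
        assert trace.discounted_qalys == pytest.approx(DISCOUNT_SERIES_10, abs=1e-12)

    def test_two_cycle_hand_trace(self):
        # well -> dead at 0.1/yr, utility 0.8, 2 annual cycles, no discounting
        config = quiet_markov_config(
            {"bg_mortality_rate_40": 0.1, "utility_well": 0.8}, horizon=2)
        trace = mcs.run_cohort(config, "A")
        surv = np.exp(-0.1)
        assert trace.occupancy[0, 0] == 1.0
        assert trace.occupancy[1, 0] == pytest.approx(surv, abs=1e-15)
        assert trace.occupancy[1, 3] == pytest.approx(1 - surv, abs=1e-15)
        assert trace.discounted_qalys == pytest.approx(0.8 * (1 + surv), abs=1e-13)

    def test_unknown_treatment(self):
        with pytest.raises(PSADomainError, match="treatment"):
            mcs.run_cohort(quiet_markov_config(), "C")

    @pytest.mark.parametrize("arm", ["A", "B"])
    def test_conservation_and_absorbing_dead(self, arm):
        trace = mcs.run_cohort(mcs.default_config(), arm)
        np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(np.diff(trace.occupancy[:, 3]) >= -1e-15)

    def test_null_relative_effect_weakly_reduces_gain(self):
        config = mcs.default_config()
        def gain(rr):
            tb = mcs.run_cohort(config, "B",
                                {"relative_effect_treatment_intensity": rr})
            ta = mcs.run_cohort(config, "A")
            return tb.discounted_qalys - ta.discounted_qalys
        assert gain(1.0) <= gain(0.9) <= gain(0.7)

    def test_outcomes_nonincreasing_in_discount_rate(self):
        lo = quiet_markov_config(horizon=20, discount_rate_qalys=0.01)
        hi = quiet_markov_config(horizon=20, discount_rate_qalys=0.06)
        assert (mcs.run_cohort(hi, "A").discounted_qalys
                < mcs.run_cohort(lo, "A").discounted_qalys)

    def test_scalar_overrides_only(self):
        with pytest.raises(PSADomainError, match="scalar"):
            mcs.run_cohort(mcs.default_config(), "A",
                           {"utility_well": np.array([0.8, 0.9])})


class TestSamplePSA:
    def test_all_deterministic_zero_variance(self):
        config = mcs.default_config()
        psa = mcs.sample_psa(config, specs=[], n_draws=5, seed=0)
        inb = compute_inb(psa)
        assert np.var(inb.values) == 0.0
        assert psa.n_params == 0

    def test_seed_reproducibility_bitwise(self):
        config = mcs.default_config()
        specs = mcs.default_parameter_specs(config)
        a = mcs.sample_psa(config, specs, n_draws=10, seed=42)
        b = mcs.sample_psa(config, specs, n_draws=10, seed=42)
        np.testing.assert_array_equal(a.draws, b.draws)
        np.testing.assert_array_equal(a.intervention.qalys, b.intervention.qalys)
        np.testing.assert_array_equal(a.comparator.costs, b.comparator.costs)

    def test_invalid_hyperparameters(self):
        config = mcs.default_config()
        bad = [mcs.ParameterSpec("utility_well",
                                 distribution={"family": "beta", "alpha": -1, "beta": 2})]
        with pytest.raises(PSADomainError):
            mcs.sample_psa(config, bad, n_draws=5, seed=0)

    def test_case_study_dimensions(self, case_study_psa):
        assert case_study_psa.n_params == 20
        assert case_study_psa.k == 13_000.0
        assert case_study_psa.incident_population == 24_799.0

    def test_ae_probabilities_correlated_and_on_simplex(self, case_study_psa):
        psa = case_study_psa
        for arm in ("A", "B"):
            total = sum(psa.column(f"prob_ae_class{c}_{arm}")
                        for c in ("2a", "2b", "3"))
            assert np.all(total <= 1.0)
        # arms share underlying uniforms, so the same class correlates across arms
        r = np.corrcoef(psa.column("prob_ae_class2a_A"),
                        psa.column("prob_ae_class2a_B"))[0, 1]
        assert r > 0.5

    def test_ae_marginal_means_match_dirichlet(self, case_study_psa):
        alpha = mcs.default_config().ae_alpha["A"]
        expected = alpha["class2a"] / sum(alpha.values())
        observed = case_study_psa.column("prob_ae_class2a_A").mean()
        assert observed == pytest.approx(expected, rel=0.05)

    def test_batch_matches_scalar_runs(self, case_study_psa):
        psa = case_study_psa
        config = mcs.default_config()
        for i in (0, 17):
            overrides = {name: psa.draws[i, j]
                         for j, name in enumerate(psa.param_names)}
            trace = mcs.run_cohort(config, "B", overrides)
            assert trace.discounted_qalys == pytest.approx(
                psa.intervention.qalys[i], abs=1e-9)
            assert trace.discounted_costs == pytest.approx(
                psa.intervention.costs[i], abs=1e-6)

    def test_intervention_dominates_by_default(self, case_study_psa):
        inb = compute_inb(case_study_psa)
        assert np.mean(inb.values > 0) > 0.9


class TestLinearGaussianToy:
    def test_sample_mean_converges(self):
        means, sds = [0.2, -0.1, 0.3], [1.0, 0.5, 0.2]
        psa = mcs.linear_gaussian_toy(means, sds, 50_000, seed=3)
        inb = compute_inb(psa)
        sigma = np.sqrt(np.sum(np.square(sds)))
        assert abs(inb.mean() - sum(means)) < 3 * sigma / np.sqrt(50_000)

    def test_draws_sum_to_inb_exactly(self):
        psa = mcs.linear_gaussian_toy([0.0, 0.0], [1.0, 1.0], 100, seed=4)
        np.testing.assert_allclose(psa.draws.sum(axis=1),
                                   compute_inb(psa).values, atol=1e-12)

    def test_closed_forms(self):
        assert mcs.toy_evpi([0.0, 0.0], [1.0, 0.0]) == pytest.approx(
            0.3989422804014327, abs=1e-12)
        assert mcs.toy_evppi([0.0, 0.0], [1.0, 0.0], [0]) == pytest.approx(
            0.3989422804014327, abs=1e-12)
        assert mcs.toy_evppi([0.0, 0.0], [1.0, 0.0], [1]) == 0.0
        assert mcs.toy_evpi([1.0], [0.0]) == 0.0  # no uncertainty

    def test_certain_decision_limit(self):
        assert mcs.toy_evpi([50.0], [1.0]) < 1e-12

    def test_closed_form_matches_monte_carlo(self):
        # brute-force check of the normal partial expectation
        x = np.random.default_rng(9).normal(0.3, 1.2, size=400_000)
        mc = np.mean(np.maximum(0.0, x)) - max(0.0, x.mean())
        assert mcs.toy_evpi([0.3], [1.2]) == pytest.approx(mc, abs=0.005)

    def test_negative_sd_rejected(self):
        with pytest.raises(PSADomainError):
            mcs.linear_gaussian_toy([0.0], [-1.0], 10, seed=0)


class TestConfigIO:
    def test_yaml_round_trip(self, tmp_path):
        config = mcs.default_config()
        path = tmp_path / "model.yaml"
        mcs.config_to_yaml(config, path)
        back = mcs.config_from_yaml(path)
        assert back.values == pytest.approx(config.values)
        assert back.k == config.k
        assert back.horizon == config.horizon

    def test_partial_override(self, tmp_path):
        path = tmp_path / "model.yaml"
        path.write_text("values:\n  utility_well: 0.5\nk: 20000\n")
        config = mcs.config_from_yaml(path)
        assert config.values["utility_well"] == 0.5
        assert config.k == 20_000
        # untouched values come from the bundled defaults
        assert config.values["cost_metastatic_yearly"] == \
            mcs.default_config().values["cost_metastatic_yearly"]

    def test_invalid_utility_rejected(self):
        with pytest.raises(PSADomainError):
            quiet_markov_config({"utility_well": 1.5})
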
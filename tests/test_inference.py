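"""Likelihood, priors, MCMC fitting and reversible-jump selection."""

import numpy as np
import pandas as pd
import pytest

import igparasitoid as ig
from igparasitoid import ChainConfig, ModelSpec, RJConfig, Trial, default_priors, fit, log_likelihood, select
from igparasitoid.inference import PosteriorResult, model_average, rj_accept_logratio
from igparasitoid.io import table_to_trials
from igparasitoid.priors import HalfNormal, Normal, Uniform

FRII_SPEC = ModelSpec.from_string("FRII:NHD:M0:R0:Cabs")
FRII_VALUES = {"b_1": 0.25, "b_2": 0.15, "H_1": 0.03, "H_2": 0.08}


def _frii_trials(seed=5, baseline_replicates=8):
    config = ig.SimulationConfig(
        spec=FRII_SPEC, values=FRII_VALUES, seed=seed, baseline_replicates=baseline_replicates
    )
    table, _ = ig.simulate_experiment(config)
    return table_to_trials(table, ("species1", "species2"))


class TestLogLikelihood:
    def test_single_trial_binomial_mass(self):
        # expected emergence 5 of 10 -> Binomial(10, 0.5) mass at 5 = 252/1024
        spec = ModelSpec.from_string("FRI:NHD:M0:R0:Cabs")
        trial = Trial("t1", first=1, second=None, n_offered=10, emerged_first=5)
        ll = log_likelihood(spec, {"b_1": 0.5, "b_2": 0.1}, [trial])
        assert ll == pytest.approx(np.log(252) - 10 * np.log(2), abs=1e-9)

    def test_observed_rate_maximizes_single_trial_likelihood(self):
        spec = ModelSpec.from_string("FRI:NHD:M0:R0:Cabs")
        trial = Trial("t1", first=1, second=None, n_offered=20, emerged_first=8)
        lls = {b: log_likelihood(spec, {"b_1": b, "b_2": 0.1}, [trial]) for b in np.linspace(0.05, 0.95, 19)}
        assert max(lls, key=lls.get) == pytest.approx(0.4)

    def test_empty_trial_set(self):
        assert log_likelihood(FRII_SPEC, FRII_VALUES, []) == 0.0

    def test_trinomial_option_close_to_binomial_at_low_rates(self):
        trials = _frii_trials()
        b = log_likelihood(FRII_SPEC, FRII_VALUES, trials, kind="binomial")
        t = log_likelihood(FRII_SPEC, FRII_VALUES, trials, kind="trinomial")
        assert np.isfinite(b) and np.isfinite(t)
        assert b != t

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            Trial("bad", first=1, second=2, n_offered=10, emerged_first=7, emerged_second=5)
        with pytest.raises(ValueError):
            Trial("bad", first=1, second=None, n_offered=10, emerged_first=-1)


class TestPriors:
    def test_base_type_one_gets_two_unit_uniforms(self):
        priors = default_priors(ModelSpec.from_string("FRI:NHD:M0:R0:Cabs"))
        assert set(priors) == {"b_1", "b_2"}
        assert all(isinstance(p, Uniform) for p in priors.values())

    def test_multiparasitism_index_prior_is_flat(self):
        priors = default_priors(ModelSpec.from_string("FRIII_G:NHD:M0:R0:Csup"))
        assert np.exp(priors["theta_1"].logpdf(0.5)) == pytest.approx(1.0)

    def test_competition_location_prior_scale(self):
        priors = default_priors(ModelSpec.from_string("FRII:NHD:M0:R0:Cbasic"))
        mu2 = priors["mu_2"]
        assert isinstance(mu2, Normal)
        assert mu2.logpdf(0.0) - mu2.logpdf(10.0) == pytest.approx(0.5)

    def test_deviation_priors_are_half_normal(self):
        priors = default_priors(ModelSpec.from_string("FRII:NHD:M0:R0:Csup"))
        assert isinstance(priors["sigma_2"], HalfNormal)
        assert priors["sigma_2"].logpdf(-0.1) == -np.inf


class TestFit:
    def test_same_seed_gives_identical_draws(self):
        trials = _frii_trials(baseline_replicates=2)
        config = ChainConfig(iterations=50, burn_in=50, seed=9)
        a = fit(FRII_SPEC, trials, config)
        b = fit(FRII_SPEC, trials, config)
        pd.testing.assert_frame_equal(a.draws, b.draws)

    def test_recovers_type_two_parameters(self):
        """Posterior means land within 2 posterior sd of the generating truth."""
        trials = _frii_trials(seed=5, baseline_replicates=8)
        result = fit(FRII_SPEC, trials, ChainConfig(iterations=600, burn_in=600, seed=2))
        for name, truth in FRII_VALUES.items():
            mean = result.summary.loc[name, "mean"]
            sd = result.summary.loc[name, "sd"]
            assert abs(mean - truth) < 2.5 * max(sd, 1e-3), name

    def test_flat_data_pushes_attack_rate_to_zero(self):
        spec = ModelSpec.from_string("FRI:NHD:M0:R0:Cabs")
        trials = [
            Trial(f"t{i}", first=1, second=None, n_offered=50, emerged_first=0) for i in range(10)
        ] + [Trial(f"u{i}", first=2, second=None, n_offered=50, emerged_first=0) for i in range(10)]
        result = fit(spec, trials, ChainConfig(iterations=400, burn_in=400, seed=4))
        assert result.summary.loc["b_1", "q97.5"] < 0.05
        assert result.summary.loc["b_2", "q97.5"] < 0.05

    def test_summary_reports_split_rhat(self):
        trials = _frii_trials(baseline_replicates=2)
        result = fit(FRII_SPEC, trials, ChainConfig(iterations=200, burn_in=200, seed=1, chains=2))
        assert result.summary["rhat"].notna().all()

    def test_needs_trials(self):
        with pytest.raises(ValueError):
            fit(FRII_SPEC, [], ChainConfig())


class TestReversibleJump:
    def test_zero_penalty_equal_dimensions_is_plain_metropolis(self):
        assert rj_accept_logratio(-10.0, 5, -12.0, 5, penalty=0.0) == pytest.approx(2.0)
        # the penalty only enters through the dimension difference
        assert rj_accept_logratio(-10.0, 6, -10.0, 5, penalty=2.0) == pytest.approx(-2.0)

    def test_duplicated_model_splits_weight_evenly(self):
        trials = _frii_trials(baseline_replicates=2)
        specs = [FRII_SPEC, ModelSpec.from_string("FRII:NHD:M0:R0:Cabs")]
        result = select(specs, trials, RJConfig(outer_iterations=400, burn_in=100, inner_sweeps=2, seed=3))
        weights = list(result.model_weights.values())
        assert sum(weights) == pytest.approx(1.0, abs=1e-9)
        assert weights[0] == pytest.approx(0.5, abs=0.15)

    def test_parsimony_penalty_prefers_the_generating_nested_model(self):
        """Data simulated from the simpler model gives it the majority weight."""
        trials = _frii_trials(seed=21, baseline_replicates=4)
        bigger = ModelSpec.from_string("FRII:NHD:M1:R1:Cabs")
        result = select(
            [FRII_SPEC, bigger], trials, RJConfig(outer_iterations=300, burn_in=100, inner_sweeps=3, seed=6)
        )
        assert result.model_weights[FRII_SPEC.to_string()] > 0.5

    def test_needs_at_least_two_models(self):
        with pytest.raises(ValueError):
            select([FRII_SPEC], _frii_trials(baseline_replicates=2), RJConfig())


class TestModelAverage:
    def _fake_rj_result(self, frames, weights):
        draws = pd.concat(frames, ignore_index=True)
        return PosteriorResult(draws, pd.DataFrame(), None, 0, RJConfig(), weights)

    def test_single_model_passthrough(self):
        frame = pd.DataFrame({"model": ["A"] * 4, "loglik": 0.0, "b_1": [0.1, 0.2, 0.3, 0.4]})
        result = self._fake_rj_result([frame], {"A": 1.0})
        avg = model_average(result)
        assert avg.loc["b_1", "mean"] == pytest.approx(0.25)
        assert avg.loc["b_1", "weight"] == pytest.approx(1.0)

    def test_equal_weight_pooling_averages_means(self):
        fa = pd.DataFrame({"model": ["A"] * 2, "loglik": 0.0, "b_1": [0.1, 0.1], "m": [np.nan] * 2})
        fb = pd.DataFrame({"model": ["B"] * 2, "loglik": 0.0, "b_1": [0.3, 0.3], "m": [0.2, 0.2]})
        avg = model_average(self._fake_rj_result([fa, fb], {"A": 0.5, "B": 0.5}))
        assert avg.loc["b_1", "mean"] == pytest.approx(0.2)
        # parameter present in only one visited model keeps its own summary
        assert avg.loc["m", "mean"] == pytest.approx(0.2)
        assert avg.loc["m", "weight"] == pytest.approx(0.5)

    def test_requires_rj_result(self):
        with pytest.raises(ValueError):
            model_average(PosteriorResult(pd.DataFrame(), pd.DataFrame(), None, 0, ChainConfig()))
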
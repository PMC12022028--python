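import numpy as np
import pytest

from hiercausal.experiments import exp1_condition
from hiercausal.fitting import (
    FitResult,
    WeightLikelihood,
    aic_compare,
    bootstrap_pvalue,
    dataset_log_likelihood,
    fit_mle,
    sample_posterior,
    variance_explained,
)
from hiercausal.io import TrialTable, simulate_trials
from hiercausal.model import ModelParams
from hiercausal.readout import POSTERIOR_SAMPLING, response_distribution

import pandas as pd

GRID = [exp1_condition(d, True, 5) for d in (0.0, 5.0, 20.0, 45.0)]


def _trials(params, n, rng=0, strategy=POSTERIOR_SAMPLING):
    return simulate_trials(GRID, params, strategy, n, rng=rng)


class TestDatasetLikelihood:
    def test_mode_beats_antimode(self, params):
        cond = GRID[3]
        rd = response_distribution(cond, params, POSTERIOR_SAMPLING, 5)
        grid = np.arange(0.0, 360.0, 1.0)
        dens = rd.pdf(grid)
        mode, antimode = grid[np.argmax(dens)], grid[np.argmin(dens)]

        def one(report):
            df = pd.DataFrame(
                [["o", "1", cond.label, 45.0, True, 5, report]],
                columns=[
                    "observer",
                    "session",
                    "condition",
                    "center_dir_deg",
                    "surround_moving",
                    "n_surround_patches",
                    "report_deg",
                ],
            )
            return dataset_log_likelihood(
                params, TrialTable.from_frame(df), POSTERIOR_SAMPLING, 5
            )

        assert one(float(mode)) > one(float(antimode))

    def test_additivity_under_duplication(self, params):
        trials = _trials(params, 10)
        doubled = TrialTable.from_frame(
            pd.concat([trials.df, trials.df], ignore_index=True)
        )
        l1 = dataset_log_likelihood(params, trials, POSTERIOR_SAMPLING, 5)
        l2 = dataset_log_likelihood(params, doubled, POSTERIOR_SAMPLING, 5)
        assert np.isclose(l2, 2.0 * l1, rtol=1e-12)

    def test_truth_beats_perturbed_sigmas(self, params):
        # doubling the observation noise lowers the likelihood of
        # self-generated data in nearly every replicate
        perturbed = params.with_updates(
            sigma_center=2 * params.sigma_center,
            sigma_surround=2 * params.sigma_surround,
        )
        wins = 0
        n_rep = 12
        for rep in range(n_rep):
            trials = _trials(params, 40, rng=1000 + rep)
            lt = dataset_log_likelihood(params, trials, POSTERIOR_SAMPLING, 5)
            lp = dataset_log_likelihood(perturbed, trials, POSTERIOR_SAMPLING, 5)
            wins += lt > lp
        assert wins >= n_rep - 1

    def test_cached_weight_likelihood_matches_direct(self, params):
        trials = _trials(params, 15)
        wl = WeightLikelihood(trials, params, POSTERIOR_SAMPLING, 5)
        direct = dataset_log_likelihood(params, trials, POSTERIOR_SAMPLING, 5)
        assert np.isclose(wl(params), direct, rtol=1e-5)
        other = params.with_updates(alpha_center=0.5, beta=0.2, lambda_lapse=0.1)
        direct_other = dataset_log_likelihood(other, trials, POSTERIOR_SAMPLING, 5)
        assert np.isclose(wl(other), direct_other, rtol=1e-5)


class TestMLE:
    def test_recovers_alpha(self, params):
        trials = _trials(params, 120, rng=42)
        fit = fit_mle(
            trials,
            POSTERIOR_SAMPLING,
            free=("alpha",),
            init=ModelParams(alpha_center=0.6, alpha_surround=0.6),
            quad_order=5,
        )
        assert abs(fit.params.alpha_center - 0.9) < 0.1
        assert fit.converged
        assert np.isclose(fit.aic, 2 * 1 - 2 * fit.log_likelihood)

    def test_degenerate_identical_reports(self, params):
        df = pd.DataFrame(
            [["o", "1", GRID[0].label, 0.0, True, 5, 0.0]] * 20,
            columns=[
                "observer",
                "session",
                "condition",
                "center_dir_deg",
                "surround_moving",
                "n_surround_patches",
                "report_deg",
            ],
        )
        trials = TrialTable.from_frame(df)
        fit = fit_mle(trials, POSTERIOR_SAMPLING, free=("alpha",), quad_order=3)
        assert np.isfinite(fit.aic)

    def test_empty_data_rejected(self, params):
        empty = TrialTable.from_frame(_trials(params, 2).df.iloc[0:0])
        with pytest.raises(ValueError):
            fit_mle(empty, POSTERIOR_SAMPLING)


class TestPosteriorSampling:
    def test_prior_only_matches_beta_uniform(self, params):
        empty = TrialTable.from_frame(_trials(params, 2).df.iloc[0:0])
        fit = sample_posterior(
            empty,
            POSTERIOR_SAMPLING,
            free=("alpha",),
            n_chains=8,
            n_samples=800,
            thin=4,
            seed=11,
        )
        flat = np.asarray(fit.samples["alpha"]).ravel()
        # Beta(1,1): mean 1/2, sd 1/sqrt(12)
        assert abs(flat.mean() - 0.5) < 0.05
        assert abs(flat.std() - 1.0 / np.sqrt(12.0)) < 0.04

    def test_recovery_run_diagnostics(self, params):
        trials = _trials(params, 80, rng=5)
        fit = sample_posterior(
            trials,
            POSTERIOR_SAMPLING,
            free=("alpha",),
            init=ModelParams(alpha_center=0.7, alpha_surround=0.7),
            n_chains=6,
            n_samples=500,
            thin=10,
            seed=2,
        )
        assert abs(fit.params.alpha_center - 0.9) < 0.12
        lo, hi = fit.credible_interval("alpha")
        assert lo < hi
        # thinning by 10 leaves low residual autocorrelation
        chains = np.asarray(fit.samples["alpha"])
        ac = np.mean(
            [np.corrcoef(c[:-1], c[1:])[0, 1] for c in chains]
        )
        assert ac < 0.5
        assert "alpha" in fit.rhat and "alpha" in fit.ess


class TestAICCompare:
    def _result(self, aic, label, h="x"):
        return FitResult(
            params=ModelParams(),
            free=("alpha",),
            strategy=POSTERIOR_SAMPLING,
            log_likelihood=-0.5 * aic + 1,
            aic=aic,
            n_params=1,
            converged=True,
            data_hash=h,
            label=label,
        )

    def test_identical_fits_zero_delta(self):
        table = aic_compare([self._result(10.0, "a"), self._result(10.0, "b")])
        assert np.allclose(table["delta_aic"], 0.0)

    def test_extra_parameter_costs_two(self):
        a = self._result(10.0, "small")
        b = self._result(10.0, "big")
        b.n_params += 1
        b.aic += 2.0
        table = aic_compare([a, b])
        assert table.iloc[0]["model"] == "small"
        assert np.isclose(table.iloc[1]["delta_aic"], 2.0)

    def test_mismatched_data_rejected(self):
        with pytest.raises(ValueError):
            aic_compare([self._result(1.0, "a", "x"), self._result(2.0, "b", "y")])


class TestVarianceExplained:
    def test_self_fit_is_high(self, params):
        trials = _trials(params, 250, rng=8)
        ve = variance_explained(params, trials, POSTERIOR_SAMPLING, quad_order=5)
        assert ve > 90.0

    def test_uniform_model_explains_nothing(self, params):
        trials = _trials(params, 80, rng=9)
        uniform = ModelParams(lambda_lapse=1.0, kappa_lapse=0.0)
        ve = variance_explained(uniform, trials, POSTERIOR_SAMPLING, quad_order=3)
        assert ve < 30.0


class TestBootstrapPValue:
    def test_no_exceedances(self):
        assert np.isclose(
            bootstrap_pvalue(np.full(5000, -1.0), 0.0), 1.0 / 5002.0
        )

    def test_all_exceedances(self):
        n = 100
        assert np.isclose(
            bootstrap_pvalue(np.ones(n), 0.0), (n + 1) / (n + 2)
        )

    def test_symmetric_near_half(self, rng):
        s = rng.normal(size=20000)
        assert abs(bootstrap_pvalue(s, 0.0) - 0.5) < 0.02

    def test_sides(self):
        s = np.array([-1.0, 2.0, 3.0])
        assert bootstrap_pvalue(s, 0.0, "greater") == 3 / 5
        assert bootstrap_pvalue(s, 0.0, "less") == 2 / 5
        with pytest.raises(ValueError):
            bootstrap_pvalue(s, 0.0, "both")
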
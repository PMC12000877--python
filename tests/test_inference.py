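"""Likelihoods, MLE fitting, BIC model selection and profile CIs."""

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import chi2, poisson

from burstcycle.age_model import AgeModelParams, nb_at_age, solve_moments
from burstcycle.inference import (
    FitResult,
    ModelSpec,
    OptimizerConfig,
    bic,
    fit_age_model,
    fit_mle,
    fit_steady_models,
    negloglik_age,
    negloglik_steady,
    profile_ci,
    select_model,
    steady_ratio_ci,
)
from burstcycle.synthetic import simulate_counts


class TestSteadyLikelihood:
    def test_poisson_closed_form_value(self):
        # -sum log Pois(m; 2) over counts [1, 2, 3]; frozen from
        # 3*2 - 6*log 2 + log(1! 2! 3!)
        nll = negloglik_steady(ModelSpec("Poisson"), {"rho": 2.0}, [1, 2, 3])
        assert nll == pytest.approx(4.326023566428326, abs=1e-10)

    def test_empty_counts(self):
        assert negloglik_steady(ModelSpec("NB"), {"f": 1.0, "p": 0.5}, []) == 0.0

    def test_two_copy_nb_equals_closed_form(self):
        rng = np.random.default_rng(0)
        counts = rng.negative_binomial(3.0, 0.3, size=500)
        v2 = negloglik_steady(ModelSpec("NB", n_copies=2), {"f": 1.5, "p": 0.3}, counts)
        v1 = negloglik_steady(ModelSpec("NB"), {"f": 3.0, "p": 0.3}, counts)
        assert v2 == pytest.approx(v1, abs=1e-10)

    def test_telegraph_convolution_against_direct_pmf(self):
        from burstcycle.steady_state import SteadyStateParams, telegraph_pmf, convolve_copies, Pmf

        counts = np.array([0, 2, 5, 9, 1])
        params = {"sigma0": 3.0, "sigma1": 1.0, "rho": 8.0}
        nll = negloglik_steady(ModelSpec("Telegraph", n_copies=2), params, counts)
        allele = telegraph_pmf(SteadyStateParams(**params))
        total = convolve_copies(Pmf(allele.probs), 2).probs
        expected = -np.sum(np.log(total[counts]))
        assert nll == pytest.approx(expected, rel=1e-8)

    def test_zero_inflation_applied_to_total(self):
        counts = np.array([0, 0, 3])
        spec = ModelSpec("ZIP", n_copies=2)
        params = {"rho": 1.0, "p0": 0.25}
        p0_total = 0.25 + 0.75 * np.exp(-2.0)
        expected = -2 * np.log(p0_total) - np.log(0.75 * poisson.pmf(3, 2.0))
        assert negloglik_steady(spec, params, counts) == pytest.approx(expected, rel=1e-10)


class TestAgeLikelihood:
    def test_single_bin_reduces_to_steady_nb(self, ref_age_params):
        p = ref_age_params
        theta = np.full(200, 0.25)
        rng = np.random.default_rng(1)
        traj = solve_moments(p, np.array([0.25]))
        dist = nb_at_age(traj.mean[0], traj.variance[0])
        counts = dist.rvs(200, rng)
        got = negloglik_age(p, theta, counts)
        expected = -dist.logpmf(counts).sum()
        assert got == pytest.approx(expected, rel=1e-10)

    def test_duplicated_data_doubles(self, ref_age_params, theta_cells):
        counts = simulate_counts(ref_age_params, theta_cells, seed=2)
        v1 = negloglik_age(ref_age_params, theta_cells, counts)
        v2 = negloglik_age(
            ref_age_params,
            np.concatenate([theta_cells, theta_cells]),
            np.concatenate([counts, counts]),
        )
        assert v2 == pytest.approx(2.0 * v1, rel=1e-12)

    def test_truth_beats_perturbations(self, ref_age_params, theta_cells):
        counts = simulate_counts(ref_age_params, theta_cells, seed=3)
        base = negloglik_age(ref_age_params, theta_cells, counts)
        rng = np.random.default_rng(0)
        for _ in range(10):
            scale = np.exp(rng.normal(0.0, 0.35, size=4))
            pert = AgeModelParams(
                f1=ref_age_params.f1 * scale[0],
                f2=ref_age_params.f2 * scale[1],
                rho1=ref_age_params.rho1 * scale[2],
                rho2=ref_age_params.rho2 * scale[3],
                betas=tuple(b + rng.normal(0, 0.3) for b in ref_age_params.betas),
                d=ref_age_params.d,
                T=ref_age_params.T,
            )
            assert negloglik_age(pert, theta_cells, counts) >= base


class TestFitMle:
    def test_poisson_is_sample_mean(self):
        fit = fit_mle(ModelSpec("Poisson"), np.array([1, 2, 3]))
        assert fit.params["rho"] == pytest.approx(2.0)
        fit2 = fit_mle(ModelSpec("Poisson", n_copies=2), np.array([2, 4, 6]))
        assert fit2.params["rho"] == pytest.approx(2.0)

    def test_nb_parameter_recovery(self):
        rng = np.random.default_rng(10)
        counts = rng.negative_binomial(2.0, 1 / (1 + 3.0), size=5000)
        fit = fit_mle(ModelSpec("NB"), counts, OptimizerConfig(seed=4))
        b = (1 - fit.params["p"]) / fit.params["p"]
        assert fit.params["f"] == pytest.approx(2.0, rel=0.10)
        assert b == pytest.approx(3.0, rel=0.10)

    def test_refit_from_optimum_does_not_improve(self):
        rng = np.random.default_rng(11)
        counts = rng.negative_binomial(2.0, 1 / (1 + 3.0), size=2000)
        spec = ModelSpec("NB")
        fit = fit_mle(spec, counts, OptimizerConfig(seed=5))
        refit = fit_mle(
            spec, counts,
            OptimizerConfig(n_restarts=1, use_de=False, inits=[fit.params], seed=6),
        )
        assert refit.loglik <= fit.loglik + 1e-6

    def test_bic_identity_holds(self):
        rng = np.random.default_rng(12)
        counts = rng.poisson(4.0, size=300)
        fit = fit_mle(ModelSpec("Poisson"), counts)
        assert fit.bic == pytest.approx(bic(fit.loglik, fit.k, fit.n), abs=1e-12)

    def test_age_model_ratio_recovery(self, ref_age_params, theta_cells):
        counts = simulate_counts(ref_age_params, theta_cells, seed=4)
        fit = fit_age_model(theta_cells, counts, d=ref_age_params.d)
        q_f = fit.params["f2"] / fit.params["f1"]
        assert q_f == pytest.approx(0.5, rel=0.15)


class TestBicLadder:
    def test_arithmetic(self):
        assert bic(-100.0, 2, 100) == pytest.approx(-2 * -100.0 + 2 * np.log(100))
        assert bic(-50.0, 0, 10) == pytest.approx(100.0)

    @staticmethod
    def _stub(family, bic_value):
        spec = ModelSpec(family)
        return FitResult(spec, {}, np.zeros(spec.k), 0.0, 1, spec.k, bic_value, 0, 0)

    def test_base_case_keeps_simplest(self):
        fits = {f: self._stub(f, 100.0 - i) for i, f in
                enumerate(["Poisson", "ZIP", "NB", "ZINB", "Telegraph", "ZITelegraph"])}
        assert select_model(fits).family == "Poisson"

    def test_ladder_advances_on_strong_evidence(self):
        bics = {"Poisson": 500.0, "ZIP": 495.0, "NB": 300.0,
                "ZINB": 303.0, "Telegraph": 301.0, "ZITelegraph": 305.0}
        fits = {f: self._stub(f, b) for f, b in bics.items()}
        assert select_model(fits).family == "NB"

    def test_invariant_to_weakly_better_complex_model(self):
        bics = {"Poisson": 100.0, "NB": 95.0}
        fits = {f: self._stub(f, b) for f, b in bics.items()}
        assert select_model(fits).family == "Poisson"
        fits["Telegraph"] = self._stub("Telegraph", 92.0)  # delta 8 <= 10
        assert select_model(fits).family == "Poisson"


class TestProfileCi:
    def test_poisson_matches_analytic_lr_interval(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(4.2, size=200)
        spec = ModelSpec("Poisson")
        fit = fit_mle(spec, counts)
        ci = profile_ci(spec, counts, fit, "rho", alpha=0.05)
        ll = lambda rho: np.sum(poisson.logpmf(counts, rho))
        mean = counts.mean()
        thresh = ll(mean) - 0.5 * chi2.ppf(0.95, 1)
        lo = brentq(lambda r: ll(r) - thresh, 1e-6, mean)
        hi = brentq(lambda r: ll(r) - thresh, mean, 3 * mean)
        assert ci.lower == pytest.approx(lo, rel=1e-3)
        assert ci.upper == pytest.approx(hi, rel=1e-3)

    def test_alpha_one_degenerates_to_mle(self):
        counts = np.array([1, 2, 3, 4])
        spec = ModelSpec("Poisson")
        fit = fit_mle(spec, counts)
        ci = profile_ci(spec, counts, fit, "rho", alpha=1.0)
        assert ci.lower == ci.upper == pytest.approx(fit.params["rho"])

    def test_intervals_are_nested(self):
        rng = np.random.default_rng(2)
        counts = rng.negative_binomial(2.0, 1 / (1 + 3.0), size=400)
        spec = ModelSpec("NB")
        fit = fit_mle(spec, counts, OptimizerConfig(n_restarts=2, seed=1))
        ci95 = profile_ci(spec, counts, fit, "f", alpha=0.05)
        ci99 = profile_ci(spec, counts, fit, "f", alpha=0.01)
        assert ci99.lower <= ci95.lower <= ci95.upper <= ci99.upper


class TestPredictionProfile:
    def test_identity_reduces_to_profile(self):
        from burstcycle.inference import _make_objective, prediction_profile_ci

        rng = np.random.default_rng(3)
        counts = rng.negative_binomial(2.0, 1 / (1 + 3.0), size=500)
        spec = ModelSpec("NB")
        fit = fit_mle(spec, counts, OptimizerConfig(n_restarts=2, seed=2))
        direct = profile_ci(spec, counts, fit, "f", alpha=0.05)
        nll = _make_objective(spec, spec.prepare(counts))
        via_ppl = prediction_profile_ci(
            nll, fit.x_trans.copy(), spec.bounds_trans(),
            eliminate_index=0, solve_eliminated=lambda z, x: np.log(z),
            z_hat=fit.params["f"], alpha=0.05, z_bounds=(1e-5, 1e5), target="f",
        )
        assert via_ppl.lower == pytest.approx(direct.lower, rel=5e-3)
        assert via_ppl.upper == pytest.approx(direct.upper, rel=5e-3)

    def test_symmetric_phases_contain_unit_ratio(self):
        rng = np.random.default_rng(4)
        counts = rng.negative_binomial(2 * 2.0, 1 / (1 + 3.0), size=2000)
        fit = fit_mle(ModelSpec("NB", n_copies=2), counts, OptimizerConfig(n_restarts=2, seed=3))
        ci = steady_ratio_ci(fit, fit, counts, counts, which="f")
        assert ci.lower <= 1.0 <= ci.upper

    def test_two_phase_ratio_covers_truth(self):
        rng = np.random.default_rng(5)
        c1 = rng.negative_binomial(2 * 2.0, 1 / (1 + 3.0), size=3000)
        c2 = rng.negative_binomial(4 * 1.0, 1 / (1 + 3.0), size=3000)  # Q_f = 0.5
        f1 = fit_mle(ModelSpec("NB", n_copies=2), c1, OptimizerConfig(n_restarts=2, seed=4))
        f2 = fit_mle(ModelSpec("NB", n_copies=4), c2, OptimizerConfig(n_restarts=2, seed=5))
        ci = steady_ratio_ci(f1, f2, c1, c2, which="f")
        assert ci.lower <= 0.5 <= ci.upper
        assert ci.upper - ci.lower < 0.5


def test_fit_steady_models_returns_ladder():
    rng = np.random.default_rng(6)
    counts = rng.poisson(6.0, size=300)
    fits = fit_steady_models(
        counts, 2, OptimizerConfig(n_restarts=1, de_maxiter=10, de_popsize=6, seed=0),
        families=["Poisson", "NB"],
    )
    assert set(fits) == {"Poisson", "NB"}
    assert select_model(fits).family == "Poisson"
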
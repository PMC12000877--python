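"""The piecewise age-dependent moment model: production rates, the
cyclo-stationary mean/variance solution and its oracles."""

import numpy as np
import pytest

from burstcycle.age_model import (
    AgeDistribution,
    AgeModelParams,
    burst_size_at_age,
    division_boundary_map,
    nb_at_age,
    phase_averaged_burst_size,
    production_rate,
    solve_mean_trajectory,
    solve_moments,
)
from burstcycle.age_model import _eval_terms, _mean_forcings, _propagate_cycle
from burstcycle.steady_state import nb_pmf


def flat_params(f2=1.0, dT=200.0, rho=1.0, T=13.25, **kw):
    return AgeModelParams(
        f1=1.0, f2=f2, rho1=rho, rho2=rho, betas=(0, 0, 0, 0), d=dT / T, T=T, **kw
    )


class TestProductionAndBurstSize:
    def test_segment_selection_is_half_open(self):
        p = flat_params()
        # exactly at the replication age the post-replication branch applies
        assert production_rate(p.theta_r, p) == pytest.approx(p.f2 * p.rho2)

    def test_continuity_with_shared_exponent(self):
        p = AgeModelParams(1.0, 1.0, 2.0, 2.0, (0.5, 0.5, 0.5, 0.5), d=0.1)
        lo = production_rate(p.theta_g1 - 1e-9, p)
        hi = production_rate(p.theta_g1 + 1e-9, p)
        assert lo == pytest.approx(hi, rel=1e-6)

    def test_flat_scaling(self):
        p = flat_params(f2=0.5, rho=3.0)
        assert production_rate(0.1, p) == pytest.approx(3.0)
        assert production_rate(0.9, p) == pytest.approx(1.5)

    def test_burst_size_examples(self):
        p = AgeModelParams(1, 1, 2.0, 2.0, (np.log(2), 0, 0, 0), d=0.1)
        assert burst_size_at_age(0.0, p) == pytest.approx(2.0)
        assert burst_size_at_age(0.1, p) == pytest.approx(2.0 * 2**0.1)
        pf = AgeModelParams(1, 1, 2.0, 2.0, (np.log(2), 0, 0, 0), d=0.1, variant="frequency")
        assert burst_size_at_age(0.1, pf) == pytest.approx(2.0)

    def test_age_domain_error(self):
        with pytest.raises(ValueError):
            production_rate(1.0, flat_params())


class TestMeanTrajectory:
    def test_quasi_steady_levels(self):
        # fast degradation: interior means sit at copies * f * rho / d
        p = flat_params()
        traj = solve_mean_trajectory(p)
        d = p.d
        g1_interior = traj.mean[(traj.theta > 0.05) & (traj.theta < p.theta_g1)]
        g2m_interior = traj.mean[traj.theta > p.theta_s + 0.05]
        assert np.allclose(g1_interior, 2.0 / d, rtol=1e-3)
        assert np.allclose(g2m_interior, 4.0 / d, rtol=1e-3)

    def test_halved_frequency_compensates(self):
        # f2 = f1/2 restores the G1 expression level after replication
        traj = solve_mean_trajectory(flat_params(f2=0.5))
        m_g1 = traj.mean[np.isclose(traj.theta, 0.10)][0]
        m_g2m = traj.mean[np.isclose(traj.theta, 0.80)][0]
        assert m_g2m == pytest.approx(m_g1, rel=1e-3)

    def test_fixed_point_equals_iterated_cycle_map(self, ref_age_params):
        p = ref_age_params
        traj = solve_mean_trajectory(p)
        m = 0.0
        for _ in range(60):
            _, end = _propagate_cycle(
                p, p.dT, lambda s, t0: _mean_forcings(p, s, t0), m
            )
            m = 0.5 * end
        assert m == pytest.approx(traj.mean[0], abs=1e-10 * max(1.0, traj.mean[0]))

    def test_continuity_at_interior_boundaries(self, ref_age_params):
        p = ref_age_params
        traj = solve_moments(p)
        edges = p.segment_edges()
        for seg, edge in ((0, edges[1]), (1, edges[2]), (2, edges[3])):
            left_m = _eval_terms(traj._mean_terms[seg], np.array([edge]), edges[seg])[0]
            right_m = _eval_terms(traj._mean_terms[seg + 1], np.array([edge]), edges[seg + 1])[0]
            assert left_m == pytest.approx(right_m, rel=1e-10)
            left_v = _eval_terms(traj._var_terms[seg], np.array([edge]), edges[seg])[0]
            right_v = _eval_terms(traj._var_terms[seg + 1], np.array([edge]), edges[seg + 1])[0]
            assert left_v == pytest.approx(right_v, rel=1e-8)

    def test_cyclostationarity_roundtrip(self, ref_age_params):
        # re-propagating the solved birth values through one cycle and
        # dividing returns the birth values
        p = ref_age_params
        traj = solve_moments(p)
        _, m_end = _propagate_cycle(p, p.dT, lambda s, t0: _mean_forcings(p, s, t0), traj.mean[0])
        assert 0.5 * m_end == pytest.approx(traj.mean[0], rel=1e-8)


class TestVarianceTrajectory:
    def test_quasi_steady_fano_is_one_plus_rho(self):
        p = flat_params(rho=3.0)
        traj = solve_moments(p)
        mid = np.isclose(traj.theta, 0.10)
        assert traj.variance[mid][0] / traj.mean[mid][0] == pytest.approx(4.0, rel=1e-3)

    def test_small_burst_size_is_poissonian(self):
        # rho -> 0 with mu = f*rho fixed: Fano -> 1
        p = AgeModelParams(1000.0, 1000.0, 0.002, 0.002, (0, 0, 0, 0), d=200 / 13.25)
        traj = solve_moments(p)
        fano = traj.variance[10] / traj.mean[10]
        assert fano == pytest.approx(1.0, abs=0.01)

    def test_variance_nonnegative(self, ref_age_params):
        traj = solve_moments(ref_age_params)
        assert np.all(traj.variance >= 0)

    def test_frequency_variant_same_mean_different_variance(self):
        betas = (0.4, -0.3, 0.5, 0.3)
        size = AgeModelParams(0.7, 0.35, 2.0, 2.0, betas, d=0.1)
        freq = AgeModelParams(0.7, 0.35, 2.0, 2.0, betas, d=0.1, variant="frequency")
        ts, tf = solve_moments(size), solve_moments(freq)
        assert np.allclose(ts.mean, tf.mean, rtol=1e-10)
        assert not np.allclose(ts.variance, tf.variance, rtol=1e-3)


class TestMomentMatchedNb:
    def test_formula_arithmetic(self):
        nb = nb_at_age(6.0, 24.0)
        assert nb.r == pytest.approx(2.0) and nb.p == pytest.approx(0.25)

    def test_poisson_fallback_at_boundary(self):
        assert nb_at_age(5.0, 5.0).is_poisson
        assert nb_at_age(5.0, 4.0).is_poisson

    def test_moments_recovered(self):
        nb = nb_at_age(10.0, 30.0)
        mean = nb.r * (1 - nb.p) / nb.p
        var = nb.r * (1 - nb.p) / nb.p**2
        assert mean == pytest.approx(10.0, abs=1e-10)
        assert var == pytest.approx(30.0, abs=1e-10)

    def test_negative_moments_rejected(self):
        with pytest.raises(ValueError):
            nb_at_age(-1.0, 2.0)


class TestPhaseAveragedBurstSize:
    def test_flat_and_point_mass(self):
        g = AgeDistribution(np.array([0.2, 0.4]), np.array([0.5, 0.5]))
        assert phase_averaged_burst_size(2.0, 0.0, g) == pytest.approx(2.0)
        point = AgeDistribution(np.array([0.3]), np.array([1.0]))
        assert phase_averaged_burst_size(1.5, 2.0, point) == pytest.approx(1.5 * np.exp(0.6))

    def test_matches_direct_sum(self):
        theta = np.round(np.arange(0.0, 0.11, 0.01), 2)
        w = np.full(theta.size, 1.0 / theta.size)
        got = phase_averaged_burst_size(1.0, 1.0, AgeDistribution(theta, w))
        assert got == pytest.approx(sum(wi * np.exp(t) for wi, t in zip(w, theta)), abs=1e-12)

    def test_unnormalised_weights_rejected(self):
        with pytest.raises(ValueError):
            AgeDistribution(np.array([0.1, 0.2]), np.array([0.5, 0.6]))


class TestDivisionMap:
    def test_arithmetic(self):
        assert division_boundary_map(10.0, 20.0) == (5.0, 7.5)
        assert division_boundary_map(0.0, 0.0) == (0.0, 0.0)

    def test_matches_binomial_thinning_enumeration(self):
        # thin an arbitrary pre-division pmf molecule-by-molecule with
        # probability 1/2 and compare exact moments
        from scipy.stats import binom

        pre = nb_pmf(1.3, 2.5, 120).probs
        m = np.arange(pre.size)
        post = np.zeros_like(pre)
        for mm, pm in enumerate(pre):
            post[: mm + 1] += pm * binom.pmf(np.arange(mm + 1), mm, 0.5)
        mean_pre = float(m @ pre)
        var_pre = float((m - mean_pre) ** 2 @ pre)
        mean_post = float(m @ post)
        var_post = float((m - mean_post) ** 2 @ post)
        exp_mean, exp_var = division_boundary_map(mean_pre, var_pre)
        assert mean_post == pytest.approx(exp_mean, rel=1e-10)
        assert var_post == pytest.approx(exp_var, rel=1e-8)


def test_moments_match_ssa_oracle(ref_age_params):
    """Closed-form moments agree with exact stochastic simulation within
    sampling error at a few probe ages."""
    from burstcycle.synthetic import ssa_simulate

    ages = np.repeat(np.array([0.15, 0.45, 0.85]), 2000)
    theta, counts = ssa_simulate(ref_age_params, ages.size, seed=11, theta=ages)
    traj = solve_moments(ref_age_params, np.unique(ages))
    for i, b in enumerate(np.unique(ages)):
        x = counts[theta == b]
        se_mean = x.std() / np.sqrt(x.size)
        assert abs(x.mean() - traj.mean[i]) < 3.5 * se_mean
        m4 = np.mean((x - x.mean()) ** 4)
        se_var = np.sqrt(max(m4 - x.var() ** 2, 0.0) / x.size)
        assert abs(x.var() - traj.variance[i]) < 3.5 * se_var
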
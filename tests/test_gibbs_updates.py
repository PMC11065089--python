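"""Closed-form spot checks of individual full-conditional updates.

The distributional (KS) verification of every scalar conditional against a
grid-density oracle lives in the acceptance suite; here each block is checked
against hand-derived means/parameters on tiny instances, plus the structural
invariants of the sweep.
"""

import numpy as np
import pytest
from scipy import stats

from conftest import clone_state

from icjm import GibbsSampler, JointDataset, PriorConfig
from icjm.splines import place_knots


def make_sampler(dataset, variant="BL", seed=11, **kw):
    return GibbsSampler(dataset, PriorConfig(variant=variant), seed=seed, **kw)


class TestLatentZ:
    def test_regions_respected(self, tiny_sampler):
        s = tiny_sampler
        for _ in range(200):
            z = s.update_z()
            assert z[0] > 0  # left-censored
            lower = -(s.dBint @ s.state.baseline.r)[0]
            assert lower < z[1] < 0  # interval-censored
            assert z[2] < 0  # right-censored

    def test_conditional_mean_matches_mills_ratio(self, tiny_sampler):
        s = tiny_sampler
        means = s._alpha_anchor() + s.data.X @ s.state.regression.beta + s.state.frailty.u
        draws = np.array([s.update_z().copy() for _ in range(20000)])
        # right-censored subject: one-sided truncation at 0 from above
        m = means[2]
        expected = m - stats.norm.pdf(-m) / stats.norm.cdf(-m)
        assert draws[:, 2].mean() == pytest.approx(expected, abs=0.02)


class TestMonotoneSpline:
    def test_r0_prior_only_limit(self, tiny_sampler):
        """With huge prior precision v0, r0 collapses to the prior mean m0."""
        s = tiny_sampler
        s.prior.v0 = 1e12
        draws = [s.update_r0() for _ in range(50)]
        assert np.allclose(draws, s.prior.m0, atol=1e-4)

    def test_r0_posterior_mean_hand_formula(self, tiny_sampler):
        s = tiny_sampler
        st = s.state
        W0 = s.prior.v0 + s.data.n
        resid = (st.latent.z - s.Bsurv @ st.baseline.r
                 - s.data.X @ st.regression.beta - st.frailty.u)
        E0 = (s.prior.v0 * s.prior.m0 + resid.sum()) / W0
        draws = []
        for _ in range(4000):
            snap = st.baseline.r0
            draws.append(s.update_r0())
            st.baseline.r0 = snap
        draws = np.array(draws)
        assert draws.mean() == pytest.approx(E0, abs=4 * (1 / np.sqrt(W0)) / np.sqrt(4000))
        assert draws.std() == pytest.approx(1 / np.sqrt(W0), rel=0.1)

    def test_r_stays_feasible_and_nonnegative(self, tiny_sampler):
        s = tiny_sampler
        for _ in range(300):
            s.update_z()
            r = s.update_r()
            assert np.all(r >= 0)
            z_int = s.state.latent.z[s.int_idx]
            lower = -(s.dBint @ r)
            assert np.all(z_int > lower)

    def test_single_constraint_bound_hand_derived(self):
        """One interval-censored subject, K*=1: d* solves z > -r (b(R)-b(L))."""
        dataset = JointDataset(
            y=np.array([0.1]), t_long=np.array([1.0]), subj=np.array([0]),
            L=np.array([0.8]), R=np.array([1.6]), X=np.array([[0.0]]),
        )
        kv_alpha = place_knots(np.array([0.8, 1.6]), J=0, degree=1)
        kv_mu = place_knots(np.array([0.5, 1.5]), J=0, degree=1)
        s = make_sampler(dataset, knots_alpha=kv_alpha, knots_mu=kv_mu)
        st = s.state
        st.latent.z = np.array([-0.2])
        db = s.dBint[0]  # both entries positive here
        # bound for r_0 given r_1: r_0 > (-z - r_1 db_1)/db_0
        expected0 = (-st.latent.z[0] - st.baseline.r[1] * db[1]) / db[0]
        rng_draws = []
        for _ in range(500):
            snap = st.baseline.r.copy()
            r = s.update_r()
            rng_draws.append(r[0])
            st.baseline.r = snap
        lower = max(expected0, 0.0)
        assert np.all(np.asarray(rng_draws) >= lower)

    def test_rho_spline_conjugate_gamma(self, tiny_sampler):
        s = tiny_sampler
        st = s.state
        st.baseline.r = np.zeros(s.K_alpha)
        s.prior.a_rho = s.prior.b_rho = 1.0
        draws = np.array([s.update_rho_spline() for _ in range(20000)])
        # Ga(1 + K*, 1): mean (1+K*)/1
        expected = (1.0 + s.K_alpha) / 1.0
        assert draws.mean() == pytest.approx(expected, rel=0.03)


class TestRegression:
    def test_beta_posterior_hand_formula(self):
        """n=1, p=1, X=1, residual 1.5, tau^2=1 => posterior N(0.75, 0.5)."""
        dataset = JointDataset(
            y=np.array([0.0]), t_long=np.array([1.0]), subj=np.array([0]),
            L=np.array([0.5]), R=np.array([1.5]), X=np.array([[1.0]]),
        )
        kv = place_knots(np.array([0.4, 1.6]), J=0, degree=1)
        s = make_sampler(dataset, knots_mu=kv, knots_alpha=kv)
        st = s.state
        # force residual z - alpha(t) - u = 1.5
        st.baseline.r0 = 0.0
        st.baseline.r = np.zeros(s.K_alpha)
        st.frailty.u = np.zeros(1)
        st.latent.z = np.array([1.5])
        st.regression.tau_s2 = np.ones(1)
        draws = np.array([s.update_beta()[0] for _ in range(40000)])
        assert draws.mean() == pytest.approx(0.75, abs=0.02)
        assert draws.var() == pytest.approx(0.5, rel=0.05)

    def test_beta_infinite_shrinkage(self, tiny_sampler):
        s = tiny_sampler
        s.state.regression.tau_s2 = np.full(1, 1e-12)
        draws = np.array([s.update_beta()[0] for _ in range(100)])
        assert np.all(np.abs(draws) < 1e-4)

    def test_theta_zero_residual_zero_mean(self, tiny_sampler):
        s = tiny_sampler
        st = s.state
        # y exactly equals the longitudinal mean => residuals 0
        st.baseline.eta = np.zeros(s.K_mu)
        st.frailty.u = np.zeros(3)
        st.frailty.xi = np.zeros(3)
        s.data.y[:] = 0.0
        draws = np.array([s.update_theta()[0] for _ in range(20000)])
        assert abs(draws.mean()) < 0.02

    def test_ss_inclusion_probability_at_zero_beta(self):
        """beta_j = 0: R = sigma_slab/sigma_spike; omega=0.5 => P(delta=1)=1/101."""
        dataset = JointDataset(
            y=np.array([0.0]), t_long=np.array([1.0]), subj=np.array([0]),
            L=np.array([0.5]), R=np.array([1.5]), X=np.array([[1.0]]),
        )
        kv = place_knots(np.array([0.4, 1.6]), J=0, degree=1)
        s = make_sampler(dataset, variant="SS", knots_mu=kv, knots_alpha=kv)
        st = s.state
        st.regression.beta = np.zeros(1)
        st.regression.omega_s = 0.5
        hits = 0
        trials = 30000
        for _ in range(trials):
            st.regression.omega_s = 0.5
            s.update_shrinkage_survival()
            hits += int(st.regression.delta_s[0])
        assert hits / trials == pytest.approx(1 / 101, abs=0.003)

    def test_ss_large_beta_always_included(self, tiny_sampler):
        s = GibbsSampler(tiny_sampler.data, PriorConfig(variant="SS"), seed=2,
                         J_mu=0, J_alpha=0, degree=1)
        s.state.regression.beta = np.array([50.0])
        s.state.regression.omega_s = 0.5
        for _ in range(50):
            s.update_shrinkage_survival()
            assert s.state.regression.delta_s[0] == 1.0

    def test_bl_lambda_gamma_mean(self, tiny_sampler):
        s = tiny_sampler
        st = s.state
        st.regression.tau_s2 = np.array([2.0])
        p = s.data.p
        draws = []
        for _ in range(20000):
            tau_snapshot = st.regression.tau_s2.copy()
            s.update_shrinkage_survival()
            draws.append(st.regression.lambda_s[0])
            st.regression.tau_s2 = tau_snapshot
        expected = (p + s.prior.a_lambda) / (0.5 * 2.0 + s.prior.b_lambda)
        assert np.mean(draws) == pytest.approx(expected, rel=0.03)

    def test_bal_per_coefficient_penalty_shape(self, tiny_sampler):
        s = GibbsSampler(tiny_sampler.data, PriorConfig(variant="BAL"), seed=4,
                         J_mu=0, J_alpha=0, degree=1)
        st = s.state
        st.regression.tau_l2 = np.array([4.0])
        draws = []
        for _ in range(20000):
            snap = st.regression.tau_l2.copy()
            s.update_shrinkage_longitudinal()
            draws.append(st.regression.lambda_l[0])
            st.regression.tau_l2 = snap
        # per-j Ga(1 + a_lambda, tau^2/2 + b_lambda), independent of p
        expected = (1.0 + s.prior.a_lambda) / (0.5 * 4.0 + s.prior.b_lambda)
        assert np.mean(draws) == pytest.approx(expected, rel=0.03)
        assert np.all(np.asarray(st.regression.tau_l2) > 0)


class TestFrailtiesAndVariances:
    def test_u_precision_formula(self, tiny_sampler):
        s = tiny_sampler
        st = s.state
        draws = []
        for _ in range(20000):
            snap = st.frailty.u.copy()
            draws.append(s.update_u()[0])
            st.frailty.u = snap
        V = s.data.m[0] / st.frailty.sigma_eps2 + 1.0 / st.frailty.sigma_u2 + 1.0
        assert np.std(draws) == pytest.approx(1.0 / np.sqrt(V), rel=0.05)

    def test_xi_hand_mean(self, tiny_sampler):
        s = tiny_sampler
        st = s.state
        d = s.data
        inv_eps = 1.0 / st.frailty.sigma_eps2
        resid = d.y - s.Mlong @ st.baseline.eta - s.Xl @ st.regression.theta \
            - st.frailty.u[d.subj]
        sums = np.add.reduceat(resid, s.offsets)
        prec = d.m * inv_eps + 1.0 / st.frailty.sigma_xi2
        expected = inv_eps * sums[1] / prec[1]
        draws = []
        for _ in range(20000):
            snap = st.frailty.xi.copy()
            draws.append(s.update_xi()[1])
            st.frailty.xi = snap
        assert np.mean(draws) == pytest.approx(expected, abs=0.03)

    def test_sigma_u_gamma_plugin(self, tiny_sampler):
        s = tiny_sampler
        st = s.state
        st.frailty.u = np.zeros(3)
        draws = np.array([1.0 / s.update_sigma_u2() for _ in range(20000)])
        # precision ~ Ga(n/2 + a_u, b_u)
        expected = (1.5 + s.prior.a_u) / s.prior.b_u
        assert draws.mean() == pytest.approx(expected, rel=0.05)

    def test_gb_eps_shape_excludes_theta_terms(self, tiny_sampler):
        """Under GB the theta prior is not scaled by sigma_eps^2, so its
        conditional drops the +p/2 shape and theta'D^-1 theta rate terms."""
        dgb = GibbsSampler(tiny_sampler.data, PriorConfig(variant="GB"), seed=5,
                           J_mu=0, J_alpha=0, degree=1)
        st = dgb.state
        st.baseline.eta = np.zeros(dgb.K_mu)
        st.regression.theta = np.zeros(1)
        st.frailty.u = np.zeros(3)
        st.frailty.xi = np.zeros(3)
        dgb.data.y[:] = 0.0  # zero residuals: rate = b_eps exactly
        draws = np.array([1.0 / dgb.update_sigma_eps2() for _ in range(20000)])
        expected = (dgb.prior.a_eps + 0.5 * dgb.data.n_obs) / dgb.prior.b_eps
        assert draws.mean() == pytest.approx(expected, rel=0.05)
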
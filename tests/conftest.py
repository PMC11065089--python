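"""Shared fixtures: a tiny hand-built joint dataset (one subject per censoring
class) and an independent unnormalized log-posterior used as the oracle for
full-conditional checks."""

from __future__ import annotations

import copy

import numpy as np
import pytest
from scipy import stats

from icjm import (
    GibbsSampler,
    JointDataset,
    PriorConfig,
    SimulationDesign,
    complete_log_likelihood,
    simulate_dataset,
)
from icjm.splines import BasisMatrix


def build_tiny_dataset() -> JointDataset:
    """Three subjects (left-, interval-, right-censored), one covariate."""
    return JointDataset(
        y=np.array([0.6, -0.2, 1.1, 0.3, -0.5]),
        t_long=np.array([0.4, 1.1, 0.7, 1.9, 1.3]),
        subj=np.array([0, 0, 1, 1, 2]),
        L=np.array([0.0, 0.8, 1.7]),
        R=np.array([1.5, 2.0, np.inf]),
        X=np.array([[0.5], [-0.3], [1.0]]),
    )


@pytest.fixture
def tiny_dataset() -> JointDataset:
    return build_tiny_dataset()


@pytest.fixture
def tiny_sampler(tiny_dataset) -> GibbsSampler:
    """Degree-1, no-interior-knot bases => 2 basis functions per baseline."""
    prior = PriorConfig(variant="BL")
    return GibbsSampler(tiny_dataset, prior, J_mu=0, J_alpha=0, degree=1, seed=7)


@pytest.fixture
def small_sim():
    """A modest simulated Scenario-I dataset for chain-level tests."""
    design = SimulationDesign(n=120, scenario="I", sigma_u2=0.25,
                              sigma_eps2=1.0, seed=314)
    return simulate_dataset(design)


def log_joint(sampler: GibbsSampler, state) -> float:
    """Unnormalized log posterior of a ChainState under the BL prior.

    Built from the augmented-data likelihood plus explicit prior densities
    (variances parameterized by their precisions), entirely independent of the
    full-conditional update formulas it is used to check.
    """
    pr = sampler.prior
    if pr.variant != "BL":
        raise NotImplementedError("oracle implemented for the BL prior")
    b, f, reg = state.baseline, state.frailty, state.regression
    ll = complete_log_likelihood(
        sampler.data, state,
        BasisMatrix(sampler.Mlong, "M"), BasisMatrix(sampler.Bsurv, "I"),
        dB=sampler.dB,
    )
    if not np.isfinite(ll):
        return -np.inf
    lp = ll
    lp += stats.norm.logpdf(b.r0, pr.m0, 1.0 / np.sqrt(pr.v0))
    lp += stats.expon.logpdf(b.r, scale=1.0 / b.rho_spline).sum()
    lp += stats.gamma.logpdf(b.rho_spline, pr.a_rho, scale=1.0 / pr.b_rho)
    lp += stats.norm.logpdf(b.eta, 0.0, np.sqrt(pr.sigma_eta2)).sum()
    lp += stats.gamma.logpdf(1.0 / f.sigma_u2, pr.a_u, scale=1.0 / pr.b_u)
    lp += stats.gamma.logpdf(1.0 / f.sigma_xi2, pr.a_xi, scale=1.0 / pr.b_xi)
    lp += stats.gamma.logpdf(1.0 / f.sigma_eps2, pr.a_eps, scale=1.0 / pr.b_eps)
    lp += stats.norm.logpdf(reg.beta, 0.0, np.sqrt(reg.tau_s2)).sum()
    lp += stats.norm.logpdf(reg.theta, 0.0, np.sqrt(f.sigma_eps2 * reg.tau_l2)).sum()
    return float(lp)


def clone_state(state):
    return copy.deepcopy(state)
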
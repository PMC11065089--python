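"""Domain model for the joint longitudinal / interval-censored analysis.

The joint model couples a semiparametric linear mixed-effects submodel for a
continuous longitudinal response,

    y_ij = mu(t_ij) + X_i' theta + xi_i + u_i + eps_ij,

with a semiparametric normal-frailty probit submodel for an interval-censored
event time,

    P(T_i <= t | X_i, u_i) = Phi(alpha(t) + X_i' beta + u_i),

where ``u_i ~ N(0, sigma_u^2)`` is a frailty shared by both submodels (the sole
source of dependence), ``xi_i ~ N(0, sigma_xi^2)`` is a longitudinal-only
frailty, ``eps_ij ~ N(0, sigma_eps^2)``, ``mu`` is a free baseline mean and
``alpha`` a nondecreasing baseline transform.  The event time is never observed
exactly: each subject contributes an interval (L_i, R_i] from the examination
schedule, with L_i = 0 encoding left censoring and R_i = inf right censoring.

Posterior computation augments each subject with a unit-variance normal latent
variable z_i ~ N(alpha(t_i) + X_i' beta + u_i, 1) constrained to a censoring
region C_i, after which every full conditional is a standard distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .splines import BasisMatrix, KnotVector, ispline_eval, mspline_eval

__all__ = [
    "JointDataset",
    "BaselineState",
    "FrailtyState",
    "RegressionState",
    "LatentState",
    "ChainState",
    "PriorConfig",
    "mu_eval",
    "alpha_eval",
    "region_C",
    "kendall_tau",
    "complete_log_likelihood",
]


@dataclass
class JointDataset:
    """Longitudinal measurements, censoring intervals and shared covariates.

    Longitudinal rows are stored flat, sorted by subject: ``y[k]`` observed at
    ``t_long[k]`` belongs to subject ``subj[k]``.  ``L``, ``R`` are the
    censoring interval endpoints per subject (``L=0`` left-censored,
    ``R=inf`` right-censored), ``X`` the n-by-p covariate matrix used by both
    submodels.
    """

    y: np.ndarray
    t_long: np.ndarray
    subj: np.ndarray
    L: np.ndarray
    R: np.ndarray
    X: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.t_long = np.asarray(self.t_long, dtype=float)
        self.subj = np.asarray(self.subj, dtype=np.intp)
        self.L = np.asarray(self.L, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n = self.L.size
        if self.R.size != n or self.X.shape[0] != n:
            raise ValueError("survival and covariate tables disagree on n")
        if np.any(self.L < 0) or np.any(self.L >= self.R):
            raise ValueError("intervals must satisfy 0 <= L < R")
        if self.y.size != self.t_long.size or self.y.size != self.subj.size:
            raise ValueError("longitudinal columns must have equal length")
        if np.any(np.diff(self.subj) < 0):
            order = np.argsort(self.subj, kind="stable")
            self.y = self.y[order]
            self.t_long = self.t_long[order]
            self.subj = self.subj[order]
        m = np.bincount(self.subj, minlength=n)
        if np.any(m < 1):
            raise ValueError("every subject needs at least one measurement")
        self.m = m
        # censoring indicators derived from the interval endpoints
        self.delta1 = (self.L == 0) & np.isfinite(self.R)
        self.delta3 = np.isinf(self.R)
        self.delta2 = ~(self.delta1 | self.delta3)
        # anchor time t_i = R_i for left-censored subjects, L_i otherwise
        self.anchor = np.where(self.delta1, self.R, self.L)

    @property
    def n(self) -> int:
        return self.L.size

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def n_obs(self) -> int:
        return self.y.size


@dataclass
class BaselineState:
    """Spline coefficients for mu (free) and alpha (monotone) baselines."""

    eta: np.ndarray
    r0: float
    r: np.ndarray
    rho_spline: float  # exponential shrinkage rate on the r_k

    def __post_init__(self) -> None:
        self.eta = np.asarray(self.eta, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if np.any(self.r < 0):
            raise ValueError("monotone spline coefficients r_k must be >= 0")
        if self.rho_spline <= 0:
            raise ValueError("rho_spline must be > 0")


@dataclass
class FrailtyState:
    u: np.ndarray
    xi: np.ndarray
    sigma_u2: float
    sigma_xi2: float
    sigma_eps2: float

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.xi = np.asarray(self.xi, dtype=float)
        for name in ("sigma_u2", "sigma_xi2", "sigma_eps2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class RegressionState:
    """Regression coefficients and the shrinkage machinery of each prior.

    ``tau_s2``/``tau_l2`` are the Lasso scale-mixture latents; ``lambda_s``/
    ``lambda_l`` the penalty rates (scalar for the Bayesian Lasso, per-
    coefficient for the adaptive Lasso); ``delta_*``/``omega_*`` the spike-and-
    slab inclusion indicators and probabilities.
    """

    beta: np.ndarray
    theta: np.ndarray
    tau_s2: np.ndarray
    tau_l2: np.ndarray
    lambda_s: np.ndarray
    lambda_l: np.ndarray
    delta_s: np.ndarray
    delta_l: np.ndarray
    omega_s: float
    omega_l: float

    def __post_init__(self) -> None:
        for name in ("beta", "theta", "tau_s2", "tau_l2", "lambda_s",
                     "lambda_l", "delta_s", "delta_l"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        if np.any(self.tau_s2 <= 0) or np.any(self.tau_l2 <= 0):
            raise ValueError("tau^2 entries must be > 0")


@dataclass
class LatentState:
    """Augmented latent normals z_i, one per subject, confined to C_i."""

    z: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)


@dataclass
class ChainState:
    latent: LatentState
    baseline: BaselineState
    frailty: FrailtyState
    regression: RegressionState


Variant = Literal["BL", "BAL", "SS", "GB"]


@dataclass
class PriorConfig:
    """Hyperparameters of the four prior variants.

    Defaults follow a weakly-informative setup: Ga(0.1, 0.1) on each precision,
    N(-6, 1) on the monotone-spline intercept r0, Ga(1, 1) on the spline
    shrinkage rate, N(0, 100 I) on eta, Ga(1, 2) on Lasso penalties,
    Beta(1, 1) on inclusion probabilities with spike/slab variances 0.01/100,
    and N(0, 100 I) on beta and theta under the general-prior variant.
    """

    variant: Variant = "BL"
    a_u: float = 0.1
    b_u: float = 0.1
    a_xi: float = 0.1
    b_xi: float = 0.1
    a_eps: float = 0.1
    b_eps: float = 0.1
    m0: float = -6.0
    v0: float = 1.0  # prior precision of r0
    a_rho: float = 1.0
    b_rho: float = 1.0
    sigma_eta2: float = 100.0  # eta ~ N(0, sigma_eta2 I)
    a_lambda: float = 1.0
    b_lambda: float = 2.0
    a_omega: float = 1.0
    b_omega: float = 1.0
    sigma_spike2: float = 0.01
    sigma_slab2: float = 100.0
    sigma_gb2: float = 100.0  # beta, theta ~ N(0, sigma_gb2 I) under GB

    def __post_init__(self) -> None:
        if self.variant not in ("BL", "BAL", "SS", "GB"):
            raise ValueError(f"unknown prior variant {self.variant!r}")
        for name in ("a_u", "b_u", "a_xi", "b_xi", "a_eps", "b_eps", "v0",
                     "a_rho", "b_rho", "sigma_eta2", "a_lambda", "b_lambda",
                     "a_omega", "b_omega", "sigma_spike2", "sigma_slab2",
                     "sigma_gb2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.sigma_spike2 >= self.sigma_slab2:
            raise ValueError("sigma_spike2 must be < sigma_slab2")


def mu_eval(eta, basis_mu: BasisMatrix | np.ndarray) -> np.ndarray:
    """Evaluate mu(t) = sum_h eta_h M_h(t) from a pre-evaluated M-basis."""
    vals = basis_mu.values if isinstance(basis_mu, BasisMatrix) else basis_mu
    return vals @ np.asarray(eta, dtype=float)


def alpha_eval(r0: float, r, basis_alpha: BasisMatrix | np.ndarray) -> np.ndarray:
    """Evaluate alpha(t) = r0 + sum_k r_k b_k(t) from a pre-evaluated I-basis."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("monotone spline coefficients r_k must be >= 0")
    vals = basis_alpha.values if isinstance(basis_alpha, BasisMatrix) else basis_alpha
    return r0 + vals @ r


def region_C(delta1: bool, delta2: bool, delta3: bool,
             alpha_L: float = np.nan, alpha_R: float = np.nan) -> tuple[float, float]:
    """Censoring region C_i for the latent normal z_i.

    Left-censored: (0, inf); interval-censored: (alpha(L)-alpha(R), 0);
    right-censored: (-inf, 0).
    """
    if int(delta1) + int(delta2) + int(delta3) != 1:
        raise ValueError("exactly one censoring indicator must be set")
    if delta1:
        return (0.0, np.inf)
    if delta3:
        return (-np.inf, 0.0)
    lower = alpha_L - alpha_R
    if not lower < 0:
        raise ValueError("nonmonotone alpha: alpha(L) >= alpha(R)")
    return (lower, 0.0)


def kendall_tau(sigma_u2: float, sigma_xi2: float, sigma_eps2: float) -> tuple[float, float]:
    """Model-implied association between y_ij and alpha(T_i).

    Returns (rho, tau): the Pearson correlation
    rho = -sigma_u^2 / sqrt((1+sigma_u^2)(sigma_eps^2+sigma_xi^2+sigma_u^2))
    and Kendall's tau = (2/pi) arcsin(rho).  Both lie in (-1, 0]; the shared
    frailty makes larger longitudinal responses go with earlier events.
    """
    if sigma_u2 < 0 or sigma_xi2 < 0 or sigma_eps2 < 0:
        raise ValueError("variances must be nonnegative")
    rho = -sigma_u2 / np.sqrt((1.0 + sigma_u2) * (sigma_eps2 + sigma_xi2 + sigma_u2))
    tau = (2.0 / np.pi) * np.arcsin(rho)
    return float(rho), float(tau)


_LOG_2PI = np.log(2.0 * np.pi)


def complete_log_likelihood(dataset: JointDataset, state: ChainState,
                            basis_mu: BasisMatrix, basis_alpha: BasisMatrix,
                            dB: np.ndarray | None = None) -> float:
    """Augmented-data log likelihood (normal factors plus region indicators).

    ``basis_mu`` is the M-basis at the flat longitudinal times; ``basis_alpha``
    the I-basis at the per-subject anchor times; ``dB`` holds
    ``b_k(R_i) - b_k(L_i)`` per subject (rows for non-interval-censored
    subjects are ignored) and is required when any subject is interval-
    censored.  Returns ``-inf`` when any z_i falls outside its censoring
    region.
    """
    b = state.baseline
    f = state.frailty
    reg = state.regression
    z = state.latent.z

    mu = mu_eval(b.eta, basis_mu)
    mean_y = mu + dataset.X[dataset.subj] @ reg.theta + f.xi[dataset.subj] + f.u[dataset.subj]
    resid_y = dataset.y - mean_y
    ll = -0.5 * (dataset.n_obs * (_LOG_2PI + np.log(f.sigma_eps2))
                 + np.sum(resid_y**2) / f.sigma_eps2)

    alpha_t = alpha_eval(b.r0, b.r, basis_alpha)
    mean_z = alpha_t + dataset.X @ reg.beta + f.u
    ll += -0.5 * (dataset.n * _LOG_2PI + np.sum((z - mean_z) ** 2))

    # region indicators: interval lower bound is alpha(L)-alpha(R) = -dB @ r
    lower = np.where(dataset.delta1, 0.0, -np.inf)
    upper = np.where(dataset.delta1, np.inf, 0.0)
    if np.any(dataset.delta2):
        if dB is None:
            raise ValueError("dB is required when interval-censored subjects exist")
        lower = np.where(dataset.delta2, -(np.asarray(dB) @ b.r), lower)
    if not (np.all(z > lower) and np.all(z < upper)):
        return -np.inf

    ll += -0.5 * (dataset.n * (_LOG_2PI + np.log(f.sigma_u2)) + np.sum(f.u**2) / f.sigma_u2)
    ll += -0.5 * (dataset.n * (_LOG_2PI + np.log(f.sigma_xi2)) + np.sum(f.xi**2) / f.sigma_xi2)
    return float(ll)
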
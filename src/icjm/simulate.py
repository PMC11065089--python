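"""Synthetic joint longitudinal / interval-censored datasets with known truth.

The generator reproduces a longitudinal study design: each subject receives
``m_i = min(Poisson(3) + 1, 10)`` clinic visits whose times are cumulative sums
of Exp(mean 0.5) gaps; the longitudinal response follows the mixed-effects
submodel with baseline mean ``mu(t) = 4 log(t+1) - 2t``; the event time is
drawn exactly from the probit submodel with monotone baseline
``alpha(t) = 2 log(t) + t^2`` by inverting its conditional CDF; and the
observed interval (L_i, R_i] is formed by the two adjacent points of
``{0, t_i1, ..., t_im_i, inf}`` that bracket the event time.  Covariates are
half Bernoulli(0.5) (the first p/2 columns) and half standard normal, shared
by both submodels.

Two preset coefficient scenarios are provided:

* ``"I"``  — p = 10: theta = (1,0,1,0,1,0,1,0,1,0), beta = (1,1,0,0,1,1,0,0,1,0);
* ``"II"`` — p = 30: theta = (ten 1s, twenty 0s), beta = (five 1s, five 0s,
  five 1s, fifteen 0s).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.special import ndtri

from .model import JointDataset

__all__ = [
    "SimulationDesign",
    "SimTruth",
    "default_mu",
    "default_alpha",
    "scenario_coefficients",
    "simulate_schedule",
    "invert_alpha",
    "simulate_dataset",
]


def default_mu(t):
    """Baseline longitudinal mean mu(t) = 4 log(t+1) - 2t."""
    t = np.asarray(t, dtype=float)
    return 4.0 * np.log1p(t) - 2.0 * t


def default_alpha(t):
    """Baseline survival transform alpha(t) = 2 log(t) + t^2 (increasing)."""
    t = np.asarray(t, dtype=float)
    return 2.0 * np.log(t) + t**2


def scenario_coefficients(scenario: str) -> tuple[np.ndarray, np.ndarray]:
    """True (theta, beta) for the two preset selection scenarios."""
    if scenario == "I":
        theta = np.array([1, 0, 1, 0, 1, 0, 1, 0, 1, 0], dtype=float)
        beta = np.array([1, 1, 0, 0, 1, 1, 0, 0, 1, 0], dtype=float)
    elif scenario == "II":
        theta = np.concatenate([np.ones(10), np.zeros(20)])
        beta = np.concatenate([np.ones(5), np.zeros(5), np.ones(5), np.zeros(15)])
    else:
        raise ValueError(f"unknown scenario {scenario!r}; use 'I' or 'II'")
    return theta, beta


@dataclass
class SimulationDesign:
    """Study-design parameters for the generator.

    ``scenario`` selects preset (theta, beta) truths; pass ``theta_true`` /
    ``beta_true`` explicitly for a custom design.  Visit counts are
    ``min(Poisson(visit_rate_mean) + 1, visit_cap)`` and visit gaps are
    exponential with mean ``gap_mean``.
    """

    n: int = 500
    scenario: str = "I"
    theta_true: np.ndarray | None = None
    beta_true: np.ndarray | None = None
    sigma_u2: float = 0.25
    sigma_xi2: float = 0.25
    sigma_eps2: float = 1.0
    visit_rate_mean: float = 3.0
    visit_cap: int = 10
    gap_mean: float = 0.5
    mu_true: Callable = default_mu
    alpha_true: Callable = default_alpha
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta_true is None or self.beta_true is None:
            theta, beta = scenario_coefficients(self.scenario)
            self.theta_true = theta if self.theta_true is None else np.asarray(self.theta_true, float)
            self.beta_true = beta if self.beta_true is None else np.asarray(self.beta_true, float)
        else:
            self.theta_true = np.asarray(self.theta_true, dtype=float)
            self.beta_true = np.asarray(self.beta_true, dtype=float)
        if self.theta_true.size != self.beta_true.size:
            raise ValueError("theta_true and beta_true must have equal length")
        if self.visit_cap < 1 or self.gap_mean <= 0:
            raise ValueError("visit_cap >= 1 and gap_mean > 0 required")

    @property
    def p(self) -> int:
        return self.theta_true.size


@dataclass
class SimTruth:
    """Ground truth recorded alongside a simulated dataset."""

    theta_true: np.ndarray
    beta_true: np.ndarray
    sigma_u2: float
    sigma_xi2: float
    sigma_eps2: float
    T: np.ndarray
    u: np.ndarray
    xi: np.ndarray


def simulate_schedule(design: SimulationDesign, rng: np.random.Generator):
    """Visit counts m_i and per-subject strictly increasing visit times."""
    m = np.minimum(rng.poisson(design.visit_rate_mean, size=design.n) + 1,
                   design.visit_cap)
    gaps = rng.exponential(design.gap_mean, size=int(m.sum()))
    offsets = np.concatenate([[0], np.cumsum(m)[:-1]])
    times = np.empty_like(gaps)
    start = 0
    for i, mi in enumerate(m):
        times[start:start + mi] = np.cumsum(gaps[start:start + mi])
        start += mi
    return m, offsets, times


def invert_alpha(c, alpha_true: Callable = default_alpha, tol: float = 1e-10):
    """Solve alpha_true(t) = c for t by bracketing bisection.

    The bracket is grown geometrically from an initial guess until it straddles
    ``c``; works for any strictly increasing alpha on (0, inf) with full range.
    """
    c_arr = np.atleast_1d(np.asarray(c, dtype=float))
    lo = np.full_like(c_arr, 1.0)
    hi = np.full_like(c_arr, 1.0)
    for _ in range(200):
        need = alpha_true(lo) > c_arr
        if not np.any(need):
            break
        lo[need] *= 0.5
    else:
        raise ValueError("cannot bracket alpha(t) = c from below")
    for _ in range(200):
        need = alpha_true(hi) < c_arr
        if not np.any(need):
            break
        hi[need] *= 2.0
    else:
        raise ValueError("cannot bracket alpha(t) = c from above")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        low_side = alpha_true(mid) < c_arr
        lo = np.where(low_side, mid, lo)
        hi = np.where(low_side, hi, mid)
        if np.all(np.abs(alpha_true(0.5 * (lo + hi)) - c_arr) < tol):
            break
    out = 0.5 * (lo + hi)
    return float(out[0]) if np.ndim(c) == 0 else out


def simulate_dataset(design: SimulationDesign) -> tuple[JointDataset, SimTruth]:
    """Generate one dataset and its ground truth under ``design``.

    Component substreams (schedule, covariates, frailties, errors, event
    uniforms) are spawned independently from the design seed so each piece is
    individually reproducible.
    """
    root = np.random.default_rng(design.seed)
    rng_sched, rng_cov, rng_frail, rng_err, rng_event = root.spawn(5)

    n, p = design.n, design.p
    m, offsets, t_long = simulate_schedule(design, rng_sched)
    subj = np.repeat(np.arange(n), m)

    # covariates: first half Bernoulli(0.5), second half N(0,1)
    n_bern = p // 2
    X = np.empty((n, p))
    X[:, :n_bern] = rng_cov.binomial(1, 0.5, size=(n, n_bern)).astype(float)
    X[:, n_bern:] = rng_cov.standard_normal((n, p - n_bern))

    u = rng_frail.normal(0.0, np.sqrt(design.sigma_u2), size=n)
    xi = rng_frail.normal(0.0, np.sqrt(design.sigma_xi2), size=n)
    eps = rng_err.normal(0.0, np.sqrt(design.sigma_eps2), size=t_long.size)

    y = (design.mu_true(t_long) + X[subj] @ design.theta_true
         + xi[subj] + u[subj] + eps)

    # exact event times by probit-CDF inversion:
    # F(t|X,u) = Phi(alpha(t) + X'beta + u)  =>  T = alpha^{-1}(ndtri(U) - X'beta - u)
    U = rng_event.uniform(size=n)
    c = ndtri(U) - X @ design.beta_true - u
    T = invert_alpha(c, design.alpha_true)

    # interval from adjacent grid points {0, t_i1..t_im, inf}: T in (L, R]
    L = np.zeros(n)
    R = np.full(n, np.inf)
    for i in range(n):
        ti = t_long[offsets[i]:offsets[i] + m[i]]
        grid = np.concatenate([[0.0], ti])
        j = np.searchsorted(grid, T[i], side="left")  # T in (grid[j-1], grid[j]]
        L[i] = grid[j - 1]
        R[i] = grid[j] if j < grid.size else np.inf

    dataset = JointDataset(y=y, t_long=t_long, subj=subj, L=L, R=R, X=X)
    truth = SimTruth(
        theta_true=design.theta_true.copy(),
        beta_true=design.beta_true.copy(),
        sigma_u2=design.sigma_u2,
        sigma_xi2=design.sigma_xi2,
        sigma_eps2=design.sigma_eps2,
        T=T,
        u=u,
        xi=xi,
    )
    return dataset, truth
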
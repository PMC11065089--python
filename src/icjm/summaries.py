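"""Posterior summaries for one fit and operating characteristics across
simulated replicates.

A fit is summarized by posterior means and equal-tailed 95% credible
intervals; Kendall's tau is summarized from the per-draw variance triplets.
Across replicates, each parameter gets BIAS (mean point estimate minus truth),
RMSE and CP95 (credible-interval coverage), and each submodel gets selection
metrics: aver.size (mean count of coefficients labeled positive, i.e. interval
excluding 0), TN (truly-zero coefficients labeled negative) and FN
(truly-nonzero coefficients labeled negative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gibbs import Draws
from .model import kendall_tau

__all__ = ["PosteriorSummary", "ReplicateReport", "summarize_fit",
           "selection_labels", "replicate_metrics"]


@dataclass
class PosteriorSummary:
    """Posterior mean and equal-tailed 2.5/97.5% quantiles per parameter."""

    beta_mean: np.ndarray
    beta_lower: np.ndarray
    beta_upper: np.ndarray
    theta_mean: np.ndarray
    theta_lower: np.ndarray
    theta_upper: np.ndarray
    sigma_u2: tuple[float, float, float]
    sigma_xi2: tuple[float, float, float]
    sigma_eps2: tuple[float, float, float]
    tau: tuple[float, float, float]

    def to_dict(self) -> dict:
        return {
            "beta": {"mean": self.beta_mean.tolist(),
                     "lower": self.beta_lower.tolist(),
                     "upper": self.beta_upper.tolist()},
            "theta": {"mean": self.theta_mean.tolist(),
                      "lower": self.theta_lower.tolist(),
                      "upper": self.theta_upper.tolist()},
            "sigma_u2": list(self.sigma_u2),
            "sigma_xi2": list(self.sigma_xi2),
            "sigma_eps2": list(self.sigma_eps2),
            "kendall_tau": list(self.tau),
        }


def _mean_ci(draws: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = draws.mean(axis=0)
    lower, upper = np.quantile(draws, [0.025, 0.975], axis=0)
    return mean, lower, upper


def summarize_fit(draws: Draws) -> PosteriorSummary:
    """Posterior means and equal-tailed 95% intervals from retained draws."""
    if draws.n_retained == 0:
        raise ValueError("no retained draws to summarize")
    bm, bl, bu = _mean_ci(draws.beta)
    tm, tl, tu = _mean_ci(draws.theta)
    scalars = {}
    for name in ("sigma_u2", "sigma_xi2", "sigma_eps2"):
        arr = getattr(draws, name)
        scalars[name] = (float(arr.mean()),
                         float(np.quantile(arr, 0.025)),
                         float(np.quantile(arr, 0.975)))
    tau_draws = np.array([
        kendall_tau(su, sx, se)[1]
        for su, sx, se in zip(draws.sigma_u2, draws.sigma_xi2, draws.sigma_eps2)
    ])
    tau = (float(tau_draws.mean()),
           float(np.quantile(tau_draws, 0.025)),
           float(np.quantile(tau_draws, 0.975)))
    return PosteriorSummary(
        beta_mean=bm, beta_lower=bl, beta_upper=bu,
        theta_mean=tm, theta_lower=tl, theta_upper=tu,
        sigma_u2=scalars["sigma_u2"], sigma_xi2=scalars["sigma_xi2"],
        sigma_eps2=scalars["sigma_eps2"], tau=tau,
    )


def selection_labels(lower: np.ndarray, upper: np.ndarray) -> np.ndarray:
    """True where a coefficient is labeled "positive" (selected).

    A coefficient is negative (not selected) when its closed 95% credible
    interval contains 0, positive otherwise.
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    contains_zero = (lower <= 0.0) & (upper >= 0.0)
    return ~contains_zero


@dataclass
class ReplicateReport:
    """Estimation and selection operating characteristics across replicates."""

    params: list[str]
    truth: np.ndarray
    bias: np.ndarray
    rmse: np.ndarray
    cp95: np.ndarray
    aver_size: dict[str, float]
    tn: dict[str, float]
    fn: dict[str, float]
    fn_per_replicate: dict[str, np.ndarray]
    true_size: dict[str, int]
    n_replicates: int

    def to_dict(self) -> dict:
        """Selection metrics are reported both raw and as percentages of the
        true model size (aver.size, FN) or true zero count (TN)."""
        selection = {}
        for side in self.aver_size:
            n_nonzero = self.true_size[side]
            n_zero = self._p - n_nonzero
            selection[side] = {
                "aver_size": self.aver_size[side],
                "aver_size_pct": 100.0 * self.aver_size[side] / n_nonzero,
                "tn": self.tn[side],
                "tn_pct": 100.0 * self.tn[side] / n_zero if n_zero else 0.0,
                "fn": self.fn[side],
                "fn_pct": 100.0 * self.fn[side] / n_nonzero,
            }
        return {
            "n_replicates": self.n_replicates,
            "parameters": {
                name: {"truth": float(t), "bias": float(b),
                       "rmse": float(r), "cp95": float(c)}
                for name, t, b, r, c in zip(
                    self.params, self.truth, self.bias, self.rmse, self.cp95)
            },
            "selection": selection,
        }

    @property
    def _p(self) -> int:
        return sum(1 for name in self.params if name.startswith("theta"))


def replicate_metrics(
    fits: list[PosteriorSummary],
    theta_true: np.ndarray,
    beta_true: np.ndarray,
    sigma_truth: tuple[float, float, float] | None = None,
) -> ReplicateReport:
    """BIAS/RMSE/CP95 per parameter and aver.size/TN/FN per submodel.

    ``sigma_truth`` optionally supplies (sigma_u2, sigma_xi2, sigma_eps2) so
    the variance parameters are scored too.
    """
    if not fits:
        raise ValueError("need at least one fit")
    theta_true = np.asarray(theta_true, dtype=float)
    beta_true = np.asarray(beta_true, dtype=float)
    p = theta_true.size
    if any(f.theta_mean.size != p or f.beta_mean.size != p for f in fits):
        raise ValueError("fit dimension does not match truth")

    names: list[str] = []
    truths: list[float] = []
    est_cols: list[np.ndarray] = []
    lo_cols: list[np.ndarray] = []
    hi_cols: list[np.ndarray] = []

    th_est = np.array([f.theta_mean for f in fits])
    th_lo = np.array([f.theta_lower for f in fits])
    th_hi = np.array([f.theta_upper for f in fits])
    be_est = np.array([f.beta_mean for f in fits])
    be_lo = np.array([f.beta_lower for f in fits])
    be_hi = np.array([f.beta_upper for f in fits])

    for j in range(p):
        names.append(f"theta{j + 1}")
        truths.append(theta_true[j])
        est_cols.append(th_est[:, j]); lo_cols.append(th_lo[:, j]); hi_cols.append(th_hi[:, j])
    for j in range(p):
        names.append(f"beta{j + 1}")
        truths.append(beta_true[j])
        est_cols.append(be_est[:, j]); lo_cols.append(be_lo[:, j]); hi_cols.append(be_hi[:, j])
    if sigma_truth is not None:
        for name, t in zip(("sigma_u2", "sigma_xi2", "sigma_eps2"), sigma_truth):
            names.append(name)
            truths.append(t)
            trip = np.array([getattr(f, name) for f in fits])
            est_cols.append(trip[:, 0]); lo_cols.append(trip[:, 1]); hi_cols.append(trip[:, 2])

    est = np.column_stack(est_cols)
    lo = np.column_stack(lo_cols)
    hi = np.column_stack(hi_cols)
    tr = np.asarray(truths)
    bias = est.mean(axis=0) - tr
    rmse = np.sqrt(np.mean((est - tr) ** 2, axis=0))
    cp95 = np.mean((lo <= tr) & (tr <= hi), axis=0)

    aver_size, tn, fn, fn_rep, true_size = {}, {}, {}, {}, {}
    for side, e_lo, e_hi, truth_vec in (
        ("longitudinal", th_lo, th_hi, theta_true),
        ("survival", be_lo, be_hi, beta_true),
    ):
        positive = selection_labels(e_lo, e_hi)  # (R, p) boolean
        nonzero = truth_vec != 0
        aver_size[side] = float(positive.sum(axis=1).mean())
        tn[side] = float((~positive[:, ~nonzero]).sum(axis=1).mean())
        fn_counts = (~positive[:, nonzero]).sum(axis=1)
        fn[side] = float(fn_counts.mean())
        fn_rep[side] = fn_counts.astype(float)
        true_size[side] = int(nonzero.sum())

    return ReplicateReport(
        params=names, truth=tr, bias=bias, rmse=rmse, cp95=cp95,
        aver_size=aver_size, tn=tn, fn=fn, fn_per_replicate=fn_rep,
        true_size=true_size, n_replicates=len(fits),
    )
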
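"""Fit one Gibbs chain to a simulated dataset and summarize the posterior.

Simulates a Scenario-I dataset, runs the Bayesian Lasso sampler, and prints
posterior means with 95% credible intervals against the known truth.  Takes a
few seconds.
"""

import numpy as np

from icjm import (
    PriorConfig,
    SimulationDesign,
    run_chain,
    simulate_dataset,
    summarize_fit,
)

design = SimulationDesign(n=500, scenario="I", sigma_u2=0.25, sigma_eps2=1.0,
                          seed=42)
dataset, truth = simulate_dataset(design)

draws = run_chain(dataset, PriorConfig(variant="BL"),
                  iters=3000, burnin=500, seed=1)
summary = summarize_fit(draws)

print(f"{'':10s}{'truth':>8s}{'mean':>8s}{'2.5%':>8s}{'97.5%':>8s}")
for j in range(dataset.p):
    print(f"theta_{j + 1:<4d}{truth.theta_true[j]:8.1f}"
          f"{summary.theta_mean[j]:8.3f}{summary.theta_lower[j]:8.3f}"
          f"{summary.theta_upper[j]:8.3f}")
for j in range(dataset.p):
    print(f"beta_{j + 1:<5d}{truth.beta_true[j]:8.1f}"
          f"{summary.beta_mean[j]:8.3f}{summary.beta_lower[j]:8.3f}"
          f"{summary.beta_upper[j]:8.3f}")
for name, t in (("sigma_u2", truth.sigma_u2), ("sigma_xi2", truth.sigma_xi2),
                ("sigma_eps2", truth.sigma_eps2)):
    m, lo, hi = getattr(summary, name)
    print(f"{name:<10s}{t:8.2f}{m:8.3f}{lo:8.3f}{hi:8.3f}")
m, lo, hi = summary.tau
print(f"{'tau':<10s}{'':8s}{m:8.3f}{lo:8.3f}{hi:8.3f}")
print("\nCoefficients whose 95% interval excludes 0 are 'selected'; the "
      "variance rows recover the frailty/error structure, and tau is the "
      "posterior of the y-vs-event-time association.")
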
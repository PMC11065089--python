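"""Compare the four selection priors on one dataset.

Fits the Bayesian Lasso (BL), adaptive Lasso (BAL), spike-and-slab (SS) and
general-normal (GB) samplers to the same Scenario-I dataset and prints, per
sampler, which covariates each submodel selects (95% interval excluding 0).
Runs in under half a minute.
"""

import numpy as np

from icjm import (
    PriorConfig,
    SimulationDesign,
    run_chain,
    selection_labels,
    simulate_dataset,
    summarize_fit,
)

design = SimulationDesign(n=500, scenario="I", sigma_u2=0.25, sigma_eps2=0.25,
                          seed=11)
dataset, truth = simulate_dataset(design)
print("true nonzero theta:", np.flatnonzero(truth.theta_true) + 1)
print("true nonzero beta: ", np.flatnonzero(truth.beta_true) + 1)

for variant in ("BL", "BAL", "SS", "GB"):
    draws = run_chain(dataset, PriorConfig(variant=variant),
                      iters=3000, burnin=500, seed=2)
    s = summarize_fit(draws)
    sel_theta = np.flatnonzero(selection_labels(s.theta_lower, s.theta_upper)) + 1
    sel_beta = np.flatnonzero(selection_labels(s.beta_lower, s.beta_upper)) + 1
    print(f"{variant:>3s}: longitudinal selects {[int(j) for j in sel_theta]}, "
          f"survival selects {[int(j) for j in sel_beta]}")
print("\nA sampler performs well when each selected set matches the true "
      "nonzero indices; shrinkage priors should drop the zero coefficients "
      "that the general prior (GB) keeps borderline.")
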
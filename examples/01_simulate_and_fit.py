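"""Simulate one Q-learning forager and recover its parameters by MLE.

A softmax Q-learner (learning rate 0.3, inverse temperature 4) forages for
2000 trials on the stable reversal schedule; its choices are then refitted
with multi-start maximum likelihood.  The fitted alpha/beta should land
close to the generating values, and the fitted likelihood can never be
worse than the truth's own likelihood on the same data.
"""

from batbandit import (
    ModelSpec, fit_model, make_schedule, negative_log_likelihood, simulate_agent,
)

spec = ModelSpec("rl", "reset")
true_params = {"alpha": 0.3, "beta": 4.0}

schedule = make_schedule("stable", 2000)
session = simulate_agent(spec, true_params, schedule, seed=1)
print(f"simulated {session.n_trials} trials, "
      f"success rate {session.rewards.mean():.3f}")

fit = fit_model([session], spec, n_starts=50, seed=2)
nll_truth = negative_log_likelihood([session], spec, true_params)
print(f"true params:   alpha=0.300 beta=4.000  NLL={nll_truth:.2f}")
print(f"fitted params: alpha={fit.params['alpha']:.3f} "
      f"beta={fit.params['beta']:.3f}  NLL={fit.nll:.2f}  BIC={fit.bic:.1f}")
print("The fitted NLL is at or below the truth's (same surface, optimised), "
      "and alpha is recovered to within a few hundredths at this data size.")
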
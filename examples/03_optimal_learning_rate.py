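"""Grid-search the learning rate that maximises foraging success.

Simulates 108 softmax Q-learning agents per grid point for 2000 trials in
each environment and reports mean success per learning rate.  In the
volatile environment (reversal every 13 trials) a maximal learning rate is
optimal — only the very last outcome is worth tracking — while the stable
environment favours a moderate rate that smooths over reward noise.
"""

from batbandit import grid_search_alpha

for env in ("stable", "volatile"):
    res = grid_search_alpha(env, n_agents=108, n_trials=2000, seed=123)
    print(f"\n{env} environment (n_agents={res.n_agents}, "
          f"n_trials={res.n_trials}):")
    for alpha, mean, sd in zip(res.grid, res.mean_success, res.sd_success):
        bar = "#" * int((mean - 0.45) * 200) if mean > 0.45 else ""
        print(f"  alpha={alpha:3.1f}  success={mean:.3f} +/- {sd:.3f}  {bar}")
    print(f"  optimal learning rate: {res.best_alpha}")
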
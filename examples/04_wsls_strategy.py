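"""Win-Stay-Lose-Shift: simulated success, its exact expectation, and the
percentile comparison against an observed success rate.

The pure strategy (always stay after a win, always shift after a loss) has
a closed-form expected success on any periodic reversal schedule, obtained
by iterating the two-state Markov chain of 'sitting on the currently good
feeder'.  On the 13-trial volatile schedule that value is
(12 x 0.68 + 0.32)/13 = 0.6523.  The Monte-Carlo simulator should agree
within its standard error, and an animal foraging at chance (0.5) should
fall in the lowest 5% of the simulated distribution.
"""

import math

from batbandit import make_schedule, percentile_test, wsls_expected_success, wsls_grid

schedule = make_schedule("volatile", 2000)
exact = wsls_expected_success(schedule, p_stay=1.0, p_shift=1.0)
print(f"exact expected success of pure WSLS (volatile): {exact:.4f}")

res = wsls_grid("volatile", grid=[1.0], n_sims=100, n_trials=2000, seed=7)
mean = res.mean_success[0, 0]
se = res.sd_success[0, 0] / math.sqrt(res.n_sims)
print(f"simulated (100 runs x 2000 trials): {mean:.4f} +/- {se:.4f} (SE)")

observed = 0.50  # e.g. an animal foraging at chance
verdict = percentile_test(observed, res.per_sim_success[0, 0])
print(f"observed success {observed:.2f} vs simulations: tail={verdict.tail} "
      f"(rank {verdict.rank_low} of {verdict.n_simulations} from below)")
print("'low' means the observation sits in the lowest 5% of simulated "
      "success rates - the animal does significantly worse than the strategy.")
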
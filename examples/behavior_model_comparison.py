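"""Fit the RL model family to a simulated session and compare variants.

The reversal learner updates both the chosen object's value (toward the
reward) and the unchosen object's value (away from it), matching the blocked
probability reversals of the task.  We simulate sessions with that learner
and check that information criteria pick it over the basic delta rule.
"""

import viewchoice as vc

true = vc.RLParams(variant="reversal", alpha=0.3, beta=3.0)
sessions = []
for s in range(6):
    sched = vc.generate_schedule("main", 200, seed=10 + s)
    sessions.append(vc.simulate_agent(sched, true, seed=50 + s))

fit = vc.fit_rl(sessions[0], "reversal", n_restarts=8, seed=0)
print(f"session 0 fit: alpha={fit.params.alpha:.2f} beta={fit.params.beta:.2f} "
      f"negLL={fit.neg_loglik:.1f} AIC={fit.aic:.1f}")
print("(alpha is the learning rate per trial; beta the softmax inverse "
      "temperature - larger means more deterministic choices)")

table = vc.compare_models(sessions, variants=("basic", "reversal"),
                          n_restarts=5, seed=1)
print("\nmodel comparison over 6 sessions (lower AIC/BIC is better):")
print(table[["k", "sum_aic", "sum_bic", "aic_wins"]].round(1))
winner = table["sum_aic"].idxmin()
print(f"\nsummed AIC prefers the '{winner}' variant - the update of the "
      "unchosen option pays off under blocked reversals.")
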
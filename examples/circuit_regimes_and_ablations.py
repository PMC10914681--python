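"""Attractor structure of the circuit's switch and decision stages, and what
breaks when pieces are removed.
"""

import numpy as np

import viewchoice as vc

params = vc.NetworkParams(eta=0.0)

print("switch (E-I) fixed points vs drive b:")
for b in (0.5, 1.5, 3.0):
    d = vc.switch_bifurcation(params, np.array([b]))
    stable, unstable = d.counts(0)
    print(f"  b={b:.1f}: {stable} stable, {unstable} unstable")
print("two stable branches coexist until the saddle-node at b ~ 2.05; the\n"
      "facilitated object drive crosses it only during the second cue.\n")

print("decision-stage regime vs background input I0:")
table = vc.decision_regime(params, np.array([-2.0, -0.6, 0.5]))
for _, row in table.iterrows():
    print(f"  I0={row['I0']:+.1f}: {row['regime']} "
          f"({row['n_stable']} stable fixed points)")
print("the switch moves the pair from the non-competing regime into the\n"
      "winner-take-all window and back out is never needed: choice latches.\n")

print("architecture ablations (noise-free battery of value pairs):")
for variant in ("no_switch", "object_specific_view", "positive_tuned_wMC08",
                "classical_simultaneous"):
    rep = vc.run_ablation(variant, seed=0)
    print(f"  {variant:24s} {rep.verdict}")
print("\nonly the full architecture both compares sequential values correctly "
      "and extends to new objects without rewiring.")
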
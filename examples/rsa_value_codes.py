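"""Representational similarity analysis of value codes.

Condition-mean population vectors (object x value quartile) are correlated
across neurons; model templates then compete to explain the similarity
matrix.  An object-specific value population yields within-object value
structure only; a view-based population yields value structure that crosses
objects.
"""

import numpy as np
import pandas as pd

import viewchoice as vc

sched = vc.generate_schedule("main", 300, seed=21)
beh = vc.simulate_agent(sched, vc.RLParams(alpha=0.3, beta=3.0, mag_weight=1.0),
                        seed=22)
values = vc.session_values(beh)

first_obj = beh.trials["first_object"].to_numpy()
v1 = values["v_first"].to_numpy()
level = np.zeros(len(v1), dtype=int)
for obj in ("A", "B"):
    sel = first_obj == obj
    level[sel] = vc.value_quartile_labels(v1[sel])
labels = pd.DataFrame({"object": first_obj, "value_level": level})

for kind, spec in [("object-specific", {"object_value_A": 0.5,
                                        "object_value_B": 0.5}),
                   ("view-based", {"view_value_pos": 0.6,
                                   "view_value_neg": 0.4})]:
    pop = vc.generate_population(spec, 60, seed=31, gain_median_hz=14.0)
    rec = vc.generate_spike_counts(pop, beh, "parametric", seed=32,
                                   values=values)
    zs = vc.zscore_epochs(rec)
    cm, rsam = vc.condition_rsa(zs.data["cue1"], labels)
    templates = vc.build_templates(cm.conditions,
                                   which=["identity", "object", "view_value",
                                          "object_value"])
    reg = vc.rsa_regression(cm, templates, n_perm=2000, seed=5)
    print(f"{kind} population:")
    for j, name in enumerate(reg.names):
        print(f"  {name:12s} t={reg.t[j]:+7.2f}  partial R2="
              f"{reg.partial_r2[j]:.3f}  perm_p={reg.perm_p[name]:.3f}")
    print()
print("the object-specific population is dominated by object-identity "
      "structure (its positive value responses separate the objects into "
      "blocks; the value gradation rides on top), while the view-based "
      "population is explained by the view-based value template.  Note the "
      "permutation p for the object partition has a floor of ~0.029 with 8 "
      "conditions: only the 1,152 of 40,320 relabelings that preserve the "
      "4/4 block structure reproduce its fit.")
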
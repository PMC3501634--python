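"""The twelve microsatellite mutation models as CTMCs on a bounded
repeat-count lattice: rate matrices, transition probabilities, and
stationary distributions.
"""

import numpy as np

import msatdemog as md

for name in ("EU1", "PU2", "EL2"):
    model = md.MutationModel.from_name(name, i_min=1, i_max=35)
    q = md.build_rate_matrix(model)
    pi = md.stationary_distribution(q)
    states = model.states
    mean_len = float(pi @ states)
    p = md.transition_probabilities(q, 0.5)
    print(f"{name}: {model.rate_law}/{model.bias_law}/{model.step_law}  "
          f"stationary mean length {mean_len:.1f} repeats, "
          f"P(stay | t=0.5) at 10 repeats = {p[9, 9]:.3f}")
# Rates are normalized so each model produces one expected mutation per
# lineage per unit time at stationarity; branch lengths are therefore
# comparable across models.
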
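"""Population-structure screen: R_ST with permutation tests, 4Nm, and the
delta-mu^2 neighbor-joining split between groups.

A negative or near-zero R_ST with a non-significant permutation p means
the groups behave as one panmictic population.
"""

import numpy as np

import msatdemog as md

rng = np.random.default_rng(3)
g = md.kibale_preset(rng)
screen = md.rst_screen(g, n_perm=1000, rng=rng)
print(f"overall R_ST = {screen.rst_overall:.4f}  (permutation p = "
      f"{screen.p_overall:.3f})")
print(f"4Nm = {screen.four_nm if screen.four_nm is not None else 'undefined (R_ST <= 0)'}")
print("pairwise R_ST:")
print(screen.pairwise_rst.round(3).to_string())

d, newick, split = md.delta_mu2_nj(g)
print("\ndelta-mu^2 distances:")
print(d.round(3).to_string())
print(f"deepest NJ split: {split[0]} | {split[1]}")
# With high gene flow the split is arbitrary and R_ST ~ 0: one population.
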
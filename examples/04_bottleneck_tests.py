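"""Recent-bottleneck screens: heterozygote excess under the two-phase
mutation model, the allele-frequency mode shift, and the Garza-Williamson
M-ratio with a simulation null.
"""

import numpy as np

import msatdemog as md
from msatdemog.bottleneck import BOTTLENECK_TPM, M_RATIO_TPM

rng = np.random.default_rng(4)
g = md.kibale_preset(rng)

het = md.het_excess_test(g, BOTTLENECK_TPM, n_sim=200, rng=rng)
print(f"one-tailed Wilcoxon heterozygote-excess p = {het.wilcoxon_p:.3f}")
print(f"mode-shift descriptor: {md.mode_shift(g)}")

mrt = md.m_ratio_test(g, theta=2.0, params=M_RATIO_TPM, n_sim=1000, rng=rng)
print(f"mean M-ratio = {mrt.m_mean:.3f}  (simulation p = {mrt.m_p:.3f})")
# Non-significant p-values, an L-shaped frequency distribution, and a large
# M-ratio (near 1) all indicate a population of stable size: no recent
# bottleneck.
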
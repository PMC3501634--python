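"""Coalescent tree priors and Felsenstein pruning likelihoods for
microsatellite genealogies.
"""

from __future__ import annotations

import math

import numpy as np

from .coalescent import Demography, Genealogy
from .genotypes import MISSING
from .mutation import MutationModel, SpectralTransitions, build_rate_matrix


def coalescent_loglik(tree: Genealogy, dem: Demography) -> float:
    """Log density of a genealogy under the time-inhomogeneous coalescent.

    Sum over inter-event intervals of -C(k,2) * integral dt/theta(t), plus
    -ln theta(t_c) at each coalescence; the per-segment integrals are exact
    for the supported demographies.
    """
    coal = np.sort(tree.coalescence_times())
    n = tree.n_tips
    ks = np.arange(n, 1, -1)
    pair = ks * (ks - 1) / 2.0
    lam = dem.cumulative_rate(coal)
    dlam = np.diff(np.concatenate(([0.0], lam)))
    return float(-(pair * dlam).sum() - np.log(dem.theta_vec(coal)).sum())


def pruning_loglik(
    tips: np.ndarray,
    tree: Genealogy,
    model: MutationModel,
    rate_modifier: float = 1.0,
    trans: SpectralTransitions | None = None,
) -> float:
    """Felsenstein pruning log likelihood of tip repeat counts.

    Transition matrices are exp(Q * rate_modifier * branch length); the root
    is weighted by the model's stationary distribution; a missing tip
    (:data:`MISSING`) contributes an all-ones partial.  Partial vectors are
    rescaled at every internal node so long trees do not underflow.
    """
    if trans is None:
        trans = SpectralTransitions(build_rate_matrix(model))
    tips = np.asarray(tips)
    n = tree.n_tips
    if tips.shape != (n,):
        raise ValueError(f"expected {n} tip states, got {tips.shape}")
    s = trans.q.shape[0]
    present = tips != MISSING
    if present.any():
        lo, hi = tips[present].min(), tips[present].max()
        if lo < model.i_min or hi > model.i_max:
            raise ValueError(
                f"tip state outside lattice [{model.i_min}, {model.i_max}]"
            )

    bl = tree.branch_lengths() * rate_modifier
    p_mats = trans.batch(bl)  # (2n-1, S, S)

    partials = np.empty((2 * n - 1, s))
    partials[:n] = 0.0
    partials[:n][~present] = 1.0
    idx = np.nonzero(present)[0]
    partials[idx, tips[idx] - model.i_min] = 1.0

    log_scale = 0.0
    for k in range(n - 1):
        a, b = tree.children[k]
        node = n + k
        v = (p_mats[a] @ partials[a]) * (p_mats[b] @ partials[b])
        top = v.max()
        if top <= 0.0:
            return -math.inf
        partials[node] = v / top
        log_scale += math.log(top)
    root_lik = float(trans.pi @ partials[tree.root])
    if root_lik <= 0.0:
        return -math.inf
    return math.log(root_lik) + log_scale
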
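"""The twelve microsatellite mutation models as continuous-time Markov
chains on a bounded repeat-count lattice.

Each model is a point in the cross product

* rate law: EQUAL (rate independent of length) or PROPORTIONAL (rate grows
  linearly with the number of repeats);
* bias law: UNBIASED (expansion and contraction equiprobable), CONSTANT
  (a fixed expansion probability from a logistic intercept), or LINEAR
  (logistic in allele length, so the expansion probability falls or rises
  with the repeat number);
* step law: ONE_STEP (all mutations change the length by one repeat) or
  MULTI_STEP (geometric step-size distribution, one or more repeats).

giving the model names EU1, EU2, EC1, ..., PL2.  The directional bias is a
logistic regression on lattice position: the probability that a mutation is
an expansion is ``expit(b0 + b1*(i - i_min))``.

All rate matrices are rescaled so that the stationary-weighted mean mutation
rate is exactly 1, which makes branch lengths comparable across models
(time is then measured in expected mutations per lineage).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import expm
from scipy.special import expit

RATE_LAWS = ("EQUAL", "PROPORTIONAL")
BIAS_LAWS = ("UNBIASED", "CONSTANT", "LINEAR")
STEP_LAWS = ("ONE_STEP", "MULTI_STEP")

#: The twelve canonical model names: {E,P} x {U,C,L} x {1,2}.
MODEL_NAMES = tuple(
    f"{r}{b}{s}" for r in "EP" for b in "UCL" for s in "12"
)


@dataclass(frozen=True)
class MutationModel:
    """One bounded-lattice microsatellite mutation CTMC.

    Parameters
    ----------
    rate_law, bias_law, step_law:
        Model family axes (see module docstring).
    alpha:
        Base mutation rate (the overall scale is later normalized away).
    b0, b1:
        Logistic bias coefficients.  UNBIASED forces b0 = b1 = 0; CONSTANT
        forces b1 = 0.
    m:
        Geometric step-size parameter in (0, 1]; the unconditional step size
        is Geometric(m) on {1, 2, ...} with mean 1/m.  Ignored by ONE_STEP.
    i_min, i_max:
        Inclusive repeat-count lattice bounds.
    """

    rate_law: str = "EQUAL"
    bias_law: str = "UNBIASED"
    step_law: str = "ONE_STEP"
    alpha: float = 1.0
    b0: float = 0.0
    b1: float = 0.0
    m: float = 1.0 / 2.8
    i_min: int = 1
    i_max: int = 35

    def __post_init__(self) -> None:
        if self.rate_law not in RATE_LAWS:
            raise ValueError(f"rate_law must be one of {RATE_LAWS}")
        if self.bias_law not in BIAS_LAWS:
            raise ValueError(f"bias_law must be one of {BIAS_LAWS}")
        if self.step_law not in STEP_LAWS:
            raise ValueError(f"step_law must be one of {STEP_LAWS}")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not 0 < self.m <= 1:
            raise ValueError("geometric step parameter m must lie in (0, 1]")
        if self.i_max - self.i_min < 1:
            raise ValueError("lattice must contain at least two states")
        if self.bias_law == "UNBIASED" and (self.b0 != 0 or self.b1 != 0):
            raise ValueError("UNBIASED forces b0 = b1 = 0")
        if self.bias_law == "CONSTANT" and self.b1 != 0:
            raise ValueError("CONSTANT bias forces b1 = 0")

    @property
    def name(self) -> str:
        return (
            self.rate_law[0]
            + self.bias_law[0]
            + ("1" if self.step_law == "ONE_STEP" else "2")
        )

    @property
    def n_states(self) -> int:
        return self.i_max - self.i_min + 1

    @property
    def states(self) -> np.ndarray:
        return np.arange(self.i_min, self.i_max + 1)

    @classmethod
    def from_name(cls, name: str, **kwargs) -> "MutationModel":
        """Build a model from its two-letter-plus-digit name (e.g. ``"PU2"``).

        Keyword arguments override the default parameters; bias coefficients
        incompatible with the named bias law raise.
        """
        name = name.upper()
        if len(name) != 3 or name not in MODEL_NAMES:
            raise ValueError(f"unknown model name {name!r}; expected one of {MODEL_NAMES}")
        rate = {"E": "EQUAL", "P": "PROPORTIONAL"}[name[0]]
        bias = {"U": "UNBIASED", "C": "CONSTANT", "L": "LINEAR"}[name[1]]
        step = {"1": "ONE_STEP", "2": "MULTI_STEP"}[name[2]]
        if bias == "UNBIASED":
            kwargs.setdefault("b0", 0.0)
            kwargs.setdefault("b1", 0.0)
        elif bias == "CONSTANT":
            # mild fixed expansion bias so the named model differs from U
            kwargs.setdefault("b0", 0.4)
            kwargs.setdefault("b1", 0.0)
        else:  # LINEAR: expansion-prone when short, contraction-prone when long
            kwargs.setdefault("b0", 1.0)
            kwargs.setdefault("b1", -0.1)
        return cls(rate_law=rate, bias_law=bias, step_law=step, **kwargs)

    def to_dict(self) -> dict:
        return {
            "rate_law": self.rate_law, "bias_law": self.bias_law,
            "step_law": self.step_law, "alpha": self.alpha,
            "b0": self.b0, "b1": self.b1, "m": self.m,
            "i_min": self.i_min, "i_max": self.i_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MutationModel":
        return cls(**d)


def build_rate_matrix(model: MutationModel, rescale: bool = True) -> np.ndarray:
    """Rate matrix Q of the model on its lattice.

    Per-state total rate is ``alpha`` (EQUAL) or ``alpha*(i - i_min + 1)``
    (PROPORTIONAL); a fraction ``expit(b0 + b1*(i - i_min))`` of mutations
    are expansions.  Step sizes are 1 (ONE_STEP) or Geometric(m)
    (MULTI_STEP) truncated at the lattice boundary and renormalized within
    the chosen direction.  Moves that would exit the lattice in a direction
    with no room at all are dropped, so boundary states mutate at a reduced
    total rate.  With ``rescale`` the matrix is divided by the
    stationary-weighted mean rate so the chain produces one expected
    mutation per unit time at stationarity.
    """
    s = model.n_states
    pos = np.arange(s)
    rates = model.alpha * (pos + 1.0) if model.rate_law == "PROPORTIONAL" \
        else np.full(s, model.alpha)
    gamma = expit(model.b0 + model.b1 * pos)
    q = np.zeros((s, s))
    for i in range(s):
        up_room = s - 1 - i
        down_room = i
        for direction, room, frac in (
            (+1, up_room, gamma[i]),
            (-1, down_room, 1.0 - gamma[i]),
        ):
            if room == 0 or frac == 0.0:
                continue
            if model.step_law == "ONE_STEP":
                q[i, i + direction] += rates[i] * frac
            else:
                steps = np.arange(1, room + 1)
                w = (1 - model.m) ** (steps - 1) * model.m
                w = w / w.sum()  # renormalize within the direction
                q[i, i + direction * steps] += rates[i] * frac * w
    np.fill_diagonal(q, -q.sum(axis=1))
    if rescale:
        pi = stationary_distribution(q)
        mean_rate = float(pi @ (-np.diag(q)))
        q = q / mean_rate
    return q


def stationary_distribution(q: np.ndarray) -> np.ndarray:
    """Stationary distribution pi with pi Q = 0 and sum(pi) = 1.

    Solved as a bordered linear system; raises if the chain is reducible
    (the stationary vector is then not strictly positive and unique).
    """
    s = q.shape[0]
    # an irreducible generator has rank exactly s-1
    if np.linalg.matrix_rank(q) < s - 1:
        raise ValueError("rate matrix is reducible")
    a = np.vstack([q.T, np.ones(s)])
    b = np.zeros(s + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    if np.any(pi < -1e-9) or not np.isclose(pi.sum(), 1.0, atol=1e-8):
        raise ValueError("rate matrix appears reducible; no valid stationary vector")
    resid = float(np.max(np.abs(pi @ q)))
    if resid > 1e-8 * max(1.0, float(np.max(np.abs(q)))):
        raise ValueError("rate matrix appears reducible (pi Q != 0)")
    pi = np.clip(pi, 0, None)
    return pi / pi.sum()


def transition_probabilities(q: np.ndarray, t: float) -> np.ndarray:
    """Transition matrix exp(Qt) for branch length t >= 0."""
    if t < 0:
        raise ValueError("branch length must be >= 0")
    if t == 0:
        return np.eye(q.shape[0])
    return expm(q * t)


class SpectralTransitions:
    """Eigendecomposition of a rate matrix for fast repeated exp(Qt).

    ``probs(t)`` returns exp(Qt) from the cached decomposition; ``batch(ts)``
    evaluates many branch lengths at once (shape (len(ts), S, S)).  Falls
    back to scipy's expm when the eigenbasis is ill-conditioned.
    """

    def __init__(self, q: np.ndarray):
        self.q = np.asarray(q, dtype=float)
        self.pi = stationary_distribution(self.q)
        # reversible chains admit a real symmetric decomposition, which is
        # both faster and numerically cleaner than the complex general case
        flux = self.pi[:, None] * self.q
        if np.allclose(flux, flux.T, atol=1e-12 * max(1.0, np.abs(q).max())):
            d = np.sqrt(np.clip(self.pi, 1e-300, None))
            sym = (d[:, None] * self.q) / d[None, :]
            w, u = np.linalg.eigh((sym + sym.T) / 2.0)
            self.w = w
            self.v = u / d[:, None]
            self.vinv = u.T * d[None, :]
            self._ok = True
            self._real = True
            return
        self._real = False
        w, v = np.linalg.eig(self.q)
        try:
            vinv = np.linalg.inv(v)
            cond = np.linalg.cond(v)
        except np.linalg.LinAlgError:
            cond = np.inf
            vinv = None
        self._ok = np.isfinite(cond) and cond < 1e10
        if self._ok:
            self.w, self.v, self.vinv = w, v, vinv

    def probs(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("branch length must be >= 0")
        if not self._ok:
            return transition_probabilities(self.q, t)
        p = (self.v * np.exp(self.w * t)) @ self.vinv
        if not self._real:
            p = np.real(p)
        np.clip(p, 0.0, None, out=p)
        return p / p.sum(axis=1, keepdims=True)

    def batch(self, ts: np.ndarray) -> np.ndarray:
        ts = np.asarray(ts, dtype=float)
        if np.any(ts < 0):
            raise ValueError("branch lengths must be >= 0")
        if not self._ok:
            return np.stack([transition_probabilities(self.q, t) for t in ts])
        e = np.exp(np.multiply.outer(ts, self.w))  # (B, S)
        p = (self.v[None, :, :] * e[:, None, :]) @ self.vinv
        if not self._real:
            p = np.real(p)
        np.clip(p, 0.0, None, out=p)
        return p / p.sum(axis=2, keepdims=True)


def all_models(**kwargs) -> dict[str, MutationModel]:
    """The full named family as a dict, with shared parameter overrides."""
    return {name: MutationModel.from_name(name, **kwargs) for name in MODEL_NAMES}
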
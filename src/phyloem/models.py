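"""K2P substitution model and the I + discrete-Gamma site-rate mixture.

The Kimura two-parameter (K2P) model has uniform base frequencies and
distinct transition/transversion rates. Rate heterogeneity among sites is
modelled as a (k+1)-component mixture: a zero-rate "invariable" category
with weight p_inv, and k discrete-Gamma categories (equal-probability
discretization represented by category means, Yang-style) sharing weight
(1 - p_inv)/k each. The mixture is normalized so the overall mean rate is
one, keeping branch lengths in expected substitutions per site averaged
over all sites.

State order throughout the package: A=0, C=1, G=2, T=3. Transitions are
the purine (A<->G) and pyrimidine (C<->T) exchanges, i.e. state pairs of
equal parity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import gammainc, gammaincinv

__all__ = [
    "K2PModel",
    "RateMixture",
    "k2p_transition_matrix",
    "k2p_transition_derivatives",
    "discrete_gamma_rates",
    "build_rate_mixture",
    "kappa_from_tstv_counts",
    "tstv_counts_from_kappa",
]

#: number of nucleotide states
N_STATES = 4

#: uniform stationary distribution of K2P
STATIONARY_FREQS = np.full(4, 0.25)

# Index pattern of the 4x4 matrix: 0 = identity, 1 = transition, 2 = transversion.
_KIND = np.array(
    [[0, 2, 1, 2],
     [2, 0, 2, 1],
     [1, 2, 0, 2],
     [2, 1, 2, 0]],
    dtype=np.int64,
)


def kappa_from_tstv_counts(R: float) -> float:
    """Convert an expected-counts ts/tv ratio R to the rate ratio kappa.

    Under uniform base frequencies each state has one transition partner
    and two transversion partners, so R = kappa/2.
    """
    if R <= 0:
        raise ValueError("ts/tv ratio must be positive")
    return 2.0 * R


def tstv_counts_from_kappa(kappa: float) -> float:
    """Expected-counts ts/tv ratio R = kappa/2 (uniform frequencies)."""
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    return kappa / 2.0


@dataclass(frozen=True)
class K2PModel:
    """Kimura 1980 model, scaled to mean substitution rate one.

    Parameters
    ----------
    kappa
        Transition/transversion *rate* ratio. ``kappa=1`` reduces to
        Jukes-Cantor; the Seq-Gen style expected-counts ratio is
        ``kappa/2``.
    """

    kappa: float = 4.0

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")

    @property
    def tstv_counts_ratio(self) -> float:
        return tstv_counts_from_kappa(self.kappa)

    @classmethod
    def from_tstv_counts(cls, R: float) -> "K2PModel":
        return cls(kappa=kappa_from_tstv_counts(R))

    def transition_matrix(self, t: float | np.ndarray) -> np.ndarray:
        return k2p_transition_matrix(t, self.kappa)


def _k2p_exponents(t: np.ndarray, kappa: float) -> tuple[np.ndarray, np.ndarray, float, float]:
    # mean-rate-1 scaling: per-target transversion rate beta, transition
    # rate alpha = kappa*beta; mean rate = beta*(kappa+2) = 1
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = np.exp(-4.0 * beta * t)
    e2 = np.exp(-2.0 * (alpha + beta) * t)
    return e1, e2, alpha, beta


def k2p_transition_matrix(t: float | np.ndarray, kappa: float) -> np.ndarray:
    """K2P transition probability matrix P(t) for branch length t.

    ``t`` may be a scalar or an array; the matrix axes are appended last,
    so an input of shape (...,) yields output of shape (..., 4, 4). Rows
    are probability distributions; with uniform frequencies the matrix is
    symmetric (detailed balance).
    """
    t = np.asarray(t, dtype=np.float64)
    if np.any(t < 0):
        raise ValueError("branch length (time) must be non-negative")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    e1, e2, _, _ = _k2p_exponents(t, kappa)
    probs = np.empty(t.shape + (3,))
    q1 = 0.25 * e1
    h2 = 0.5 * e2
    probs[..., 0] = 0.25 + q1 + h2
    probs[..., 1] = 0.25 + q1 - h2
    probs[..., 2] = 0.25 - q1
    return np.ascontiguousarray(probs[..., _KIND])


def k2p_transition_derivatives(
    t: float | np.ndarray, kappa: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """P(t), dP/dt and d2P/dt2 for the K2P model (shapes (..., 4, 4))."""
    t = np.asarray(t, dtype=np.float64)
    e1, e2, alpha, beta = _k2p_exponents(t, kappa)
    c1 = -4.0 * beta
    c2 = -2.0 * (alpha + beta)
    out = []
    for f1, f2 in ((1.0, 1.0), (c1, c2), (c1 * c1, c2 * c2)):
        q1 = 0.25 * f1 * e1
        h2 = 0.5 * f2 * e2
        m = np.empty(t.shape + (3,))
        m[..., 0] = (0.25 if f1 == 1.0 else 0.0) + q1 + h2
        m[..., 1] = (0.25 if f1 == 1.0 else 0.0) + q1 - h2
        m[..., 2] = (0.25 if f1 == 1.0 else 0.0) - q1
        out.append(np.ascontiguousarray(m[..., _KIND]))
    return out[0], out[1], out[2]


def discrete_gamma_rates(
    alpha: float, k: int, use_median: bool = False
) -> np.ndarray:
    """Discrete-Gamma category rates (equal category probabilities).

    The continuous Gamma(alpha, mean 1) is cut at its j/k quantiles and
    each category is represented by its conditional mean (or median with
    ``use_median=True``). Rates are renormalized to average exactly one,
    absorbing floating-point drift.
    """
    return _discrete_gamma_rates_cached(float(alpha), int(k), bool(use_median)).copy()


@lru_cache(maxsize=4096)
def _discrete_gamma_rates_cached(
    alpha: float, k: int, use_median: bool
) -> np.ndarray:
    if not np.isfinite(alpha):
        raise ValueError("gamma shape alpha must be finite")
    if alpha <= 0:
        raise ValueError("gamma shape alpha must be positive")
    if k < 1:
        raise ValueError("need at least one rate category")
    if k == 1:
        return np.ones(1)
    probs = np.arange(1, k) / k
    # quantiles of Gamma(shape=alpha, rate=alpha), i.e. mean-1 scaling
    cuts = gammaincinv(alpha, probs) / alpha
    if use_median:
        med_probs = (np.arange(k) + 0.5) / k
        rates = gammaincinv(alpha, med_probs) / alpha
    else:
        # E[X ; X <= c] = I(alpha+1, alpha*c) for X ~ Gamma(alpha, alpha)
        upper = np.concatenate([gammainc(alpha + 1.0, alpha * cuts), [1.0]])
        lower = np.concatenate([[0.0], upper[:-1]])
        rates = k * (upper - lower)
    rates = np.maximum(rates, 0.0)
    return rates / rates.mean()


@dataclass(frozen=True)
class RateMixture:
    """The (k+1)-category I + discrete-Gamma site-rate mixture.

    rates[0] = 0 is the invariable category with weight w[0] = p_inv; the
    k Gamma categories share weight (1 - p_inv)/k each and are scaled by
    1/(1 - p_inv) so the overall mean rate sum(w * r) is one.
    """

    alpha: float
    p_inv: float
    k: int = 4
    use_median: bool = False
    rates: np.ndarray = field(init=False, repr=False, compare=False)
    weights: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_inv < 1.0:
            raise ValueError("p_inv must lie in [0, 1)")
        gamma = discrete_gamma_rates(self.alpha, self.k, self.use_median)
        rates = np.concatenate([[0.0], gamma / (1.0 - self.p_inv)])
        weights = np.concatenate(
            [[self.p_inv], np.full(self.k, (1.0 - self.p_inv) / self.k)]
        )
        object.__setattr__(self, "rates", rates)
        object.__setattr__(self, "weights", weights)

    @property
    def n_categories(self) -> int:
        return self.k + 1

    def mean_rate(self) -> float:
        return float(self.weights @ self.rates)


def build_rate_mixture(
    alpha: float, p_inv: float, k: int = 4, use_median: bool = False
) -> RateMixture:
    """Construct the I + discrete-Gamma mixture (see :class:`RateMixture`)."""
    return RateMixture(alpha=alpha, p_inv=p_inv, k=k, use_median=use_median)
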
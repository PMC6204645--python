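"""Pattern-compressed pruning likelihood for the I + discrete-Gamma mixture.

Site patterns are deduplicated (a 6-taxon alignment has at most 4^6
distinct columns, so a 100,000-bp alignment collapses to a few thousand
weighted patterns). Conditional likelihoods are propagated up the tree
with Felsenstein's pruning algorithm, batched over the Gamma categories.
Per-pattern log-scaling guards against underflow on large trees; for
small trees (<= 32 leaves) double precision cannot underflow under the
rates of interest and the scaling pass is skipped, which changes nothing
but the constant zero scalers.

The zero-rate (invariable) category needs no pruning: a pattern can only
be invariable if its non-missing states all agree, in which case its
category-0 likelihood is the stationary frequency 1/4 of the shared state
(1 for an all-missing pattern).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numba
import numpy as np

from .models import (
    K2PModel,
    RateMixture,
    STATIONARY_FREQS,
    k2p_transition_derivatives,
    k2p_transition_matrix,
)
from .simulate import Alignment, MISSING
from .trees import PhyloTree

__all__ = [
    "PatternTable",
    "PatternLikelihoods",
    "compress_patterns",
    "pattern_category_likelihoods",
    "log_likelihood",
    "PruningEngine",
]

_LOG_QUARTER = float(np.log(0.25))

#: trees with at most this many leaves skip the underflow-scaling pass
_NO_SCALING_MAX_LEAVES = 32


@dataclass
class PatternTable:
    """Distinct site patterns with multiplicities.

    ``codes`` is (n_taxa, n_patterns) int8 in the same row order as
    ``labels``; ``counts`` sums to the alignment length ``n``.
    """

    labels: list[str]
    codes: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 1):
            raise ValueError("pattern counts must be at least 1")
        self._inv_logs: np.ndarray | None = None

    @property
    def n(self) -> int:
        """Total number of alignment sites."""
        return int(self.counts.sum())

    @property
    def n_patterns(self) -> int:
        return self.codes.shape[1]

    @property
    def constant_mask(self) -> np.ndarray:
        """True where the non-missing states of a pattern all agree."""
        lo = np.where(self.codes == MISSING, 3, self.codes).min(axis=0)
        hi = np.where(self.codes == MISSING, 0, self.codes).max(axis=0)
        all_missing = (self.codes == MISSING).all(axis=0)
        return (lo >= hi) | all_missing

    def constant_site_fraction(self) -> float:
        """Fraction of sites whose column is constant (non-missing agree)."""
        return float(self.counts[self.constant_mask].sum() / self.n)

    def invariable_log_likelihoods(self) -> np.ndarray:
        """log L[i][0]: log(1/4) for constant, 0 for all-missing, -inf else."""
        if self._inv_logs is None:
            out = np.full(self.n_patterns, -np.inf)
            out[self.constant_mask] = _LOG_QUARTER
            out[(self.codes == MISSING).all(axis=0)] = 0.0
            self._inv_logs = out
        return self._inv_logs

    def invariable_likelihoods(self) -> np.ndarray:
        """Linear-scale category-0 likelihoods: 1/4, 1 or 0."""
        with np.errstate(over="ignore"):
            return np.exp(self.invariable_log_likelihoods())


def compress_patterns(aln: Alignment) -> PatternTable:
    """Collapse alignment columns into unique patterns with counts.

    Patterns are ordered by first occurrence, so the mapping from columns
    to (pattern, multiplicity) pairs is deterministic.
    """
    if aln.n_sites == 0:
        raise ValueError("cannot compress an empty alignment")
    cols = np.ascontiguousarray(aln.codes.T)
    uniq, first, counts = np.unique(
        cols, axis=0, return_index=True, return_counts=True
    )
    order = np.argsort(first, kind="stable")
    return PatternTable(
        labels=list(aln.labels),
        codes=uniq[order].T,
        counts=counts[order],
    )


@dataclass
class PatternLikelihoods:
    """Per-pattern, per-category likelihoods L[i][j] = P(D_i | r_j).

    Stored in log space (``log_lik``, shape (n_patterns, k+1), -inf for
    impossible pattern/category pairs); column 0 is the invariable
    category.
    """

    log_lik: np.ndarray
    counts: np.ndarray = field(repr=False)

    @property
    def likelihoods(self) -> np.ndarray:
        """Linear-scale likelihoods (may underflow to 0 for large trees)."""
        return np.exp(self.log_lik)

    def posterior_invariable(self, mixture: RateMixture) -> np.ndarray:
        """E-step: P(r_0 | D_i) = w_0 L[i][0] / sum_j w_j L[i][j]."""
        return posterior_invariable(self.log_lik, mixture.weights)

    def mixture_log_likelihood(self, mixture: RateMixture) -> float:
        return mixture_loglik(self.log_lik, mixture.weights, self.counts)


# no fastmath here: the kernel must honour -inf entries exactly
@numba.njit(cache=True)
def _mixture_loglik_njit(log_lik, weights, counts):
    npat, ncat = log_lik.shape
    total = 0.0
    bad = -1
    for pat in range(npat):
        m = -np.inf
        for j in range(ncat):
            if weights[j] > 0.0 and log_lik[pat, j] > m:
                m = log_lik[pat, j]
        if not np.isfinite(m):
            bad = pat
            break
        s = 0.0
        for j in range(ncat):
            if weights[j] > 0.0:
                s += weights[j] * np.exp(log_lik[pat, j] - m)
        total += counts[pat] * (np.log(s) + m)
    return total, bad


@numba.njit(cache=True, fastmath=True)
def _root_mix_ll_njit(down_root, pi, inv_lin, weights, counts):
    # mixture log-likelihood straight from the root partials (unscaled
    # path): no log/exp round-trip through the per-category matrix
    ncat, npat = down_root.shape[0], down_root.shape[1]
    total = 0.0
    bad = -1
    w0 = weights[0]
    for pat in range(npat):
        s = w0 * inv_lin[pat]
        for k in range(ncat):
            s += weights[k + 1] * (
                pi[0] * down_root[k, pat, 0]
                + pi[1] * down_root[k, pat, 1]
                + pi[2] * down_root[k, pat, 2]
                + pi[3] * down_root[k, pat, 3]
            )
        if s <= 0.0:
            bad = pat
            break
        total += counts[pat] * np.log(s)
    return total, bad


@numba.njit(cache=True, fastmath=True)
def _root_logs_njit(down_root, pi, inv_logs, out):
    # out: (npat, ncat+1); column 0 = invariable category
    ncat, npat = down_root.shape[0], down_root.shape[1]
    for pat in range(npat):
        out[pat, 0] = inv_logs[pat]
    for k in range(ncat):
        dk = down_root[k]
        for pat in range(npat):
            s = (
                pi[0] * dk[pat, 0]
                + pi[1] * dk[pat, 1]
                + pi[2] * dk[pat, 2]
                + pi[3] * dk[pat, 3]
            )
            out[pat, k + 1] = np.log(s) if s > 0.0 else -np.inf


def _site_mixture_logs(log_lik: np.ndarray, weights: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        logw = np.where(weights > 0, np.log(np.maximum(weights, 1e-300)), -np.inf)
    terms = log_lik + logw[None, :]
    m = terms.max(axis=1)
    shift = np.where(np.isfinite(m), m, 0.0)
    with np.errstate(invalid="ignore"):
        s = np.exp(terms - shift[:, None]).sum(axis=1)
    with np.errstate(divide="ignore"):
        return np.log(s) + shift


def mixture_loglik(
    log_lik: np.ndarray, weights: np.ndarray, counts: np.ndarray
) -> float:
    """Total log-likelihood sum_i c_i log sum_j w_j L[i][j]."""
    total, bad = _mixture_loglik_njit(
        np.ascontiguousarray(log_lik),
        np.asarray(weights, dtype=np.float64),
        counts.astype(np.float64),
    )
    if bad >= 0:
        raise FloatingPointError(
            f"pattern {bad} has zero likelihood under every category"
        )
    return float(total)


def posterior_invariable(log_lik: np.ndarray, weights: np.ndarray) -> np.ndarray:
    site = _site_mixture_logs(log_lik, weights)
    if np.any(~np.isfinite(site)):
        raise FloatingPointError("pattern with zero total mixture likelihood")
    if weights[0] <= 0:
        return np.zeros(log_lik.shape[0])
    with np.errstate(invalid="ignore"):
        post = np.exp(np.log(weights[0]) + log_lik[:, 0] - site)
    return np.where(np.isfinite(log_lik[:, 0]), post, 0.0)


# -- compiled kernels (unscaled path; small trees cannot underflow) --------


@numba.njit(cache=True, fastmath=True)
def _down_njit(internal_post, child_ptr, child_idx, is_leaf, leaf_codes, pmats, down):
    # Leaf children contribute P[x, observed_code] directly (their
    # conditional is one-hot), or 1 for missing data (row-stochastic P).
    n_cat = down.shape[1]
    npat = down.shape[2]
    for ii in range(internal_post.size):
        v = internal_post[ii]
        lo = child_ptr[v]
        hi = child_ptr[v + 1]
        for k in range(n_cat):
            out = down[v, k]
            for ci in range(lo, hi):
                c = child_idx[ci]
                pm = pmats[c, k]
                first = ci == lo
                if is_leaf[c]:
                    codes = leaf_codes[c]
                    for pat in range(npat):
                        code = codes[pat]
                        if code < 4:
                            m0 = pm[0, code]
                            m1 = pm[1, code]
                            m2 = pm[2, code]
                            m3 = pm[3, code]
                        else:  # missing data: message is 1 for every state
                            m0 = 1.0
                            m1 = 1.0
                            m2 = 1.0
                            m3 = 1.0
                        if first:
                            out[pat, 0] = m0
                            out[pat, 1] = m1
                            out[pat, 2] = m2
                            out[pat, 3] = m3
                        else:
                            out[pat, 0] *= m0
                            out[pat, 1] *= m1
                            out[pat, 2] *= m2
                            out[pat, 3] *= m3
                else:
                    dc = down[c, k]
                    for pat in range(npat):
                        d0 = dc[pat, 0]
                        d1 = dc[pat, 1]
                        d2 = dc[pat, 2]
                        d3 = dc[pat, 3]
                        m0 = pm[0, 0] * d0 + pm[0, 1] * d1 + pm[0, 2] * d2 + pm[0, 3] * d3
                        m1 = pm[1, 0] * d0 + pm[1, 1] * d1 + pm[1, 2] * d2 + pm[1, 3] * d3
                        m2 = pm[2, 0] * d0 + pm[2, 1] * d1 + pm[2, 2] * d2 + pm[2, 3] * d3
                        m3 = pm[3, 0] * d0 + pm[3, 1] * d1 + pm[3, 2] * d2 + pm[3, 3] * d3
                        if first:
                            out[pat, 0] = m0
                            out[pat, 1] = m1
                            out[pat, 2] = m2
                            out[pat, 3] = m3
                        else:
                            out[pat, 0] *= m0
                            out[pat, 1] *= m1
                            out[pat, 2] *= m2
                            out[pat, 3] *= m3


@numba.njit(cache=True, fastmath=True)
def _stem_njit(
    pre_internal, root, child_ptr, child_idx, is_leaf, leaf_codes, pmats,
    down, stem, pi,
):
    n_cat = down.shape[1]
    npat = down.shape[2]
    for ii in range(pre_internal.size):
        u = pre_internal[ii]
        lo = child_ptr[u]
        hi = child_ptr[u + 1]
        for ci in range(lo, hi):
            v = child_idx[ci]
            for k in range(n_cat):
                sv = stem[v, k]
                # base: outside partial of u carried across u's own branch
                if u == root:
                    for pat in range(npat):
                        sv[pat, 0] = pi[0]
                        sv[pat, 1] = pi[1]
                        sv[pat, 2] = pi[2]
                        sv[pat, 3] = pi[3]
                else:
                    pm_u = pmats[u, k]
                    su = stem[u, k]
                    for pat in range(npat):
                        s0 = su[pat, 0]
                        s1 = su[pat, 1]
                        s2 = su[pat, 2]
                        s3 = su[pat, 3]
                        sv[pat, 0] = s0 * pm_u[0, 0] + s1 * pm_u[1, 0] + s2 * pm_u[2, 0] + s3 * pm_u[3, 0]
                        sv[pat, 1] = s0 * pm_u[0, 1] + s1 * pm_u[1, 1] + s2 * pm_u[2, 1] + s3 * pm_u[3, 1]
                        sv[pat, 2] = s0 * pm_u[0, 2] + s1 * pm_u[1, 2] + s2 * pm_u[2, 2] + s3 * pm_u[3, 2]
                        sv[pat, 3] = s0 * pm_u[0, 3] + s1 * pm_u[1, 3] + s2 * pm_u[2, 3] + s3 * pm_u[3, 3]
                # multiply in the sibling messages
                for cj in range(lo, hi):
                    if cj == ci:
                        continue
                    c = child_idx[cj]
                    pm = pmats[c, k]
                    if is_leaf[c]:
                        codes = leaf_codes[c]
                        for pat in range(npat):
                            code = codes[pat]
                            if code < 4:
                                sv[pat, 0] *= pm[0, code]
                                sv[pat, 1] *= pm[1, code]
                                sv[pat, 2] *= pm[2, code]
                                sv[pat, 3] *= pm[3, code]
                    else:
                        dc = down[c, k]
                        for pat in range(npat):
                            d0 = dc[pat, 0]
                            d1 = dc[pat, 1]
                            d2 = dc[pat, 2]
                            d3 = dc[pat, 3]
                            sv[pat, 0] *= pm[0, 0] * d0 + pm[0, 1] * d1 + pm[0, 2] * d2 + pm[0, 3] * d3
                            sv[pat, 1] *= pm[1, 0] * d0 + pm[1, 1] * d1 + pm[1, 2] * d2 + pm[1, 3] * d3
                            sv[pat, 2] *= pm[2, 0] * d0 + pm[2, 1] * d1 + pm[2, 2] * d2 + pm[2, 3] * d3
                            sv[pat, 3] *= pm[3, 0] * d0 + pm[3, 1] * d1 + pm[3, 2] * d2 + pm[3, 3] * d3


@numba.njit(cache=True, fastmath=True)
def _edge_ll_njit(sv, dv, codes, p, dp, d2p, rates, wc, w0lin, counts, order):
    # codes: per-pattern observed state for a leaf edge (4 = missing),
    # or an empty array for an internal edge (use the full dv vector).
    n_cat, npat = sv.shape[0], sv.shape[1]
    is_leaf_edge = codes.size > 0
    tot = np.empty(npat)
    dtot = np.zeros(npat)
    d2tot = np.zeros(npat)
    tot[:] = w0lin
    for k in range(n_cat):
        svk = sv[k]
        dvk = dv[k]
        pk = p[k]
        dpk = dp[k]
        d2pk = d2p[k]
        w = wc[k]
        r = rates[k]
        r2 = r * r
        if is_leaf_edge:
            for pat in range(npat):
                code = codes[pat]
                s0 = svk[pat, 0]
                s1 = svk[pat, 1]
                s2 = svk[pat, 2]
                s3 = svk[pat, 3]
                if code < 4:
                    a = s0 * pk[0, code] + s1 * pk[1, code] + s2 * pk[2, code] + s3 * pk[3, code]
                    tot[pat] += w * a
                    if order > 0:
                        b = s0 * dpk[0, code] + s1 * dpk[1, code] + s2 * dpk[2, code] + s3 * dpk[3, code]
                        c2 = s0 * d2pk[0, code] + s1 * d2pk[1, code] + s2 * d2pk[2, code] + s3 * d2pk[3, code]
                        dtot[pat] += w * b * r
                        d2tot[pat] += w * c2 * r2
                else:
                    # missing data: P row sums are 1, derivative rows sum to 0
                    tot[pat] += w * (s0 + s1 + s2 + s3)
        else:
            for pat in range(npat):
                d0 = dvk[pat, 0]
                d1 = dvk[pat, 1]
                d2_ = dvk[pat, 2]
                d3 = dvk[pat, 3]
                a = 0.0
                b = 0.0
                c2 = 0.0
                for x in range(4):
                    sx = svk[pat, x]
                    if sx != 0.0:
                        a += sx * (pk[x, 0] * d0 + pk[x, 1] * d1 + pk[x, 2] * d2_ + pk[x, 3] * d3)
                        if order > 0:
                            b += sx * (dpk[x, 0] * d0 + dpk[x, 1] * d1 + dpk[x, 2] * d2_ + dpk[x, 3] * d3)
                            c2 += sx * (d2pk[x, 0] * d0 + d2pk[x, 1] * d1 + d2pk[x, 2] * d2_ + d2pk[x, 3] * d3)
                tot[pat] += w * a
                if order > 0:
                    dtot[pat] += w * b * r
                    d2tot[pat] += w * c2 * r2
    ll = 0.0
    dll = 0.0
    d2ll = 0.0
    for pat in range(npat):
        cnt = counts[pat]
        ll += cnt * np.log(tot[pat])
        if order > 0:
            r1 = dtot[pat] / tot[pat]
            dll += cnt * r1
            d2ll += cnt * (d2tot[pat] / tot[pat] - r1 * r1)
    return ll, dll, d2ll


class PruningEngine:
    """Felsenstein pruning over compressed patterns, batched by category.

    The engine owns a private copy of the branch lengths (so callers can
    tweak single branches during optimization) and caches the per-branch
    transition matrices and the pattern log-likelihood matrix for the
    current (kappa, rates, lengths); caches are invalidated whenever a
    branch length or the model changes. Results are identical with the
    cache on or off.
    """

    def __init__(self, tree: PhyloTree, patterns: PatternTable, use_cache: bool = True):
        if set(tree.leaf_labels) != set(patterns.labels):
            raise ValueError(
                "tree taxa and alignment taxa differ: "
                f"{sorted(set(tree.leaf_labels) ^ set(patterns.labels))}"
            )
        self.tree = tree
        self.patterns = patterns
        self.use_cache = use_cache
        self.lengths = tree.lengths.copy()
        self.root = tree.root
        self.children = tree.children
        self.postorder = list(tree.postorder())
        self.preorder = list(reversed(self.postorder))
        self.scaled = tree.n_leaves > _NO_SCALING_MAX_LEAVES
        row_of = {lab: i for i, lab in enumerate(patterns.labels)}
        npat = patterns.n_patterns
        # per-leaf conditional likelihoods (npat, 4): one-hot or all-ones
        self.leaf_partial: dict[int, np.ndarray] = {}
        eye = np.vstack([np.eye(4), np.ones(4)])
        for v in tree.leaf_indices():
            self.leaf_partial[v] = eye[patterns.codes[row_of[tree.labels[v]]]]
        self.npat = npat
        # CSR children structure + internal-node orders for the kernels
        n_nodes = tree.n_nodes
        self._child_ptr = np.zeros(n_nodes + 1, dtype=np.int64)
        for v in range(n_nodes):
            self._child_ptr[v + 1] = self._child_ptr[v] + len(self.children[v])
        self._child_idx = np.array(
            [c for v in range(n_nodes) for c in self.children[v]], dtype=np.int64
        )
        self._internal_post = np.array(
            [v for v in self.postorder if self.children[v]], dtype=np.int64
        )
        self._internal_pre = self._internal_post[::-1].copy()
        self._is_leaf = np.array(
            [tree.is_leaf(v) for v in range(n_nodes)], dtype=np.bool_
        )
        self._leaf_codes = np.zeros((n_nodes, npat), dtype=np.int8)
        for v in tree.leaf_indices():
            self._leaf_codes[v] = patterns.codes[row_of[tree.labels[v]]]
        self._kappa: float | None = None
        self._rates: np.ndarray | None = None
        self._pmats: np.ndarray | None = None  # (n_nodes, ncat, 4, 4)
        self._down: np.ndarray | None = None
        self._dscale: np.ndarray | None = None
        self._stem: np.ndarray | None = None
        self._sscale: np.ndarray | None = None
        self._logs_cache: np.ndarray | None = None
        self._down_valid = False

    # -- parameter management --------------------------------------------

    def set_model(self, kappa: float, rates: np.ndarray) -> None:
        """Set kappa and the positive category rates (zero category excluded)."""
        rates = np.asarray(rates, dtype=np.float64)
        if (
            self.use_cache
            and self._pmats is not None
            and self._kappa == kappa
            and self._rates is not None
            and self._rates.shape == rates.shape
            and np.array_equal(self._rates, rates)
        ):
            return
        self._kappa = float(kappa)
        self._rates = rates
        ts = self.lengths.copy()
        ts[self.root] = 0.0
        self._pmats = k2p_transition_matrix(ts[:, None] * rates[None, :], kappa)
        self._logs_cache = None
        self._down_valid = False

    def set_branch(self, v: int, t: float) -> None:
        if t < 0:
            raise ValueError("branch length must be non-negative")
        self.lengths[v] = t
        if self._pmats is not None:
            self._pmats[v] = k2p_transition_matrix(t * self._rates, self._kappa)
        self._logs_cache = None
        self._down_valid = False

    def set_lengths(self, lengths: np.ndarray) -> None:
        self.lengths = np.asarray(lengths, dtype=np.float64).copy()
        if self._pmats is not None:
            ts = self.lengths.copy()
            ts[self.root] = 0.0
            self._pmats = k2p_transition_matrix(
                ts[:, None] * self._rates[None, :], self._kappa
            )
        self._logs_cache = None
        self._down_valid = False

    # -- passes -----------------------------------------------------------

    def _require_model(self) -> None:
        if self._pmats is None:
            raise RuntimeError("call set_model() before computing likelihoods")

    def _buffers(self) -> tuple[np.ndarray, np.ndarray]:
        ncat = len(self._rates)
        shape = (self.tree.n_nodes, ncat, self.npat, 4)
        if self._down is None or self._down.shape != shape:
            self._down = np.empty(shape)
            self._dscale = np.zeros(shape[:3])
            self._down_valid = False
            # leaf conditionals are constant: fill them once per buffer
            for v, part in self.leaf_partial.items():
                self._down[v] = part[None, :, :]
        return self._down, self._dscale

    def down_pass(self) -> tuple[np.ndarray, np.ndarray]:
        """Conditional likelihoods of each subtree, with log scalers.

        Returns ``down`` (n_nodes, ncat, npat, 4) and ``dscale``
        (n_nodes, ncat, npat); the scalers are identically zero when the
        scaling pass is skipped (small trees).
        """
        self._require_model()
        down, dscale = self._buffers()
        if self.use_cache and self._down_valid:
            return down, dscale
        self._down_valid = True
        if not self.scaled:
            _down_njit(
                self._internal_post, self._child_ptr, self._child_idx,
                self._is_leaf, self._leaf_codes, self._pmats, down,
            )
            return down, dscale
        dscale[:] = 0.0
        for v in self.postorder:
            kids = self.children[v]
            if not kids:
                down[v] = self.leaf_partial[v][None, :, :]
                continue
            acc = down[kids[0]] @ self._pmats[kids[0]]
            for c in kids[1:]:
                acc *= down[c] @ self._pmats[c]
            sc = dscale[kids[0]].copy()
            for c in kids[1:]:
                sc += dscale[c]
            s = acc.max(axis=-1)
            safe = np.where(s > 0, s, 1.0)
            down[v] = acc / safe[..., None]
            with np.errstate(divide="ignore"):
                dscale[v] = sc + np.where(s > 0, np.log(safe), -np.inf)
        return down, dscale

    def stem_pass(
        self, down: np.ndarray, dscale: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Outside partials for every branch.

        ``stem[v]`` is the likelihood of all data outside the subtree of
        ``v``, as a function of the state at v's parent, including the
        stationary frequencies but excluding the transition matrix of the
        branch to ``v`` itself. Together with ``down[v]`` this isolates
        one branch length: the site likelihood for category c is
        stem[v] . P(r_c t_v) . down[v] times exp(sscale+dscale).
        """
        self._require_model()
        if self._stem is None or self._stem.shape != down.shape:
            self._stem = np.empty_like(down)
            self._sscale = np.zeros(down.shape[:3])
        stem, sscale = self._stem, self._sscale
        if not self.scaled:
            _stem_njit(
                self._internal_pre, self.root, self._child_ptr,
                self._child_idx, self._is_leaf, self._leaf_codes,
                self._pmats, down, stem, STATIONARY_FREQS,
            )
            return stem, sscale
        sscale[:] = 0.0
        ncat = len(self._rates)
        pi = STATIONARY_FREQS
        for u in self.preorder:
            kids = self.children[u]
            if not kids:
                continue
            ms = {c: down[c] @ self._pmats[c] for c in kids}
            if u == self.root:
                base = np.broadcast_to(pi, (ncat, self.npat, 4))
                base_sc = None
            else:
                base = stem[u] @ self._pmats[u]
                base_sc = sscale[u]
            for v in kids:
                acc = base
                for s in kids:
                    if s != v:
                        acc = acc * ms[s]
                if self.scaled:
                    sc = np.zeros((ncat, self.npat)) if base_sc is None else base_sc.copy()
                    for s in kids:
                        if s != v:
                            sc += dscale[s]
                    mx = acc.max(axis=-1)
                    safe = np.where(mx > 0, mx, 1.0)
                    stem[v] = acc / safe[..., None]
                    with np.errstate(divide="ignore"):
                        sscale[v] = sc + np.where(mx > 0, np.log(safe), -np.inf)
                else:
                    stem[v] = acc
        return stem, sscale

    def variable_category_logs(self) -> np.ndarray:
        """log P(D_i | r_c) for the positive-rate categories, (npat, ncat)."""
        down, dscale = self.down_pass()
        lik = down[self.root] @ STATIONARY_FREQS  # (ncat, npat)
        with np.errstate(divide="ignore"):
            logs = np.log(lik)
        if self.scaled:
            logs = logs + dscale[self.root]
        return logs.T

    def pattern_log_likelihoods(self) -> np.ndarray:
        """Full (npat, k+1) log-likelihood matrix including category 0."""
        if self.use_cache and self._logs_cache is not None:
            return self._logs_cache
        inv_logs = self.patterns.invariable_log_likelihoods()
        if not self.scaled:
            down, _ = self.down_pass()
            logs = np.empty((self.npat, len(self._rates) + 1))
            _root_logs_njit(down[self.root], STATIONARY_FREQS, inv_logs, logs)
        else:
            logs = np.column_stack([inv_logs, self.variable_category_logs()])
        if self.use_cache:
            self._logs_cache = logs
        return logs

    def log_likelihood(self, weights: np.ndarray) -> float:
        """Mixture log-likelihood for the current branch lengths/model."""
        if self.use_cache and self._logs_cache is not None:
            return mixture_loglik(self._logs_cache, weights, self.patterns.counts)
        if not self.scaled:
            down, _ = self.down_pass()
            total, bad = _root_mix_ll_njit(
                down[self.root],
                STATIONARY_FREQS,
                self.patterns.invariable_likelihoods(),
                np.asarray(weights, dtype=np.float64),
                self.patterns.counts.astype(np.float64),
            )
            if bad >= 0:
                raise FloatingPointError(
                    f"pattern {bad} has zero likelihood under every category"
                )
            return float(total)
        return mixture_loglik(
            self.pattern_log_likelihoods(), weights, self.patterns.counts
        )

    # -- single-branch objective ------------------------------------------

    def full_passes(self):
        """Inside and outside partials for the current parameters."""
        down, dscale = self.down_pass()
        stem, sscale = self.stem_pass(down, dscale)
        return down, dscale, stem, sscale

    def branch_objective(self, v: int, weights: np.ndarray, passes=None):
        """Factory for the log-likelihood (and derivatives) in one branch.

        Returns ``f(t, order) -> (ll, dll, d2ll)``: the mixture
        log-likelihood as a function of the length of branch ``v`` with
        everything else fixed at the state captured in ``passes`` (or
        freshly recomputed when ``passes`` is None, in which case the
        objective is exact for the engine's current state).
        """
        self._require_model()
        if passes is None:
            passes = self.full_passes()
        down, dscale, stem, sscale = passes
        d_v = down[v]  # (ncat, npat, 4)
        s_v = stem[v]
        off = (sscale[v] + dscale[v]) if self.scaled else None
        inv_logs = self.patterns.invariable_log_likelihoods()
        counts = self.patterns.counts
        rates = self._rates
        kappa = self._kappa
        with np.errstate(divide="ignore"):
            logw = np.where(weights > 0, np.log(np.maximum(weights, 1e-300)), -np.inf)
        w0_lin = weights[0] * np.exp(inv_logs)  # safe: inv_logs in {log 1/4, 0, -inf}
        wc = weights[1:]
        counts_f = counts.astype(np.float64)
        edge_codes = (
            self._leaf_codes[v] if self._is_leaf[v] else np.empty(0, dtype=np.int8)
        )

        def objective(t: float, order: int = 0):
            p, dp, d2p = k2p_transition_derivatives(t * rates, kappa)
            if off is None:
                ll, dll, d2ll = _edge_ll_njit(
                    s_v, d_v, edge_codes, p, dp, d2p, rates, wc, w0_lin,
                    counts_f, order,
                )
                if order == 0:
                    return ll, None, None
                if order == 1:
                    return ll, dll, None
                return ll, dll, d2ll
            # scaled path (large trees): work in log space with the offsets
            a = np.einsum("cps,csy,cpy->cp", s_v, p, d_v, optimize=True)
            with np.errstate(divide="ignore"):
                log_terms = np.where(
                    a > 0, np.log(np.maximum(a, 1e-300)), -np.inf
                ) + off + logw[1:, None]
            col0 = inv_logs + logw[0]
            allcols = np.vstack([col0[None, :], log_terms])
            m = allcols.max(axis=0)
            m = np.where(np.isfinite(m), m, 0.0)
            lin_all = np.exp(allcols - m[None, :])
            tot = lin_all.sum(axis=0)
            ll = float(counts @ (np.log(tot) + m))
            lin = lin_all[1:]
            if order == 0:
                return ll, None, None
            da = np.einsum("cps,csy,cpy->cp", s_v, dp, d_v, optimize=True)
            da = da * rates[:, None]
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio_d = np.where(a > 0, da / np.maximum(a, 1e-300), 0.0)
            dl = (lin * ratio_d).sum(axis=0) / tot
            dll = float(counts @ dl)
            if order == 1:
                return ll, dll, None
            d2a = np.einsum("cps,csy,cpy->cp", s_v, d2p, d_v, optimize=True)
            d2a = d2a * (rates[:, None] ** 2)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio_d2 = np.where(a > 0, d2a / np.maximum(a, 1e-300), 0.0)
            d2l = (lin * ratio_d2).sum(axis=0) / tot
            d2ll = float(counts @ (d2l - dl**2))
            return ll, dll, d2ll

        return objective


# -- public operations ----------------------------------------------------


def pattern_category_likelihoods(
    tree: PhyloTree,
    model: K2PModel,
    mixture: RateMixture,
    patterns: PatternTable,
) -> PatternLikelihoods:
    """Likelihood of every pattern under every rate category.

    Category 0 (rate 0) is the invariable category: nonzero only for
    patterns whose non-missing states agree. Categories 1..k are pruning
    likelihoods with every branch scaled by the category rate.
    """
    eng = PruningEngine(tree, patterns)
    eng.set_model(model.kappa, mixture.rates[1:])
    return PatternLikelihoods(
        log_lik=eng.pattern_log_likelihoods(), counts=patterns.counts
    )


def log_likelihood(
    tree: PhyloTree,
    model: K2PModel,
    mixture: RateMixture,
    patterns: PatternTable,
) -> float:
    """Mixture log-likelihood sum_i c_i log sum_j w_j P(D_i | r_j)."""
    eng = PruningEngine(tree, patterns)
    eng.set_model(model.kappa, mixture.rates[1:])
    return eng.log_likelihood(mixture.weights)
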
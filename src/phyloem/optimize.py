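"""EM + multi-start heuristic for fitting the I + discrete-Gamma model.

Given a fixed tree topology, one fit start runs an outer loop of

  1. branch lengths, one safeguarded Newton-Raphson sweep per branch;
  2. the substitution parameter kappa, by safeguarded scalar search;
  3. the E-step: each site's posterior probability of being invariable;
  4. the M-step: p_inv <- count-weighted mean of those posteriors;
  5. the Gamma shape alpha, by Brent's method;

until the outer-iteration log-likelihood gain drops to epsilon. To escape
the well-known two-peak (alpha, p_inv) likelihood surface, the loop is
restarted from ten p_inv values evenly spaced between 0 and the observed
fraction of constant sites (alpha always restarts at 1.0) and the best
final log-likelihood wins.

Internally the optimizer keeps the Gamma category rates *unnormalized*
(mean 1 over the variable categories only), so the closed-form p_inv
update is an exact M-step and every step provably never decreases the
likelihood. Reported branch lengths are converted back to the overall
mean-rate-1 convention (multiplied by 1 - p_inv), which leaves the
likelihood untouched and makes tree lengths directly comparable to
simulation truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .likelihood import (
    PatternLikelihoods,
    PatternTable,
    PruningEngine,
    compress_patterns,
    posterior_invariable,
)
from .models import K2PModel, RateMixture, build_rate_mixture, discrete_gamma_rates
from .simulate import Alignment
from .trees import PhyloTree

__all__ = [
    "FitConfig",
    "FitResult",
    "em_step_pinv",
    "optimize_alpha",
    "optimize_branch_lengths",
    "optimize_substitution",
    "fit_ig",
    "loglik_at",
]

logger = logging.getLogger("phyloem")


@dataclass(frozen=True)
class FitConfig:
    """Settings of the estimation heuristic.

    epsilon is the outer-loop convergence threshold in log-likelihood
    units; n_starts the number of p_inv starting values; alpha always
    starts at alpha_init. Bounds are wide relative to the regimes of
    interest; estimates pinned at a bound are flagged in the result.
    """

    epsilon: float = 0.01
    n_starts: int = 10
    alpha_init: float = 1.0
    kappa_init: float = 4.0
    alpha_bounds: tuple[float, float] = (0.02, 100.0)
    kappa_bounds: tuple[float, float] = (0.05, 100.0)
    branch_bounds: tuple[float, float] = (1e-6, 100.0)
    n_categories: int = 4
    max_outer: int = 100
    branch_sweeps: int = 1
    optimize_kappa: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.n_starts < 1:
            raise ValueError("need at least one start")


@dataclass
class FitResult:
    """Estimates and diagnostics of one multi-start fit."""

    alpha: float
    p_inv: float
    kappa: float
    tree: PhyloTree
    log_likelihood: float
    traces: list[list[float]] = field(repr=False)
    start_pinv: list[float] = field(repr=False)
    chosen_start: int = 0
    boundary_flags: list[str] = field(default_factory=list)
    n_iterations: int = 0

    @property
    def tree_length(self) -> float:
        return self.tree.tree_length()

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "p_inv": self.p_inv,
            "kappa": self.kappa,
            "tree_length": self.tree_length,
            "log_likelihood": self.log_likelihood,
            "chosen_start": self.chosen_start,
            "start_pinv": list(self.start_pinv),
            "n_iterations": self.n_iterations,
            "boundary_flags": list(self.boundary_flags),
            "traces": [list(t) for t in self.traces],
        }


def _weights(p_inv: float, k: int) -> np.ndarray:
    return np.concatenate([[p_inv], np.full(k, (1.0 - p_inv) / k)])


# -- scalar search helpers -------------------------------------------------


def _bounded_max(fun, bounds: tuple[float, float], xatol: float) -> tuple[float, float]:
    """Maximize a scalar function on [lo, hi]; returns (x, f(x))."""
    res = minimize_scalar(
        lambda x: -fun(x),
        bounds=bounds,
        method="bounded",
        options={"xatol": xatol},
    )
    return float(res.x), float(-res.fun)


def _windowed_log_max(
    fun_logx,
    x0: float,
    bounds: tuple[float, float],
    xatol: float = 2e-3,
    window: float | None = None,
) -> tuple[float, float]:
    """Maximize fun(log x) over log-space, optionally in a warm window.

    The window around log(x0) is expanded (up to the full bounds)
    whenever the maximizer lands on its edge, so warm starting never
    traps the search at a spurious interior boundary.
    """
    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    if window is None:
        return _bounded_max(fun_logx, (lo, hi), xatol)
    c = float(np.clip(np.log(x0), lo, hi))
    w = window
    while True:
        wlo, whi = max(lo, c - w), min(hi, c + w)
        x, best = _bounded_max(fun_logx, (wlo, whi), xatol)
        at_lo = x - wlo < 3 * xatol and wlo > lo
        at_hi = whi - x < 3 * xatol and whi < hi
        if not (at_lo or at_hi):
            return x, best
        w *= 3.0
        if w > (hi - lo):
            return _bounded_max(fun_logx, (lo, hi), xatol)


def _parabolic_log_max(
    fun_logx,
    x0: float,
    bounds: tuple[float, float],
    f0: float | None = None,
    h: float = 0.12,
    rounds: int = 2,
) -> tuple[float, float]:
    """Cheap warm-started maximizer: successive parabolic interpolation
    through symmetric three-point stencils in log space.

    Used inside the outer loop where the optimum moves only slightly
    between iterations; never returns a point scoring below the entry
    value. Falls back to shifting the stencil when the maximum sits on
    its edge (and so can still travel arbitrarily far along the axis).
    """
    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    c = float(np.clip(np.log(x0), lo, hi))
    fc = fun_logx(c) if f0 is None else f0
    best_x, best_f = c, fc
    for _ in range(rounds):
        a = max(lo, c - h)
        b = min(hi, c + h)
        fa = fun_logx(a) if a < c else None
        fb = fun_logx(b) if b > c else None
        for x, f in ((a, fa), (b, fb)):
            if f is not None and f > best_f:
                best_x, best_f = x, f
        if (fa is not None and fa >= fc) or (fb is not None and fb >= fc):
            # maximum beyond the stencil edge: recentre, keep the step
            c, fc = best_x, best_f
            continue
        if fa is None or fb is None:
            # pinned against a bound with no improvement on the open side
            break
        denom = fa - 2.0 * fc + fb
        if denom >= 0 or not np.isfinite(denom):
            break
        step = 0.5 * h * (fa - fb) / denom
        v = float(np.clip(c + step, lo, hi))
        if not np.isfinite(v) or abs(v - c) < 1e-6:
            break
        fv = fun_logx(v)
        if fv > best_f:
            best_x, best_f = v, fv
        c, fc = best_x, best_f
        h *= 0.5
    return best_x, best_f


# -- public single-step operations ----------------------------------------


def em_step_pinv(
    patterns: PatternTable,
    likelihoods: PatternLikelihoods,
    mixture: RateMixture,
) -> float:
    """One EM update of p_inv.

    E-step: posterior P(r_0|D_i) = w_0 L[i][0] / sum_j w_j L[i][j] under
    the current mixture; M-step: the new p_inv is the count-weighted mean
    of the posteriors over all n sites. The result can never exceed the
    constant-site fraction (variable patterns have zero posterior).
    """
    post = posterior_invariable(likelihoods.log_lik, mixture.weights)
    return float(patterns.counts @ post / patterns.n)


def optimize_alpha(
    tree: PhyloTree,
    model: K2PModel,
    patterns: PatternTable,
    p_inv: float,
    bounds: tuple[float, float] = (0.02, 100.0),
    k: int = 4,
) -> float:
    """Maximize the log-likelihood over the Gamma shape, p_inv held fixed.

    Derivative-free scalar search (Brent-style bounded minimization) in
    log(alpha). A boundary return is allowed; callers can detect it by
    comparing against ``bounds``.
    """
    eng = PruningEngine(tree, patterns)
    w = _weights(p_inv, k)

    def ll_of(log_a: float) -> float:
        mix = build_rate_mixture(float(np.exp(log_a)), p_inv, k)
        eng.set_model(model.kappa, mix.rates[1:])
        return eng.log_likelihood(w)

    x, _ = _windowed_log_max(ll_of, 1.0, bounds, xatol=1e-4)
    return float(np.exp(x))


def optimize_substitution(
    tree: PhyloTree,
    model: K2PModel,
    mixture: RateMixture,
    patterns: PatternTable,
    bounds: tuple[float, float] = (0.05, 100.0),
) -> float:
    """Maximize the log-likelihood over kappa (other parameters fixed).

    For K2P this is a one-dimensional problem; a safeguarded scalar
    search in log(kappa) replaces the general quasi-Newton step while
    honouring the same never-decrease contract.
    """
    eng = PruningEngine(tree, patterns)

    def ll_of(log_k: float) -> float:
        eng.set_model(float(np.exp(log_k)), mixture.rates[1:])
        return eng.log_likelihood(mixture.weights)

    entry_ll = ll_of(float(np.log(model.kappa)))
    x, best = _windowed_log_max(ll_of, model.kappa, bounds, xatol=1e-4)
    if best < entry_ll:
        return float(model.kappa)
    return float(np.exp(x))


def optimize_branch_lengths(
    tree: PhyloTree,
    model: K2PModel,
    mixture: RateMixture,
    patterns: PatternTable,
    bounds: tuple[float, float] = (1e-6, 100.0),
    sweeps: int = 1,
) -> PhyloTree:
    """Newton-Raphson branch-length sweep(s); returns an updated tree.

    Each branch is optimized against exact inside/outside partials; a
    Newton step that leaves the bounds or lowers the likelihood falls
    back to safeguarded bounded scalar search, and a whole sweep that
    fails to improve is redone branch-by-branch with fresh partials, so
    the total log-likelihood never decreases.
    """
    eng = PruningEngine(tree, patterns)
    eng.set_model(model.kappa, mixture.rates[1:])
    for _ in range(sweeps):
        _branch_sweep(eng, mixture.weights, bounds)
    out = tree.copy()
    out.lengths = eng.lengths.copy()
    out.lengths[out.root] = 0.0
    return out


def _optimize_one_branch(
    objective, t0: float, bounds: tuple[float, float]
) -> tuple[float, float]:
    """Safeguarded Newton-Raphson on one branch; returns (t, ll)."""
    lo, hi = bounds
    t = float(np.clip(t0, lo, hi))
    ll0, d1, d2 = objective(t, order=2)
    best_t, best_ll = t, ll0
    newton_ok = True
    for _ in range(10):
        if not np.isfinite(d1) or not np.isfinite(d2) or d2 >= 0:
            newton_ok = False
            break
        # expected gain of the Newton step; stop when negligible
        if d1 * d1 / (2.0 * abs(d2)) < 1e-5:
            break
        step = -d1 / d2
        t_new = float(np.clip(t + step, lo, hi))
        if abs(t_new - t) < 1e-8 * (1.0 + t):
            break
        ll_new, d1n, d2n = objective(t_new, order=2)
        if not np.isfinite(ll_new) or ll_new < best_ll - 1e-9:
            newton_ok = False
            break
        t, d1, d2 = t_new, d1n, d2n
        if ll_new > best_ll:
            best_t, best_ll = t_new, ll_new
        if abs(d1) < 1e-7:
            break
    if not newton_ok:
        # golden/Brent bounded fallback in log-length (the likelihood
        # plateaus at saturation, so linear-scale probes miss the basin)
        x, ll = _bounded_max(
            lambda u: objective(float(np.exp(u)), order=0)[0],
            (np.log(lo), np.log(hi)),
            xatol=1e-6,
        )
        if ll > best_ll:
            best_t, best_ll = float(np.exp(x)), ll
    return best_t, best_ll


def _branch_sweep(
    eng: PruningEngine, weights: np.ndarray, bounds: tuple[float, float]
) -> float:
    """One sweep over all branches; never decreases the log-likelihood.

    Fast path: optimize every branch against inside/outside partials
    computed once for the whole sweep (a Jacobi-style update). If the
    joint update fails to improve the total log-likelihood, the sweep is
    redone branch-by-branch with exact freshly recomputed partials
    (Gauss-Seidel), and kept only if it improves.
    """
    ll0 = eng.log_likelihood(weights)
    old = eng.lengths.copy()
    passes = eng.full_passes()
    new = eng.lengths.copy()
    for v in eng.postorder:
        if v == eng.root:
            continue
        obj = eng.branch_objective(v, weights, passes=passes)
        new[v], _ = _optimize_one_branch(obj, float(eng.lengths[v]), bounds)
    eng.set_lengths(new)
    ll1 = eng.log_likelihood(weights)
    if ll1 >= ll0 - 1e-9:
        return max(ll0, ll1)
    # fallback: exact per-branch recomputation
    eng.set_lengths(old)
    for v in eng.postorder:
        if v == eng.root:
            continue
        obj = eng.branch_objective(v, weights)
        t, _ = _optimize_one_branch(obj, float(eng.lengths[v]), bounds)
        eng.set_branch(v, t)
    ll2 = eng.log_likelihood(weights)
    if ll2 < ll0 - 1e-9:
        eng.set_lengths(old)
        return ll0
    return ll2


def loglik_at(
    tree: PhyloTree,
    model: K2PModel,
    alpha: float,
    p_inv: float,
    patterns: PatternTable,
    k: int = 4,
) -> float:
    """Plain log-likelihood evaluation at a full parameter specification.

    No optimization: used for truth-versus-estimate comparisons and for
    likelihood-surface scans. Branch lengths are taken from ``tree`` in
    the overall mean-rate-1 convention.
    """
    eng = PruningEngine(tree, patterns)
    mix = build_rate_mixture(alpha, p_inv, k)
    eng.set_model(model.kappa, mix.rates[1:])
    return eng.log_likelihood(mix.weights)


# -- the full heuristic ----------------------------------------------------


def _single_start(
    eng: PruningEngine,
    patterns: PatternTable,
    config: FitConfig,
    p0: float,
    init_lengths: np.ndarray,
) -> dict:
    """One run of the outer loop from (p_inv=p0, alpha=alpha_init)."""
    k = config.n_categories
    alpha = config.alpha_init
    kappa = config.kappa_init
    p = min(p0, 1.0 - 1e-9)
    eng.set_lengths(init_lengths)
    eng.set_model(kappa, discrete_gamma_rates(alpha, k))
    w = _weights(p, k)
    ll = eng.log_likelihood(w)
    trace = [ll]
    flags: set[str] = set()
    n_iter = 0
    for n_iter in range(1, config.max_outer + 1):
        cold = n_iter == 1
        # Step 2: branch lengths (internal scale)
        for _ in range(config.branch_sweeps):
            _branch_sweep(eng, w, config.branch_bounds)
        # Step 3: substitution parameter
        if config.optimize_kappa:

            def ll_of_kappa(log_k: float) -> float:
                eng.set_model(float(np.exp(log_k)), discrete_gamma_rates(alpha, k))
                return eng.log_likelihood(w)

            entry = ll_of_kappa(float(np.log(kappa)))
            if cold:
                x, best = _windowed_log_max(
                    ll_of_kappa, kappa, config.kappa_bounds, window=1.0
                )
            else:
                x, best = _parabolic_log_max(
                    ll_of_kappa, kappa, config.kappa_bounds, f0=entry,
                    rounds=2 if n_iter <= 3 else 1,
                )
            if best >= entry:
                kappa = float(np.exp(x))
            eng.set_model(kappa, discrete_gamma_rates(alpha, k))
        # Steps 4-5: EM update of p_inv (exact M-step on the weights)
        log_lik = eng.pattern_log_likelihoods()
        post = posterior_invariable(log_lik, w)
        p = float(patterns.counts @ post / patterns.n)
        w = _weights(p, k)
        # Step 6: Gamma shape

        def ll_of_alpha(log_a: float) -> float:
            eng.set_model(kappa, discrete_gamma_rates(float(np.exp(log_a)), k))
            return eng.log_likelihood(w)

        entry = ll_of_alpha(float(np.log(alpha)))
        if cold:
            x, best = _windowed_log_max(
                ll_of_alpha, alpha, config.alpha_bounds, window=1.5
            )
        else:
            x, best = _parabolic_log_max(
                ll_of_alpha, alpha, config.alpha_bounds, f0=entry,
                rounds=2 if n_iter <= 3 else 1,
            )
        if best >= entry:
            alpha = float(np.exp(x))
            ll_new = best
        else:
            ll_new = entry
        eng.set_model(kappa, discrete_gamma_rates(alpha, k))
        trace.append(ll_new)
        # Step 7: convergence on the outer-iteration improvement
        if ll_new - ll <= config.epsilon:
            ll = max(ll, ll_new)
            break
        ll = ll_new
    else:
        logger.warning("outer loop hit the %d-iteration cap", config.max_outer)
        flags.add("max_iterations")
    lo_a, hi_a = config.alpha_bounds
    if alpha <= lo_a * 1.001 or alpha >= hi_a * 0.999:
        flags.add("alpha_at_bound")
    lo_k, hi_k = config.kappa_bounds
    if config.optimize_kappa and (kappa <= lo_k * 1.001 or kappa >= hi_k * 0.999):
        flags.add("kappa_at_bound")
    if np.any(
        eng.lengths[np.arange(eng.tree.n_nodes) != eng.root]
        <= config.branch_bounds[0] * 1.001
    ):
        flags.add("branch_at_lower_bound")
    return {
        "alpha": alpha,
        "p_inv": p,
        "kappa": kappa,
        "lengths": eng.lengths.copy(),
        "ll": max(ll, trace[-1]),
        "trace": trace,
        "flags": flags,
        "n_iter": n_iter,
    }


def fit_ig(
    tree_topology: PhyloTree,
    alignment: Alignment | PatternTable,
    model_family: str = "K2P",
    config: FitConfig | None = None,
) -> FitResult:
    """Fit I + discrete-Gamma(k) by the multi-start EM heuristic.

    ``tree_topology`` supplies the topology and the starting branch
    lengths (branches that are zero or missing start at 0.1). The
    alignment taxa must match the topology's leaves. Returns the best of
    the multi-start runs; ties within 1e-6 log-likelihood units go to the
    smaller p_inv estimate for determinism.
    """
    if model_family.upper() != "K2P":
        raise ValueError(f"unsupported model family: {model_family!r}")
    if config is None:
        config = FitConfig()
    patterns = (
        alignment
        if isinstance(alignment, PatternTable)
        else compress_patterns(alignment)
    )
    if set(tree_topology.leaf_labels) != set(patterns.labels):
        raise ValueError("alignment taxa do not match the tree topology leaves")
    eng = PruningEngine(tree_topology, patterns)
    init_lengths = tree_topology.lengths.copy()
    mask = np.arange(tree_topology.n_nodes) != tree_topology.root
    init_lengths[mask & (init_lengths <= 0)] = 0.1

    const_frac = patterns.constant_site_fraction()
    starts = np.linspace(0.0, const_frac, config.n_starts)
    # collapse exactly duplicated starts (e.g. no constant site at all)
    starts = sorted(set(float(s) for s in starts))
    runs = [
        _single_start(eng, patterns, config, p0, init_lengths) for p0 in starts
    ]
    best = None
    best_i = -1
    for i, run in enumerate(runs):
        if best is None:
            best, best_i = run, i
            continue
        if run["ll"] > best["ll"] + 1e-6:
            best, best_i = run, i
        elif abs(run["ll"] - best["ll"]) <= 1e-6 and run["p_inv"] < best["p_inv"]:
            best, best_i = run, i

    # convert internal branch lengths to the overall mean-rate-1 scale
    fitted = tree_topology.copy()
    fitted.lengths = best["lengths"] * (1.0 - best["p_inv"])
    fitted.lengths[fitted.root] = 0.0
    return FitResult(
        alpha=best["alpha"],
        p_inv=best["p_inv"],
        kappa=best["kappa"],
        tree=fitted,
        log_likelihood=best["ll"],
        traces=[r["trace"] for r in runs],
        start_pinv=list(starts),
        chosen_start=best_i,
        boundary_flags=sorted(best["flags"]),
        n_iterations=best["n_iter"],
    )
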
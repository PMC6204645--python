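# Methods

## Model

Sites evolve independently on a fixed unrooted topology under the Kimura
two-parameter (K2P) substitution model: uniform base frequencies,
transition rate κ·β and transversion rate β per target, scaled so the
expected substitution rate at stationarity is one (β = 1/(κ+2)). Branch
lengths are therefore expected substitutions per site. The
transition-probability matrix and its first two time-derivatives are
closed-form sums of two exponentials; κ = 1 reduces to Jukes–Cantor.

"Transition/transversion ratio 2.0" is interpreted as the
*expected-counts* ratio R (the Seq-Gen convention), which under uniform
frequencies equals κ/2; hence the default κ = 4. Both parameterizations
are exposed (`--tstv-kind {counts,rate}`), since the two conventions are
a recurring source of silent disagreement between programs.

Among-site rate variation follows the I + discrete-Γ mixture with k+1
categories: rate r₀ = 0 with weight w₀ = p_inv, and k = 4 Gamma
categories with weight (1−p_inv)/k each. The Γ(α, mean 1) distribution
is discretized into equal-probability categories represented by their
conditional means, computed from the regularized incomplete gamma
function (medians available as an option). The mixture is normalized so
the overall mean rate — **including** the invariable category — is one:
the variable-category rates are the mean-one Γ rates divided by
(1−p_inv). This keeps estimated tree lengths directly comparable to the
generating tree lengths, and is exactly why a wrong p̂_inv drags the
tree-length estimate with it.

## Study trees

The simulation trees are balanced: a central degree-3 node whose three
subtrees take the taxa split as evenly as possible (6 → 2/2/2, the
three-cherry shape; 24 → 8/8/8; 96 → 32/32/32), each subtree a balanced
rooted binary tree, with 2n−3 branches of 0.1 substitutions/site. On
the 6-taxon tree one internal branch is lengthened to 0.2 so the tree
has three distinct interspecies distances (an identifiability
requirement for I + continuous Γ). Which internal branch carries the 0.2
is arbitrary; the first in preorder (adjacent to the first cherry) is
used and configurable.

## Simulator

Alignments are generated Seq-Gen-style: per site, a category is drawn
from the mixture weights; a root state is drawn from the uniform
stationary distribution; states are propagated to the leaves by exact
sampling from the per-branch transition matrices in a fixed pre-order.
One integer seed drives a single NumPy generator, so alignments are
byte-reproducible. Category-0 sites are constant by construction. The
true per-site categories are retained on the alignment (and exported as
a sidecar CSV by the CLI) for diagnostics only — estimation never sees
them. The simulator emits pure A/C/G/T; the readers map anything else
(gaps, N, U, ambiguity codes) to "missing", which contributes partial
likelihood 1 at that leaf.

What the generator deliberately does not emulate: indels and alignment
error, compositional heterogeneity, covarion-style rate switching, and
non-independence between sites. Passing tests therefore demonstrate
correct estimation *under the model*, not robustness to real-data
violations of it.

## Likelihood engine

Columns are deduplicated into site patterns with multiplicities
(first-occurrence order); for six taxa an alignment of any length
collapses to ≤ 4⁶ patterns, which is what makes the 100,000-bp study
cells tractable. Felsenstein pruning runs batched over the Gamma
categories in numba-compiled kernels; leaf children enter as direct
transition-matrix lookups (their conditionals are one-hot). The
invariable category needs no pruning: L(Dᵢ|r₀) is 1/4 for a pattern
whose non-missing states agree, 1 for an all-missing pattern, 0
otherwise.

Underflow: for trees of ≤ 32 leaves the smallest attainable partial
(bounded below by the product of minimum transition probabilities over
at most 2n−3 edges at the rates of interest) is far above the double
floor, so no scaling is applied; larger trees use per-pattern,
per-category log-scaling at every internal node. The two paths agree to
rounding; a 96-taxon × rate-10 evaluation is finite by test.

The per-branch objective isolates one branch between "inside" (subtree)
and "outside" (rest of tree) partials, giving the exact log-likelihood
and its first two derivatives in that branch length from the closed-form
P, P′, P″.

Kernels are compiled with fastmath except for the one routine that must
honour −∞ log-likelihood entries exactly. Results with caching disabled
are identical by test.

## Optimizer

Each start runs the outer loop: branch lengths → κ → E-step → p_inv
update → α, stopping when the outer-iteration gain ≤ ε = 0.01
log-likelihood units (ε is configurable; 0.01 is small against the
≈ 27-unit peak separation seen on bimodal surfaces), with a hard cap of
100 outer iterations (flagged when hit; in practice only starts
crawling down the ridge from high p_inv initials hit it, and those never
win the multi-start comparison).

**Internal parameterization.** The closed-form p_inv update is an exact
EM M-step only if the category rates do not move with p_inv. The
optimizer therefore works internally with *unnormalized* Γ rates (mean
one over the variable categories) and branch lengths on the matching
scale; every step — Newton sweep, κ and α searches, EM update — is then
provably non-decreasing. On report, branch lengths are multiplied by
(1−p̂_inv), which restores the overall mean-rate-one convention without
changing the likelihood (the products b·r are invariant). Public
single-step operations (`optimize_alpha`, `optimize_branch_lengths`,
`loglik_at`, …) speak the normalized convention throughout.

**Branch lengths.** One sweep per outer iteration (configurable). The
fast path optimizes all branches against inside/outside partials
computed once per sweep (a Jacobi-style update) and verifies the joint
result; if the total log-likelihood did not improve, the sweep is redone
branch-by-branch with freshly recomputed partials, and kept only if it
improves — the non-decrease contract is unconditional. Each branch uses
safeguarded Newton–Raphson (analytic first and second derivatives,
stopping when the predicted gain < 10⁻⁵) with a log-scale bounded Brent
fallback; the log scale matters because the likelihood plateaus at
saturating lengths and linear-scale golden-section probes would miss the
basin. Bounds 10⁻⁶–10².

**κ and α.** One-dimensional safeguarded searches in log-parameter
space: a windowed bounded (Brent-style) search on the first outer
iteration, then cheap three-point parabolic refinement warm-started at
the incumbent (the optimum moves little between outer iterations; the
stencil recentres and so can still travel). A candidate scoring below
the entry point is rejected, preserving monotonicity. Bounds: α ∈
[0.02, 100], κ ∈ [0.05, 100]; results pinned at a bound are flagged.
For K2P the substitution step is genuinely one-dimensional, so the
scalar search stands in for the general quasi-Newton step under the same
non-decrease contract.

**Multi-start.** p_inv starting values: an inclusive evenly spaced grid
of n_starts = 10 points from 0 to the observed constant-site fraction
(duplicates collapsed, e.g. when there are no constant sites); α starts
at 1.0 and κ at its configured value each time. The best final
log-likelihood wins; ties within 10⁻⁶ go to the smaller p̂_inv for
determinism.

## Experiments

`run_grid` reruns the study design: for each (tree size, α, p_inv) cell
it simulates replicates, fits on the true topology, and records
estimates, the fitted log-likelihood, and the log-likelihood at the true
generating specification (true branch lengths, κ, α, p_inv). Replicate
seeds derive deterministically from (base seed, cell, replicate), so any
cell reruns in isolation. Cell means are classified against truth:
accurate < 10 % deviation, moderately inaccurate 10–25 %, inaccurate
> 25 %, with absolute bands when the true p_inv is 0 (≤ 0.01 accurate,
≤ 0.05 moderate). Deviations use the mean of estimates, not the mean of
deviations. A truth-beats-fit "win" requires the truth's log-likelihood
to exceed the fit's by more than 10⁻⁴, so floating-point ties never
count.

`surface_scan` evaluates the (α, p_inv) log-likelihood surface of one
alignment on a grid, either at fixed branch lengths or re-optimizing
them per grid point, and reports all grid-local maxima with their
ΔlnL — the two-peak structure of hard replicates is directly visible
there.

## Problem sizes in the bundled checks

The full study (90 cells × 100 replicates × 100 kb) is a cluster-scale
computation. The bundled checks use these profiles, chosen so the whole
default test session completes on one CPU in well under half an hour:

* the flagship hard cell (6 taxa, α = 0.5, p_inv = 0) at full alignment
  length, 100 replicates in `scripts/acceptance.py` and 30 in the test
  suite;
* the accuracy grid over all 30 (α, p_inv) cells for the 6-taxon tree —
  the hardest of the three tree sizes — at the full 100,000-site
  alignment length with 4 replicates per cell, shared between the
  classification check and the 6-taxon truth-beats-fit count. The
  budget goes into sites rather than replicates deliberately: the 10 %
  accuracy bands are an asymptotic property, and at short alignments
  the ML estimates scatter along the (α, p_inv) ridge far beyond 10 %
  even though every fit reaches the global optimum (the truth's
  log-likelihood essentially never beats the fit's at any length);
* a 24-taxon truth-beats-fit subset (α = 0.5 row, 2 × 4 replicates,
  2,000 sites);
* parameter recovery at (α = 1.0, p_inv = 0.5), 20 replicates × 100 kb.

## Known limitations

* DNA/K2P only: no GTR, no protein models, hence the substitution step
  never exercises a true multiparameter quasi-Newton.
* The topology is taken as given; there is no tree search, and branch
  lengths inherit the input tree's values as starting points.
* EM convergence along the (α, p_inv) ridge is geometric with ratio
  close to one in near-unidentifiable regimes; the iteration cap (with
  flag) bounds the cost, and such starts lose the multi-start
  comparison, but their reported traces end unconverged.
* No standard errors or intervals on the estimates.
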
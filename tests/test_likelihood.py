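import numpy as np
import pytest

import phyloem as pe
from phyloem.likelihood import PruningEngine, mixture_loglik
from conftest import brute_force_loglik


class TestPatternCompression:
    def test_identical_columns_collapse(self):
        aln = pe.Alignment.from_sequences(["A", "B"], ["AAAA", "CCCC"])
        pat = pe.compress_patterns(aln)
        assert pat.n_patterns == 1
        assert pat.counts.tolist() == [4]

    def test_two_taxon_example(self):
        aln = pe.Alignment.from_sequences(["x", "y"], ["AC", "AG"])
        pat = pe.compress_patterns(aln)
        assert pat.n_patterns == 2
        assert pat.counts.tolist() == [1, 1]

    def test_counts_conserved(self, small_alignment):
        pat = pe.compress_patterns(small_alignment)
        assert pat.n == small_alignment.n_sites
        assert pat.n_patterns <= small_alignment.n_sites

    def test_constant_fraction_counts_missing_as_agreeing(self):
        aln = pe.Alignment.from_sequences(["a", "b", "c"], ["AAC", "ANC", "A-G"])
        pat = pe.compress_patterns(aln)
        # columns: (A,A,A) constant; (A,N,-) constant; (C,C,G) variable
        assert pat.constant_site_fraction() == pytest.approx(2 / 3)


class TestCategoryLikelihoods:
    def test_two_taxon_closed_form(self, model):
        tree = pe.parse_newick("(A:0.07,B:0.05);")
        mix = pe.build_rate_mixture(0.5, 0.2, 4)
        aln = pe.Alignment.from_sequences(["A", "B"], ["AA", "AC"])
        pat = pe.compress_patterns(aln)
        pl = pe.pattern_category_likelihoods(tree, model, mix, pat)
        lik = pl.likelihoods
        for j, r in enumerate(mix.rates[1:], start=1):
            p = pe.k2p_transition_matrix(0.12 * r, model.kappa)
            assert lik[0, j] == pytest.approx(0.25 * p[0, 0], rel=1e-10)
            assert lik[1, j] == pytest.approx(0.25 * p[0, 1], rel=1e-10)
        # invariable category: 1/4 for the constant pattern, 0 otherwise
        assert lik[0, 0] == pytest.approx(0.25)
        assert lik[1, 0] == 0.0

    @pytest.mark.parametrize("n_taxa,seed", [(4, 0), (4, 1), (5, 2), (5, 3)])
    def test_pruning_equals_enumeration(self, model, n_taxa, seed):
        # independent oracle: sum over all internal-state assignments
        rng = np.random.default_rng(seed)
        tree = pe.make_balanced_tree(n_taxa, 0.1)
        mask = np.arange(tree.n_nodes) != tree.root
        tree.lengths[mask] = rng.uniform(0.02, 1.5, mask.sum())
        mix = pe.build_rate_mixture(rng.uniform(0.2, 2.0), rng.uniform(0, 0.5), 4)
        aln = pe.simulate_alignment(tree, model, mix, 60, seed=seed + 100)
        pat = pe.compress_patterns(aln)
        fast = pe.log_likelihood(tree, model, mix, pat)
        slow = brute_force_loglik(tree, model, mix, pat)
        assert fast == pytest.approx(slow, rel=1e-10)

    def test_enumeration_with_missing_data(self, model):
        tree = pe.make_balanced_tree(4, 0.15)
        mix = pe.build_rate_mixture(0.8, 0.3, 4)
        aln = pe.Alignment.from_sequences(
            ["T1", "T2", "T3", "T4"], ["ACNG", "AC-G", "ATAG", "ACAN"]
        )
        pat = pe.compress_patterns(aln)
        fast = pe.log_likelihood(tree, model, mix, pat)
        slow = brute_force_loglik(tree, model, mix, pat)
        assert fast == pytest.approx(slow, rel=1e-10)


class TestLogLikelihood:
    def test_rerooting_invariance(self, paper6, model, small_patterns):
        mix = pe.build_rate_mixture(0.5, 0.2, 4)
        ref = pe.log_likelihood(paper6, model, mix, small_patterns)
        for v in paper6.internal_branch_indices():
            rr = paper6.rerooted(v)
            assert pe.log_likelihood(rr, model, mix, small_patterns) == pytest.approx(
                ref, abs=1e-6
            )

    def test_compression_is_a_refactor(self, paper6, model, small_alignment):
        # the uncompressed column-by-column table gives the same value
        mix = pe.build_rate_mixture(0.5, 0.2, 4)
        compressed = pe.compress_patterns(small_alignment)
        raw = pe.PatternTable(
            labels=list(small_alignment.labels),
            codes=small_alignment.codes.copy(),
            counts=np.ones(small_alignment.n_sites, dtype=np.int64),
        )
        a = pe.log_likelihood(paper6, model, mix, compressed)
        b = pe.log_likelihood(paper6, model, mix, raw)
        assert a == pytest.approx(b, abs=1e-7)

    def test_rate_time_scaling_consistency(self, paper6, model, small_patterns):
        # multiplying branch lengths by c and dividing rates by c is a no-op
        mix = pe.build_rate_mixture(0.5, 0.2, 4)
        c = 3.7
        eng1 = PruningEngine(paper6, small_patterns)
        eng1.set_model(model.kappa, mix.rates[1:])
        scaled = paper6.copy()
        scaled.lengths = scaled.lengths * c
        eng2 = PruningEngine(scaled, small_patterns)
        eng2.set_model(model.kappa, mix.rates[1:] / c)
        assert eng1.log_likelihood(mix.weights) == pytest.approx(
            eng2.log_likelihood(mix.weights), abs=1e-7
        )

    def test_mixture_between_category_extremes(self, paper6, model, small_patterns):
        # per site, the mixture likelihood is a convex combination of the
        # category likelihoods, so the summed log-likelihood is bounded
        # by summing the per-site extremes
        mix = pe.build_rate_mixture(0.5, 0.2, 4)
        pl = pe.pattern_category_likelihoods(paper6, model, mix, small_patterns)
        counts = small_patterns.counts
        lo = float(counts @ pl.log_lik.min(axis=1))
        hi = float(counts @ pl.log_lik.max(axis=1))
        total = pe.log_likelihood(paper6, model, mix, small_patterns)
        assert lo - 1e-9 <= total <= hi + 1e-9

    def test_constant_alignment_limit(self, model):
        # nearly-invariable data with tiny branches: LL ~ n log(1/4)
        tree = pe.make_balanced_tree(4, 1e-7)
        aln = pe.Alignment.from_sequences(
            ["T1", "T2", "T3", "T4"], ["A" * 50] * 4
        )
        pat = pe.compress_patterns(aln)
        mix = pe.build_rate_mixture(1.0, 0.99, 4)
        ll = pe.log_likelihood(tree, model, mix, pat)
        assert ll == pytest.approx(50 * np.log(0.25), abs=1e-3)

    def test_zero_total_likelihood_reports_pattern(self):
        log_lik = np.array([[-np.inf, -1.0], [-np.inf, -np.inf]])
        with pytest.raises(FloatingPointError, match="pattern 1"):
            mixture_loglik(log_lik, np.array([0.0, 1.0]), np.array([1, 1]))

    def test_large_tree_fast_rate_stays_finite(self, model):
        # 96 taxa with a rate-10 category exercises the scaling path
        tree = pe.make_balanced_tree(96, 0.1)
        mix = pe.build_rate_mixture(0.05, 0.0, 4)  # top rate close to 4
        aln = pe.simulate_alignment(tree, model, mix, 100, seed=4)
        pat = pe.compress_patterns(aln)
        eng = PruningEngine(tree, pat)
        eng.set_model(model.kappa, np.array([0.01, 0.1, 1.0, 10.0]))
        ll = eng.log_likelihood(np.array([0.0, 0.25, 0.25, 0.25, 0.25]))
        assert np.isfinite(ll)

    def test_cache_is_observationally_transparent(self, paper6, model, small_patterns):
        mix = pe.build_rate_mixture(0.5, 0.2, 4)
        a = PruningEngine(paper6, small_patterns, use_cache=True)
        b = PruningEngine(paper6, small_patterns, use_cache=False)
        for eng in (a, b):
            eng.set_model(model.kappa, mix.rates[1:])
        assert a.log_likelihood(mix.weights) == pytest.approx(
            b.log_likelihood(mix.weights), abs=1e-9
        )
        for eng in (a, b):
            eng.set_branch(1, 0.33)
        assert a.log_likelihood(mix.weights) == pytest.approx(
            b.log_likelihood(mix.weights), abs=1e-9
        )

    def test_taxon_mismatch_rejected(self, model, small_patterns):
        other = pe.make_balanced_tree(6, 0.1, labels=[f"X{i}" for i in range(6)])
        mix = pe.build_rate_mixture(0.5, 0.2, 4)
        with pytest.raises(ValueError, match="differ"):
            pe.log_likelihood(other, model, mix, small_patterns)
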
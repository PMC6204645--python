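import numpy as np
import pytest

import phyloem as pe
from phyloem.likelihood import PatternLikelihoods


def _sim_patterns(tree, model, alpha, p_inv, n_sites, seed):
    mix = pe.build_rate_mixture(alpha, p_inv, 4)
    aln = pe.simulate_alignment(tree, model, mix, n_sites, seed)
    return pe.compress_patterns(aln)


class TestEMStep:
    def test_hand_computed_two_pattern_update(self):
        # constant pattern (count 3) with L = [0.25, 0.1 x4]; variable
        # pattern (count 1) can never be invariable. With p_inv = 0.4:
        # posterior(const) = 0.4*0.25 / (0.4*0.25 + 0.6*0.1) = 0.625
        # update = (3*0.625 + 1*0) / 4 = 0.46875
        aln = pe.Alignment.from_sequences(["a", "b"], ["AAAC", "AAAG"])
        pat = pe.compress_patterns(aln)
        assert pat.counts.tolist() == [3, 1]
        log_lik = np.log(np.array([
            [0.25, 0.1, 0.1, 0.1, 0.1],
            [1e-300, 0.2, 0.2, 0.2, 0.2],
        ]))
        log_lik[1, 0] = -np.inf
        pl = PatternLikelihoods(log_lik=log_lik, counts=pat.counts)
        mix = pe.build_rate_mixture(1.0, 0.4, 4)
        assert pe.em_step_pinv(pat, pl, mix) == pytest.approx(0.46875, abs=1e-12)

    def test_no_constant_columns_updates_to_zero(self, model):
        tree = pe.parse_newick("(A:0.1,B:0.1);")
        aln = pe.Alignment.from_sequences(["A", "B"], ["ACGT", "CATG"])
        pat = pe.compress_patterns(aln)
        mix = pe.build_rate_mixture(1.0, 0.3, 4)
        pl = pe.pattern_category_likelihoods(tree, model, mix, pat)
        assert pe.em_step_pinv(pat, pl, mix) == 0.0

    def test_uninformative_likelihood_is_fixed_point(self):
        aln = pe.Alignment.from_sequences(["a", "b"], ["AA", "AA"])
        pat = pe.compress_patterns(aln)
        log_lik = np.zeros((1, 5))  # L identical across all categories
        pl = PatternLikelihoods(log_lik=log_lik, counts=pat.counts)
        mix = pe.build_rate_mixture(1.0, 0.37, 4)
        assert pe.em_step_pinv(pat, pl, mix) == pytest.approx(0.37, abs=1e-12)

    def test_update_bounded_by_constant_fraction(self, paper6, model):
        pat = _sim_patterns(paper6, model, 0.5, 0.5, 2000, 11)
        mix = pe.build_rate_mixture(0.5, 0.8, 4)
        pl = pe.pattern_category_likelihoods(paper6, model, mix, pat)
        update = pe.em_step_pinv(pat, pl, mix)
        assert 0.0 <= update <= pat.constant_site_fraction()


class TestScalarOptimizers:
    def test_alpha_recovery_on_simulation(self, paper6, model):
        pat = _sim_patterns(paper6, model, 1.0, 0.0, 30_000, 17)
        est = pe.optimize_alpha(paper6, model, pat, p_inv=0.0)
        assert est == pytest.approx(1.0, rel=0.10)

    def test_alpha_never_decreases_likelihood(self, paper6, model):
        pat = _sim_patterns(paper6, model, 0.5, 0.1, 2000, 23)
        est = pe.optimize_alpha(paper6, model, pat, p_inv=0.1)
        ll_est = pe.loglik_at(paper6, model, est, 0.1, pat)
        ll_one = pe.loglik_at(paper6, model, 1.0, 0.1, pat)
        assert ll_est >= ll_one - 1e-6

    def test_kappa_recovery_on_simulation(self, paper6):
        truth = pe.K2PModel(kappa=4.0)
        pat = _sim_patterns(paper6, truth, 1.0, 0.0, 30_000, 29)
        mix = pe.build_rate_mixture(1.0, 0.0, 4)
        est = pe.optimize_substitution(paper6, pe.K2PModel(kappa=2.0), mix, pat)
        assert est == pytest.approx(4.0, rel=0.10)

    def test_kappa_transversion_free_hits_upper_bound(self):
        tree = pe.parse_newick("(A:0.3,B:0.3);")
        # only transitions (A<->G) observed
        aln = pe.Alignment.from_sequences(["A", "B"], ["AG" * 40, "GA" * 40])
        pat = pe.compress_patterns(aln)
        mix = pe.build_rate_mixture(1e4, 0.0, 4)
        est = pe.optimize_substitution(tree, pe.K2PModel(kappa=4.0), mix, pat)
        assert est >= 99.0

    def test_kappa_entry_at_optimum_unchanged(self, paper6):
        truth = pe.K2PModel(kappa=4.0)
        pat = _sim_patterns(paper6, truth, 1.0, 0.0, 5000, 31)
        mix = pe.build_rate_mixture(1.0, 0.0, 4)
        first = pe.optimize_substitution(paper6, truth, mix, pat)
        again = pe.optimize_substitution(paper6, pe.K2PModel(kappa=first), mix, pat)
        assert again == pytest.approx(first, rel=1e-2)


class TestBranchLengths:
    def test_jukes_cantor_distance_closed_form(self):
        # JC limit: kappa=1, no invariable sites, near-uniform rates;
        # the ML distance is -(3/4) ln(1 - (4/3) p_hat)
        jc = pe.K2PModel(kappa=1.0)
        tree = pe.parse_newick("(A:0.05,B:0.05);")
        mix = pe.build_rate_mixture(1e6, 0.0, 4)
        aln = pe.simulate_alignment(tree, jc, mix, 50_000, seed=37)
        pat = pe.compress_patterns(aln)
        p_hat = float(np.mean(aln.codes[0] != aln.codes[1]))
        expected = -0.75 * np.log(1.0 - 4.0 * p_hat / 3.0)
        start = tree.copy()
        start.lengths[start.lengths > 0] = 0.3  # deliberately wrong start
        fitted = pe.optimize_branch_lengths(start, jc, mix, pat, sweeps=5)
        assert fitted.tree_length() == pytest.approx(expected, rel=5e-3)

    def test_identical_sequences_shrink_to_lower_bound(self, model):
        tree = pe.parse_newick("(A:0.2,B:0.2);")
        aln = pe.Alignment.from_sequences(["A", "B"], ["ACGT" * 25] * 2)
        pat = pe.compress_patterns(aln)
        mix = pe.build_rate_mixture(1.0, 0.0, 4)
        fitted = pe.optimize_branch_lengths(tree, model, mix, pat, sweeps=3)
        assert fitted.tree_length() <= 3e-6

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_sweep_never_decreases_likelihood(self, paper6, model, seed):
        pat = _sim_patterns(paper6, model, 0.5, 0.2, 1500, seed)
        mix = pe.build_rate_mixture(0.8, 0.1, 4)
        rng = np.random.default_rng(seed)
        start = paper6.copy()
        mask = np.arange(start.n_nodes) != start.root
        start.lengths[mask] = rng.uniform(0.02, 0.6, mask.sum())
        before = pe.log_likelihood(start, model, mix, pat)
        fitted = pe.optimize_branch_lengths(start, model, mix, pat)
        after = pe.log_likelihood(fitted, model, mix, pat)
        assert after >= before - 1e-9


class TestFitIG:
    def test_loglik_at_matches_fit_result(self, paper6, model):
        pat = _sim_patterns(paper6, model, 1.0, 0.3, 3000, 41)
        fit = pe.fit_ig(paper6, pat, "K2P", pe.FitConfig(n_starts=4))
        check = pe.loglik_at(
            fit.tree, pe.K2PModel(kappa=fit.kappa), fit.alpha, fit.p_inv, pat
        )
        assert check == pytest.approx(fit.log_likelihood, abs=1e-3)

    def test_traces_are_monotone(self, paper6, model):
        pat = _sim_patterns(paper6, model, 0.5, 0.4, 3000, 43)
        fit = pe.fit_ig(paper6, pat, "K2P", pe.FitConfig(n_starts=5))
        for trace in fit.traces:
            assert np.all(np.diff(trace) >= -1e-6)

    @pytest.mark.parametrize("seed", [5, 6])
    def test_multistart_dominates_single_start(self, paper6, model, seed):
        pat = _sim_patterns(paper6, model, 0.5, 0.3, 4000, seed)
        multi = pe.fit_ig(paper6, pat, "K2P", pe.FitConfig(n_starts=10))
        single = pe.fit_ig(paper6, pat, "K2P", pe.FitConfig(n_starts=1))
        assert multi.log_likelihood >= single.log_likelihood - 1e-6

    def test_all_constant_alignment_degenerate(self, paper6, model):
        aln = pe.Alignment.from_sequences(
            [f"T{i+1}" for i in range(6)], ["A" * 200] * 6
        )
        fit = pe.fit_ig(paper6, aln, "K2P", pe.FitConfig(n_starts=3))
        assert np.isfinite(fit.log_likelihood)
        assert fit.p_inv >= 0.5
        # no substitutions observed: the fitted tree collapses
        assert fit.tree_length < 1e-5

    def test_start_grid_spans_constant_fraction(self, paper6, model):
        pat = _sim_patterns(paper6, model, 0.5, 0.5, 2000, 47)
        fit = pe.fit_ig(paper6, pat, "K2P", pe.FitConfig(n_starts=10))
        starts = fit.start_pinv
        assert starts[0] == 0.0
        assert starts[-1] == pytest.approx(pat.constant_site_fraction())
        assert len(starts) == 10

    def test_taxon_mismatch_rejected(self, model):
        tree = pe.make_balanced_tree(6, 0.1, labels=[f"Z{i}" for i in range(6)])
        aln = pe.Alignment.from_sequences(
            [f"T{i+1}" for i in range(6)], ["ACGT"] * 6
        )
        with pytest.raises(ValueError):
            pe.fit_ig(tree, aln, "K2P", pe.FitConfig(n_starts=1))

    def test_unsupported_model_family(self, paper6, small_alignment):
        with pytest.raises(ValueError):
            pe.fit_ig(paper6, small_alignment, "GTR")

    def test_config_validation(self):
        with pytest.raises(ValueError):
            pe.FitConfig(epsilon=0.0)
        with pytest.raises(ValueError):
            pe.FitConfig(n_starts=0)
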
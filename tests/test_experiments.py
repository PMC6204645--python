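import numpy as np
import pandas as pd
import pytest

import phyloem as pe
from phyloem.experiments import ACCURATE, INACCURATE, MODERATE


class TestClassification:
    @pytest.mark.parametrize(
        "mean,truth,quantity,expected",
        [
            (0.59, 0.5, "alpha", MODERATE),        # 18% deviation
            (1.0, 1.0, "alpha", ACCURATE),
            (0.549, 0.5, "alpha", ACCURATE),       # 9.8%
            (0.55, 0.5, "alpha", MODERATE),        # exactly 10%
            (0.625, 0.5, "alpha", MODERATE),       # exactly 25%
            (0.626, 0.5, "alpha", INACCURATE),
            (17.5, 18.9, "tree_length", ACCURATE),  # 7.4%
            (177.0, 18.9, "tree_length", INACCURATE),
            # absolute bands for true p_inv = 0
            (0.005, 0.0, "p_inv", ACCURATE),
            (0.01, 0.0, "p_inv", ACCURATE),
            (0.011, 0.0, "p_inv", MODERATE),
            (0.05, 0.0, "p_inv", MODERATE),
            (0.06, 0.0, "p_inv", INACCURATE),
        ],
    )
    def test_deviation_bands(self, mean, truth, quantity, expected):
        assert pe.classify_deviation(mean, truth, quantity) == expected

    def test_zero_truth_only_valid_for_p_inv(self):
        with pytest.raises(ValueError):
            pe.classify_deviation(0.5, 0.0, "alpha")
        with pytest.raises(ValueError):
            pe.classify_deviation(0.5, 0.0, "tree_length")
        with pytest.raises(ValueError):
            pe.classify_deviation(0.5, 1.0, "banana")


class TestSeeding:
    def test_replicate_seed_deterministic_and_bounded(self):
        a = pe.replicate_seed(1, 6, 0.5, 0.0, 3)
        b = pe.replicate_seed(1, 6, 0.5, 0.0, 3)
        c = pe.replicate_seed(1, 6, 0.5, 0.1, 3)
        assert a == b
        assert a != c
        assert 0 <= a < 2**31

    def test_cells_independent_of_iteration_order(self):
        seeds = {
            pe.replicate_seed(0, s, a, p, r)
            for s in (6, 24)
            for a in (0.5, 1.0)
            for p in (0.0, 0.5)
            for r in range(3)
        }
        assert len(seeds) == 24  # no collisions on this small grid


@pytest.fixture(scope="module")
def tiny_cell_config():
    return pe.GridConfig(
        tree_sizes=(6,),
        alphas=(1.0,),
        pinvs=(0.3,),
        replicates=2,
        n_sites=400,
        base_seed=5,
        fit=pe.FitConfig(n_starts=3),
    )


class TestGrid:
    def test_run_cell_rows_and_determinism(self, tiny_cell_config):
        t1 = pe.run_cell(6, 1.0, 0.3, tiny_cell_config)
        t2 = pe.run_cell(6, 1.0, 0.3, tiny_cell_config)
        assert len(t1) == 2
        pd.testing.assert_frame_equal(t1, t2)
        assert {"alpha_hat", "pinv_hat", "ll_fit", "ll_truth"} <= set(t1.columns)

    def test_run_grid_and_report_idempotent(self, tiny_cell_config):
        report, table = pe.run_grid(tiny_cell_config)
        assert len(table) == 2
        assert report.cells["n_replicates"].sum() == 2
        lengths = {6: pe.study_tree(6).tree_length()}
        again = pe.aggregate_cells(table, lengths)
        pd.testing.assert_frame_equal(report.cells, again)

    def test_truth_beats_percentage(self):
        table = pd.DataFrame(
            {
                "tree_size": [6, 6, 6, 24],
                "ll_fit": [-10.0, -10.0, -10.0, -5.0],
                "ll_truth": [-10.0, -9.5, -10.2, -5.0],
            }
        )
        assert pe.truth_beats_estimate_pct(table, 6) == pytest.approx(100 / 3)
        assert pe.truth_beats_estimate_pct(table, 24) == 0.0
        # exact ties never count as wins
        tied = table.assign(ll_truth=table["ll_fit"])
        assert pe.truth_beats_estimate_pct(tied) == 0.0
        with pytest.raises(ValueError):
            pe.truth_beats_estimate_pct(table.iloc[:0])
        with pytest.raises(ValueError):
            pe.truth_beats_estimate_pct(table, 96)

    def test_config_json_round_trip(self, tiny_cell_config):
        back = pe.GridConfig.from_json(tiny_cell_config.to_json())
        assert back == tiny_cell_config


class TestSurface:
    def test_single_point_equals_loglik_at(self, paper6, model, small_patterns):
        scan = pe.surface_scan(
            small_patterns, paper6, model, [0.5], [0.2], mode="fixed"
        )
        expected = pe.loglik_at(paper6, model, 0.5, 0.2, small_patterns)
        assert scan.loglik[0, 0] == pytest.approx(expected, abs=1e-9)
        peaks = scan.local_maxima()
        assert len(peaks) == 1
        assert peaks.loc[0, "delta_lnl"] == 0.0

    def test_grid_maximum_dominates(self, paper6, model, small_patterns):
        scan = pe.surface_scan(
            small_patterns, paper6, model,
            np.geomspace(0.1, 2.0, 5), np.linspace(0.0, 0.6, 4),
        )
        assert scan.loglik.shape == (4, 5)
        best = scan.local_maxima().iloc[0]
        assert best["loglik"] == scan.loglik.max()
        frame = scan.to_frame()
        assert frame.shape == (4, 5)

    def test_reoptimize_mode_not_below_fixed(self, paper6, model, small_patterns):
        fixed = pe.surface_scan(
            small_patterns, paper6, model, [0.8], [0.1], mode="fixed"
        )
        reopt = pe.surface_scan(
            small_patterns, paper6, model, [0.8], [0.1], mode="reoptimize"
        )
        assert reopt.loglik[0, 0] >= fixed.loglik[0, 0] - 1e-6

    def test_invalid_arguments(self, paper6, model, small_patterns):
        with pytest.raises(ValueError):
            pe.surface_scan(small_patterns, paper6, model, [], [0.1])
        with pytest.raises(ValueError):
            pe.surface_scan(small_patterns, paper6, model, [1.0], [0.1], mode="x")


def test_taxon_sampling_improves_pinv_accuracy(model):
    # more taxa give more reliable p_inv estimates: aggregate absolute
    # error over matched cells is no worse for 24 than for 6 taxa
    cells = [(1.0, 0.5), (1.0, 0.8)]
    errs = {}
    for size in (6, 24):
        tree = pe.study_tree(size)
        tot = 0.0
        for a, p in cells:
            mix = pe.build_rate_mixture(a, p, 4)
            for rep in range(2):
                seed = pe.replicate_seed(3, size, a, p, rep)
                aln = pe.simulate_alignment(tree, model, mix, 4000, seed)
                fit = pe.fit_ig(tree, aln, "K2P", pe.FitConfig())
                tot += abs(fit.p_inv - p)
        errs[size] = tot / (2 * len(cells))
    assert errs[24] <= errs[6] + 0.01
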
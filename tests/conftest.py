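import numpy as np
import pytest

import phyloem as pe


@pytest.fixture(scope="session")
def model():
    """K2P with the study's ts/tv counts ratio of 2 (rate ratio 4)."""
    return pe.K2PModel.from_tstv_counts(2.0)


@pytest.fixture(scope="session")
def paper6():
    """The 6-taxon study tree: three cherries, one 0.2 internal branch."""
    return pe.make_balanced_tree(6, 0.1, 0.2)


@pytest.fixture(scope="session")
def small_alignment(paper6, model):
    """A modest simulated alignment shared by read-only tests."""
    mix = pe.build_rate_mixture(0.5, 0.2, 4)
    return pe.simulate_alignment(paper6, model, mix, 2000, seed=42)


@pytest.fixture(scope="session")
def small_patterns(small_alignment):
    return pe.compress_patterns(small_alignment)


def brute_force_loglik(tree, model, mixture, patterns):
    """Independent oracle: likelihood by explicit summation over all
    internal-state assignments (exponential in the number of internal
    nodes; only usable on tiny trees)."""
    from itertools import product

    internals = [v for v in range(tree.n_nodes) if not tree.is_leaf(v)]
    leaves = tree.leaf_indices()
    row_of = {lab: i for i, lab in enumerate(patterns.labels)}
    total = 0.0
    for i in range(patterns.n_patterns):
        site = 0.0
        for j, (w, r) in enumerate(zip(mixture.weights, mixture.rates)):
            if w == 0:
                continue
            pmats = {
                v: pe.k2p_transition_matrix(float(tree.lengths[v]) * r, model.kappa)
                for v in range(tree.n_nodes)
                if v != tree.root
            }
            lik = 0.0
            for assign in product(range(4), repeat=len(internals)):
                state = dict(zip(internals, assign))
                for v in leaves:
                    code = int(patterns.codes[row_of[tree.labels[v]], i])
                    state[v] = code
                term = 0.25  # uniform root frequency
                ok = True
                for v in range(tree.n_nodes):
                    if v == tree.root:
                        continue
                    pa = state[int(tree.parent[v])]
                    ch = state[v]
                    if ch == 4:  # missing: marginalize by summing P row
                        continue
                    term *= pmats[v][pa, ch]
                    if term == 0.0:
                        ok = False
                        break
                if ok:
                    lik += term
            site += w * lik
        total += float(patterns.counts[i]) * np.log(site)
    return total
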
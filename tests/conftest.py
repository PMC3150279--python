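import itertools

import numpy as np
import pytest

from skyisland import build_model, simulate_gene_tree


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def session_rng():
    return np.random.default_rng(87)


def brute_force_parsimony(tree, states):
    """Minimum unordered-parsimony length by exhaustive internal-state
    enumeration on a GeneTree; oracle for the Fitch/Hartigan pass."""
    n = tree.n_tips
    K = max(states) + 1
    best = None
    for assign in itertools.product(range(K), repeat=n - 1):
        full = list(states) + list(assign)
        cost = 0
        for j in range(n - 1):
            p = full[n + j]
            cost += (full[tree.left[j]] != p) + (full[tree.right[j]] != p)
        if best is None or cost < best:
            best = cost
    return best


def random_gene_tree(n_tips, rng, ne=100.0):
    """A random panmictic coalescent genealogy with anonymous tips."""
    model = build_model("single", total_ne=ne, deme_sizes={"POP": n_tips})
    return simulate_gene_tree(model, {"POP": n_tips}, rng)
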
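import dendropy
import numpy as np
import pytest
from scipy.linalg import block_diag

from phylosparse import solver


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def hand_tree():
    """((A:1,B:1):1,C:2); — pairwise distances computable by hand."""
    return dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick")


@pytest.fixture
def two_leaf_tree():
    return dendropy.Tree.get(data="(A:0.5,B:0.5);", schema="newick")


@pytest.fixture(scope="session")
def tree20():
    from phylosparse.simulate import simulate_tree

    return simulate_tree(20, seed=3)


@pytest.fixture(scope="session")
def tree200_structures():
    """200-leaf coalescent tree with distances, correlations at alpha=2."""
    from phylosparse import phylo
    from phylosparse.simulate import simulate_tree

    tree = simulate_tree(200, seed=11)
    D = phylo.patristic_distances(tree)
    C = phylo.correlation_matrix(D, 2.0)
    return tree, D, C


@pytest.fixture
def small_linear_problem(rng):
    X = rng.normal(size=(50, 5))
    beta = np.array([1.0, -1.0, 0.0, 0.0, 0.5])
    y = X @ beta + 0.5 * rng.normal(size=50)
    return X, y


def make_clique_omega(sizes, kappas, omega0s):
    """Block-diagonal inverse-correlation matrix of disjoint cliques.

    Within clique g of size v_g: diagonal kappa_g (v_g - 1) Omega_g0,
    off-diagonal -Omega_g0.
    """
    blocks = []
    for v, k, o in zip(sizes, kappas, omega0s):
        B = -o * np.ones((v, v))
        np.fill_diagonal(B, k * (v - 1) * o)
        blocks.append(B)
    return block_diag(*blocks)


def theorem_xi(t: float, gamma: float) -> float:
    """Grouping-bound factor xi(t, gamma) for the clique design."""
    if gamma * t > 1:
        return max(2 * gamma / (gamma * t - 1),
                   (gamma * t + 1) / (t * (gamma * t - 1)),
                   1 / t)
    return 1 / t


def brute_force_objective(intercept, beta, X, y, family, lam1, gamma, lam2,
                          structure):
    """Term-by-term naive recomputation of the penalized objective."""
    n = len(y)
    beta = np.asarray(beta, dtype=float)
    total = 0.0
    for i in range(n):
        eta = intercept + float(np.dot(X[i], beta))
        if family == "linear":
            total += 0.5 * (y[i] - eta) ** 2
        else:
            total += np.log(1 + np.exp(eta)) - y[i] * eta
    total /= n
    for bj in beta:
        a = abs(bj)
        if a <= gamma * lam1:
            total += lam1 * a - a * a / (2 * gamma)
        else:
            total += 0.5 * gamma * lam1 * lam1
    if lam2 > 0:
        total += lam2 * float(beta @ structure @ beta)
    return total


@pytest.fixture
def clique_tools():
    return make_clique_omega, theorem_xi
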
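"""Independent brute-force oracles used to check the implementation.

These deliberately avoid the code paths they validate: probabilities come
from binomial coefficients, DAG statistics from explicit transitive
closures, and loss counts from exhaustive set-cover search over subtree
leaf sets.
"""

import itertools
from math import comb

import networkx as nx


# -- MSGEA ------------------------------------------------------------------


def hypergeom_pmf(m: int, N: int, K: int, n: int) -> float:
    """P(X = m) for X ~ Hypergeometric(population N, successes K, draws n)."""
    if m < max(0, n + K - N) or m > min(n, K):
        return 0.0
    return comb(K, m) * comb(N - K, n - m) / comb(N, n)


def z_score(m: int, N: int, K: int, n: int) -> float:
    mean = K * n / N
    return (m - mean) / mean**0.5


def joint_tail_probability(margins, observed, tol=1e-12) -> float:
    """P(sum of z-scores >= observed) by explicit nested enumeration.

    ``margins`` is a list of (N, K, n) per species; every joint outcome is
    visited and weighted by the product of exact PMFs.
    """
    supports = [
        range(max(0, n + K - N), min(n, K) + 1) for (N, K, n) in margins
    ]
    total = 0.0
    for outcome in itertools.product(*supports):
        score = sum(
            z_score(m, N, K, n) for m, (N, K, n) in zip(outcome, margins)
        )
        if score >= observed - tol:
            prob = 1.0
            for m, (N, K, n) in zip(outcome, margins):
                prob *= hypergeom_pmf(m, N, K, n)
            total += prob
    return total


def fisher_upper_tail(N: int, K: int, n: int, m_obs: int) -> float:
    """One-tailed Fisher p = P(X >= m_obs) from binomial coefficients."""
    return sum(hypergeom_pmf(m, N, K, n) for m in range(m_obs, min(n, K) + 1))


def bh_by_hand(pvalues):
    """Step-up BH: q_(i) = min_{j>=i} min(1, m p_(j) / j)."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * pvalues[i] / rank)
        adjusted[i] = min(1.0, running)
    return adjusted


# -- DAG statistics ----------------------------------------------------------


def dag_ancestors(graph: nx.DiGraph, term: str) -> set[str]:
    return set(nx.descendants(graph, term))  # edges point child -> parent


def dag_min_depth(graph: nx.DiGraph, term: str, root: str) -> int:
    return nx.shortest_path_length(graph, term, root)


def dag_descendant_count(graph: nx.DiGraph, term: str) -> int:
    return len(nx.ancestors(graph, term))


# -- Dollo loss counting -----------------------------------------------------


def subtree_leaf_sets(tree, exempt) -> list[frozenset]:
    """Leaf set (exempt pruned) of every node of a dendropy tree."""
    out = []
    for node in tree.preorder_node_iter():
        leaves = frozenset(
            leaf.taxon.label.replace(" ", "_") for leaf in node.leaf_iter()
        ) - frozenset(exempt)
        if leaves:
            out.append(leaves)
    return list(set(out))


def min_losses_by_cover(tree, exempt, present, leaves) -> int:
    """Minimum number of disjoint all-absent subtrees covering the absent set.

    Exhaustive search over combinations of candidate subtree leaf sets
    (those fully contained in the absent set), requiring an exact disjoint
    cover.
    """
    absent = frozenset(leaves) - frozenset(present)
    if not absent:
        return 0
    candidates = [s for s in subtree_leaf_sets(tree, exempt) if s <= absent]
    for k in range(1, len(candidates) + 1):
        for combo in itertools.combinations(candidates, k):
            if sum(len(c) for c in combo) != len(absent):
                continue
            union = frozenset().union(*combo)
            if union == absent:
                return k
    raise AssertionError("no subtree cover found for a non-empty absent set")
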
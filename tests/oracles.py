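"""Independent brute-force oracles used to pin expected values.

Everything here is deliberately written without the package's pruning or
spectral machinery: likelihoods come from exhaustive enumeration over
internal-node state assignments, matrix exponentials from a truncated Taylor
series, and the residue/gap dynamics from the closed-form two-state chain.
"""

from __future__ import annotations

import itertools

import numpy as np

from indelphase.io import GAP, UNKNOWN, PhyloTree
from indelphase.likelihood import LEAF_PARTIAL_TABLE

N_STATES = 5


def series_expm(q: np.ndarray, t: float, order: int = 50) -> np.ndarray:
    """exp(Qt) by truncated Taylor series (valid for small ||Qt||)."""
    a = q * t
    term = np.eye(q.shape[0])
    total = term.copy()
    for k in range(1, order + 1):
        term = term @ a / k
        total += term
    return total


def two_state_gap_prob(lam: float, mu: float, t: float) -> tuple[float, float]:
    """(P(gap|residue,t), P(gap|gap,t)) of the lumped two-state chain."""
    total = lam + mu
    if total == 0:
        return 0.0, 1.0
    decay = 1.0 - np.exp(-total * t)
    xi = lam / total * decay
    from_res = mu / total * decay
    return from_res, 1.0 - xi


def enum_column_likelihood(tree: PhyloTree, leaf_codes: dict,
                           p_branch: list, root_weights: np.ndarray) -> float:
    """Column likelihood by summing over every internal-state assignment.

    ``leaf_codes`` maps leaf node id -> symbol code; ``p_branch[i]`` is the
    transition matrix on the branch above node ``i``.
    """
    internal = [i for i in range(tree.n_nodes) if not tree.is_leaf(i)]
    total = 0.0
    for assign in itertools.product(range(N_STATES), repeat=len(internal)):
        state = dict(zip(internal, assign))
        prob = root_weights[state[0]] if internal else None
        if prob is None:  # single-leaf tree: root is the leaf
            prob = float(root_weights @ LEAF_PARTIAL_TABLE[leaf_codes[0]])
            return prob
        for child in range(1, tree.n_nodes):
            parent_state = state[tree.parent[child]]
            if tree.is_leaf(child):
                emit = LEAF_PARTIAL_TABLE[leaf_codes[child]]
                prob *= float(p_branch[child][parent_state] @ emit)
            else:
                prob *= p_branch[child][parent_state, state[child]]
        total += prob
    return total


def enum_node_posteriors(tree: PhyloTree, leaf_codes: dict, p_branch: list,
                         root_weights: np.ndarray) -> np.ndarray:
    """(n_nodes, 5) marginal posterior over states for every node, by
    enumerating internal assignments and leaf states jointly."""
    post = np.zeros((tree.n_nodes, N_STATES))
    internal = [i for i in range(tree.n_nodes) if not tree.is_leaf(i)]
    leaves = [i for i in range(tree.n_nodes) if tree.is_leaf(i)]
    for assign in itertools.product(range(N_STATES),
                                    repeat=len(internal) + len(leaves)):
        state = dict(zip(internal + leaves, assign))
        prob = root_weights[state[0]]
        for child in range(1, tree.n_nodes):
            prob *= p_branch[child][state[tree.parent[child]], state[child]]
        for leaf in leaves:
            prob *= LEAF_PARTIAL_TABLE[leaf_codes[leaf]][state[leaf]]
        for node in range(tree.n_nodes):
            post[node, state[node]] += prob
    return post / post.sum(axis=1, keepdims=True)
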
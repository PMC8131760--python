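"""Independent oracles used by the test suite.

Everything here deliberately avoids the package's own likelihood path:
transition probabilities come from scipy's matrix exponential and tree
likelihoods/marginals from explicit enumeration over all interior-node
state assignments, so agreement with the pruning implementation is a real
cross-check, not a tautology.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.linalg import expm

from chardisp.treedata import Phylogeny


def transition_matrix_expm(q01: float, q10: float, t: float) -> np.ndarray:
    Q = np.array([[-q01, q01], [q10, -q10]])
    return expm(Q * t)


def _prior_vector(root_prior, q01, q10):
    if root_prior == "flat":
        return np.array([0.5, 0.5])
    if root_prior == "unweighted":
        return np.array([1.0, 1.0])
    if root_prior == "stationary":
        s = q01 + q10
        return np.array([q10 / s, q01 / s])
    return np.asarray(root_prior, dtype=float)


def brute_force_loglik(
    tree: Phylogeny, states: dict, q01: float, q10: float, root_prior="flat"
) -> float:
    """Sum over every interior-node state assignment (exponential; tiny trees only)."""
    prior = _prior_vector(root_prior, q01, q10)
    P = {
        v: transition_matrix_expm(q01, q10, tree.branch_lengths[v])
        for v in range(tree.n_nodes)
        if v != tree.root
    }
    interior = [v for v in range(tree.n_nodes) if not tree.is_leaf(v)]
    fixed = {v: states[tree.labels[v]] for v in tree.leaves}
    total = 0.0
    for assign in itertools.product((0, 1), repeat=len(interior)):
        st = dict(fixed)
        st.update(zip(interior, assign))
        p = prior[st[tree.root]]
        for v in range(tree.n_nodes):
            if v != tree.root:
                p *= P[v][st[tree.parent[v]], st[v]]
        total += p
    return math.log(total)


def brute_force_marginals(
    tree: Phylogeny, states: dict, q01: float, q10: float, root_prior="flat"
) -> dict:
    """Per-interior-node state-1 posterior by enumeration, renormalized."""
    prior = _prior_vector(root_prior, q01, q10)
    P = {
        v: transition_matrix_expm(q01, q10, tree.branch_lengths[v])
        for v in range(tree.n_nodes)
        if v != tree.root
    }
    interior = [v for v in range(tree.n_nodes) if not tree.is_leaf(v)]
    fixed = {v: states[tree.labels[v]] for v in tree.leaves}
    mass = {v: np.zeros(2) for v in interior}
    total = 0.0
    for assign in itertools.product((0, 1), repeat=len(interior)):
        st = dict(fixed)
        st.update(zip(interior, assign))
        p = prior[st[tree.root]]
        for v in range(tree.n_nodes):
            if v != tree.root:
                p *= P[v][st[tree.parent[v]], st[v]]
        total += p
        for v in interior:
            mass[v][st[v]] += p
    return {v: mass[v] / total for v in interior}


def random_tree(rng: np.random.Generator, n_leaves: int, polytomy_prob: float = 0.25) -> Phylogeny:
    """Random topology (with occasional polytomies) and Exp(1) branch lengths."""
    items = [(f"L{i}",) for i in range(n_leaves)]  # nested-tuple subtrees
    while len(items) > 1:
        k = 3 if (len(items) >= 3 and rng.random() < polytomy_prob) else 2
        idx = rng.choice(len(items), size=k, replace=False)
        merged = tuple(items[i] for i in sorted(idx, reverse=True))
        for i in sorted(idx, reverse=True):
            items.pop(i)
        items.append(merged)

    children, blens, labels = [], [], []

    def emit(sub) -> int:
        if len(sub) == 1 and isinstance(sub[0], str):
            children.append([])
            labels.append(sub[0])
        else:
            kids = [emit(s) for s in sub]
            children.append(kids)
            labels.append(None)
        blens.append(float(rng.exponential(1.0)))
        return len(children) - 1

    emit(items[0])
    blens[-1] = 0.0
    return Phylogeny(children, blens, labels)


def random_states(rng: np.random.Generator, tree: Phylogeny) -> dict:
    return {lab: int(rng.integers(2)) for lab in tree.leaf_labels}
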
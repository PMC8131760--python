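"""Marginal ancestral-state probabilities under a fitted 2-state Mk model.

For every internal node v the marginal P(state(v) = r | tip data) is
obtained with the up-down (inside-outside) algorithm: the post-order
"inside" partial likelihoods from the pruning pass are combined with a
pre-order "outside" quantity carrying the likelihood contribution of the
rest of the tree and the root prior, then renormalized per node.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ValidationError
from .mk import RateModel, RootPrior, _resolve_root_prior
from .treedata import Phylogeny, TipStates

__all__ = ["NodeStateProbabilities", "marginal_states"]


@dataclass
class NodeStateProbabilities:
    """Per-internal-node (P(absent), P(present)) plus human-readable anchors."""

    probabilities: dict[int, tuple[float, float]]
    leaf_span: dict[int, tuple[str, str]]
    root: int

    def __getitem__(self, node: int) -> tuple[float, float]:
        return self.probabilities[node]

    def __len__(self) -> int:
        return len(self.probabilities)

    def items(self):
        return self.probabilities.items()

    def to_rows(self) -> list[dict]:
        rows = []
        for node, (p0, p1) in sorted(self.probabilities.items()):
            first, last = self.leaf_span[node]
            rows.append(
                {
                    "node_id": node,
                    "first_leaf": first,
                    "last_leaf": last,
                    "p_absent": p0,
                    "p_present": p1,
                }
            )
        return rows


def _edge_probs(model: RateModel, t: float) -> tuple[float, float, float, float]:
    """(P00, P01, P10, P11) along one branch, closed form."""
    s = model.q01 + model.q10
    if s == 0.0:
        return 1.0, 0.0, 0.0, 1.0
    e = math.exp(-s * t)
    pi0, pi1 = model.q10 / s, model.q01 / s
    return pi0 + pi1 * e, pi1 - pi1 * e, pi0 - pi0 * e, pi1 + pi0 * e


def marginal_states(
    tree: Phylogeny,
    states: TipStates,
    model: RateModel,
    root_prior: RootPrior = "flat",
    marginalize_missing: bool = False,
) -> NodeStateProbabilities:
    """Marginal state probabilities at every internal node (root included)."""
    pr0, pr1 = _resolve_root_prior(root_prior, model)
    n = tree.n_nodes

    # inside pass: renormalized partials (scaling factors cancel on normalization)
    L0 = [0.0] * n
    L1 = [0.0] * n
    for node in tree.postorder():
        kids = tree.children[node]
        if not kids:
            lab = tree.labels[node]
            st = states.states.get(lab, None)
            if st is None:
                if not marginalize_missing:
                    raise ValidationError(
                        f"leaf {lab!r} has no determined state; drop unknown-state "
                        "tips first or pass marginalize_missing=True"
                    )
                L0[node] = L1[node] = 1.0
            else:
                L0[node], L1[node] = (1.0, 0.0) if st == 0 else (0.0, 1.0)
            continue
        a0, a1 = 1.0, 1.0
        for c in kids:
            p00, p01, p10, p11 = _edge_probs(model, tree.branch_lengths[c])
            a0 *= p00 * L0[c] + p01 * L1[c]
            a1 *= p10 * L0[c] + p11 * L1[c]
        tot = a0 + a1
        if tot <= 0.0:
            raise ValidationError("tip data have zero likelihood under this model")
        L0[node], L1[node] = a0 / tot, a1 / tot

    # outside pass: G[v][s] ∝ P(data outside subtree v, state(v)=s)
    G0 = [0.0] * n
    G1 = [0.0] * n
    G0[tree.root], G1[tree.root] = pr0, pr1
    for node in tree.preorder():
        kids = tree.children[node]
        if not kids:
            continue
        # per-child message at the parent: m_c(s) = sum_r P(t_c)[s, r] L_c(r)
        msgs = []
        for c in kids:
            p00, p01, p10, p11 = _edge_probs(model, tree.branch_lengths[c])
            msgs.append((p00 * L0[c] + p01 * L1[c], p10 * L0[c] + p11 * L1[c]))
        for i, c in enumerate(kids):
            sib0, sib1 = G0[node], G1[node]
            for j, (m0, m1) in enumerate(msgs):
                if j != i:
                    sib0 *= m0
                    sib1 *= m1
            p00, p01, p10, p11 = _edge_probs(model, tree.branch_lengths[c])
            g0 = sib0 * p00 + sib1 * p10
            g1 = sib0 * p01 + sib1 * p11
            tot = g0 + g1
            if tot > 0:  # renormalize to keep magnitudes tame on deep trees
                g0, g1 = g0 / tot, g1 / tot
            G0[c], G1[c] = g0, g1

    probs: dict[int, tuple[float, float]] = {}
    span: dict[int, tuple[str, str]] = {}
    for node in range(n):
        if tree.is_leaf(node):
            continue
        w0 = G0[node] * L0[node]
        w1 = G1[node] * L1[node]
        tot = w0 + w1
        if tot <= 0.0:
            raise ValidationError("degenerate marginal at node {node}")
        probs[node] = (w0 / tot, w1 / tot)
        span[node] = tree.subtree_leaf_span(node)
    return NodeStateProbabilities(probabilities=probs, leaf_span=span, root=tree.root)
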
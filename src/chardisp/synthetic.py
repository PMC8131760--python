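"""Synthetic study inputs: Yule trees, traits with known rates, pairs, masks.

These generators stand in for real study inputs (a dated population tree, a
binary phenotype table with some unknowns, and a sympatric-pair list) so
the whole pipeline is exercisable and parameter recovery measurable with
known truth.  Trees are pure-birth (Yule): the simplest branching model
with species-tree-like shape; traits evolve under a user-chosen ER/ARD
model via the exact endpoint sampler; pairs are disjoint and either random
or biased toward large tip-to-tip path lengths, mimicking sympatric pairs
drawn from different species or species complexes (non-sisters).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ValidationError
from .mk import RateModel
from .simulate import simulate_tips
from .treedata import Phylogeny, SympatricPairs, TipStates

__all__ = ["SyntheticDataset", "yule_tree", "generate_dataset"]


def yule_tree(
    n_tips: int,
    birth_rate: float = 1.0,
    seed: int = 0,
    rescale_height: Optional[float] = None,
) -> Phylogeny:
    """Simulate a pure-birth (Yule) tree with *n_tips* extant leaves.

    Lineages split at per-lineage rate *birth_rate*; after the last split
    the tree grows for one further Exp(n * birth_rate) waiting time so
    terminal sister branches have positive length.  The result is
    ultrametric with leaves labelled t1..tn; *rescale_height* rescales all
    branch lengths so the root-to-tip height equals the given value.
    """
    if n_tips < 2:
        raise ValidationError(f"need at least 2 tips, got {n_tips}")
    if birth_rate <= 0:
        raise ValidationError(f"birth rate must be positive, got {birth_rate}")
    rng = np.random.default_rng(seed)

    t = 0.0
    counter = [0]

    class _Node:
        __slots__ = ("children", "length")

        def __init__(self):
            self.children: list[_Node] = []
            self.length = 0.0

    root = _Node()
    live_nodes = [(root, 0.0)]  # (node, birth time)
    k = 1
    t_root_split = 0.0
    while k < n_tips:
        t += rng.exponential(1.0 / (birth_rate * k))
        if k == 1:
            t_root_split = t
        idx = int(rng.integers(k))
        node, born = live_nodes[idx]
        node.length = t - born
        c1, c2 = _Node(), _Node()
        node.children = [c1, c2]
        live_nodes[idx] = (c1, t)
        live_nodes.append((c2, t))
        k += 1
    t += rng.exponential(1.0 / (birth_rate * k))
    for node, born in live_nodes:
        node.length = t - born

    # flatten to post-order arrays
    children: list[list[int]] = []
    blens: list[float] = []
    labels: list[Optional[str]] = []

    def emit(node: _Node) -> int:
        kids = [emit(c) for c in node.children]
        children.append(kids)
        blens.append(node.length)
        if kids:
            labels.append(None)
        else:
            counter[0] += 1
            labels.append(f"t{counter[0]}")
        return len(children) - 1

    emit(root)
    blens[-1] = 0.0  # root has no edge above it
    if rescale_height is not None:
        if rescale_height <= 0:
            raise ValidationError("rescale_height must be positive")
        height = t - t_root_split  # root-to-tip distance (pre-split stem excluded)
        blens = [b * rescale_height / height for b in blens]
    return Phylogeny(children, blens, labels)


@dataclass
class SyntheticDataset:
    """A complete synthetic study input with its generating truth recorded."""

    tree: Phylogeny
    true_model: RateModel
    complete_states: TipStates
    masked_states: TipStates
    pairs: SympatricPairs
    seed: int
    parameters: dict

    def masked_taxa(self) -> list[str]:
        return self.masked_states.missing_taxa()


def _choose_pairs(
    tree: Phylogeny, n_pairs: int, mode: str, rng: np.random.Generator
) -> SympatricPairs:
    labels = tree.leaf_labels
    if 2 * n_pairs > len(labels):
        raise ValidationError(
            f"{n_pairs} disjoint pairs need {2 * n_pairs} tips, tree has {len(labels)}"
        )
    if mode == "random":
        chosen = rng.choice(len(labels), size=2 * n_pairs, replace=False)
        pairs = [(labels[chosen[2 * i]], labels[chosen[2 * i + 1]]) for i in range(n_pairs)]
        return SympatricPairs(pairs)
    if mode != "distant":
        raise ValidationError(f"pair_mode must be 'random' or 'distant', got {mode!r}")

    # distant mode: repeatedly sample a pair from the top quintile of path
    # lengths among still-unused tips, so pairs are deep (non-sister) but not
    # deterministic
    unused = set(range(len(labels)))
    dist = {}
    pairs = []
    for _ in range(n_pairs):
        avail = sorted(unused)
        cand = []
        for ii, a in enumerate(avail):
            for b in avail[ii + 1 :]:
                key = (a, b)
                if key not in dist:
                    dist[key] = tree.path_length(labels[a], labels[b])
                cand.append((dist[key], a, b))
        cand.sort(reverse=True)
        top = cand[: max(1, len(cand) // 5)]
        _, a, b = top[int(rng.integers(len(top)))]
        pairs.append((labels[a], labels[b]))
        unused.discard(a)
        unused.discard(b)
    return SympatricPairs(pairs)


def generate_dataset(
    n_tips: int,
    model: RateModel,
    n_pairs: int,
    pair_mode: str = "distant",
    missing_fraction: float = 0.0,
    seed: int = 0,
    birth_rate: float = 1.0,
    root_prior: str = "stationary",
) -> SyntheticDataset:
    """Generate a full synthetic dataset: tree, trait, pairs and NA mask.

    ``round(missing_fraction * n_tips)`` tips, drawn uniformly without
    replacement, are masked to unknown in ``masked_states``;
    ``complete_states`` keeps the truth.  All generation parameters are
    recorded for exact replay.
    """
    if not (0 <= missing_fraction < 1):
        raise ValidationError("missing_fraction must lie in [0, 1)")
    tree = yule_tree(n_tips, birth_rate=birth_rate, seed=seed)
    batch = simulate_tips(tree, model, n_reps=1, seed=seed + 1, root_prior=root_prior)
    complete = batch.replicate(0)

    rng = np.random.default_rng(seed + 2)
    pairs = _choose_pairs(tree, n_pairs, pair_mode, rng)

    n_mask = round(missing_fraction * n_tips)
    labels = tree.leaf_labels
    masked_idx = rng.choice(n_tips, size=n_mask, replace=False) if n_mask else []
    masked_set = {labels[i] for i in masked_idx}
    masked = TipStates(
        {t: (None if t in masked_set else s) for t, s in complete.states.items()}
    )

    return SyntheticDataset(
        tree=tree,
        true_model=model,
        complete_states=complete,
        masked_states=masked,
        pairs=pairs,
        seed=seed,
        parameters={
            "n_tips": n_tips,
            "model_family": model.family,
            "q01": model.q01,
            "q10": model.q10,
            "n_pairs": n_pairs,
            "pair_mode": pair_mode,
            "missing_fraction": missing_fraction,
            "birth_rate": birth_rate,
            "root_prior": root_prior,
            "seed": seed,
            "masking": "uniform without replacement, exact count",
        },
    )
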
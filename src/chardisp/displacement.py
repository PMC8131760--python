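"""Sympatric-divergence statistic and its simulated null distribution.

The test asks whether sympatric taxon pairs differ in a binary phenotype
more often than stochastic character evolution on the phylogeny alone
("evolutionary contingency") predicts.  The statistic is the number of
sympatric pairs whose members carry different states; its null is built by
re-simulating tip states many times under the fitted transition rates and
recounting.  The upper tail P(D_sim >= d) is the probability that chance
alone produces at least the observed amount of divergence.

For the symmetric (ER) model the per-pair divergence probability has the
closed form p = (1 - exp(-2 q T))/2, where T is the tip-to-tip path length:
the state difference along the path joining two tips behaves as a 2-state
symmetric chain over total time T, regardless of where the root sits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ValidationError
from .mk import RateModel
from .simulate import SimulationBatch, simulate_tips
from .treedata import Phylogeny, SympatricPairs, TipStates

__all__ = [
    "PairClassification",
    "NullDistribution",
    "divergence_count",
    "classify_pairs",
    "null_distribution",
    "pair_difference_probability",
    "expected_pair_probabilities",
    "tail_probability",
    "lower_tail_probability",
]


@dataclass
class PairClassification:
    """Empirical pair status: confirmed different / same / undetermined."""

    different: list[tuple[str, str]]
    same: list[tuple[str, str]]
    undetermined: list[tuple[str, str]]

    @property
    def n_different(self) -> int:
        return len(self.different)

    @property
    def n_same(self) -> int:
        return len(self.same)

    @property
    def n_undetermined(self) -> int:
        return len(self.undetermined)

    @property
    def observed_range(self) -> tuple[int, int]:
        """Possible divergence counts once undetermined pairs are resolved."""
        return self.n_different, self.n_different + self.n_undetermined


def classify_pairs(states: TipStates, pairs: SympatricPairs) -> PairClassification:
    """Split pairs by whether their members' states differ, agree, or are unknown."""
    diff, same, undet = [], [], []
    for a, b in pairs:
        sa = states.states.get(a, None)
        sb = states.states.get(b, None)
        if sa is None or sb is None:
            undet.append((a, b))
        elif sa != sb:
            diff.append((a, b))
        else:
            same.append((a, b))
    return PairClassification(different=diff, same=same, undetermined=undet)


def divergence_count(states: TipStates, pairs: SympatricPairs) -> int:
    """Number of pairs whose members have determined, unequal states."""
    return classify_pairs(states, pairs).n_different


@dataclass
class NullDistribution:
    """Histogram of the divergence count over simulated tip-state datasets."""

    counts: np.ndarray  # length n_pairs + 1; counts[k] = #replicates with D = k
    n_sims: int
    seed: int
    model: RateModel
    pair_difference_frequency: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_pairs(self) -> int:
        return len(self.counts) - 1

    @property
    def mode(self) -> int:
        return int(np.argmax(self.counts))

    @property
    def mean(self) -> float:
        k = np.arange(len(self.counts))
        return float((k * self.counts).sum() / self.n_sims)


def null_distribution(
    tree: Phylogeny,
    model: RateModel,
    pairs: SympatricPairs,
    n_sims: int,
    seed: int,
    root_prior: str = "stationary",
    batch: Optional[SimulationBatch] = None,
) -> NullDistribution:
    """Simulate the null distribution of the divergence count.

    Simulation runs on the full tree (including any unknown-state taxa —
    simulated datasets have no missing states).  Pass a pre-built *batch*
    to reuse simulations across analyses.
    """
    pairs.validate_against(tree)
    if batch is None:
        batch = simulate_tips(tree, model, n_reps=n_sims, seed=seed, root_prior=root_prior)
    elif batch.n_reps != n_sims:
        raise ValidationError("supplied batch size does not match n_sims")

    pos = {lab: i for i, lab in enumerate(batch.tree_leaf_labels)}
    ia = np.array([pos[a] for a, _ in pairs], dtype=int)
    ib = np.array([pos[b] for _, b in pairs], dtype=int)
    differs = batch.tip_matrix[:, ia] != batch.tip_matrix[:, ib]  # (n_sims, n_pairs)
    d = differs.sum(axis=1)
    counts = np.bincount(d, minlength=len(pairs) + 1)
    return NullDistribution(
        counts=counts,
        n_sims=n_sims,
        seed=seed,
        model=model,
        pair_difference_frequency=differs.mean(axis=0),
    )


def pair_difference_probability(q: float, T: float) -> float:
    """Closed-form probability two tips differ under ER rate q, path length T."""
    if q < 0 or T < 0:
        raise ValidationError("rate and path length must be non-negative")
    return 0.5 * (1.0 - math.exp(-2.0 * q * T))


def expected_pair_probabilities(
    tree: Phylogeny, q: float, pairs: SympatricPairs
) -> np.ndarray:
    """Closed-form ER divergence probability for every pair, from path lengths."""
    return np.array([pair_difference_probability(q, tree.path_length(a, b)) for a, b in pairs])


def tail_probability(null: NullDistribution, d: int) -> float:
    """Monte Carlo upper-tail probability P(D_sim >= d)."""
    if d < 0 or d > null.n_pairs + 1:
        raise ValidationError(f"d must lie in [0, {null.n_pairs + 1}], got {d}")
    if d > null.n_pairs:
        return 0.0
    return float(null.counts[d:].sum() / null.n_sims)


def lower_tail_probability(null: NullDistribution, d: int) -> float:
    """P(D_sim <= d): the convergence-side alternative."""
    if d < -1 or d > null.n_pairs:
        raise ValidationError(f"d must lie in [-1, {null.n_pairs}], got {d}")
    if d < 0:
        return 0.0
    return float(null.counts[: d + 1].sum() / null.n_sims)
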
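import numpy as np
import pytest

import chardisp as cd


@pytest.fixture()
def cherry():
    return cd.parse_tree("(A:1.0,B:1.0);")


@pytest.fixture()
def three_leaf():
    return cd.parse_tree("((A:1,B:1):2,C:3);")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def lrt_size_experiment():
    """Shared Monte Carlo experiment: ER-vs-ARD LRT under ER truth (q = 0.26)
    on 1,000 independent 100-tip Yule trees.  Returns (n_rejections_at_0.05,
    n_replicates, mean_statistic); consumed by both the behavioural check and
    the strict nominal-size check."""
    from chardisp import mk

    n_rep = 1000
    rejections = 0
    stats_sum = 0.0
    for s in range(n_rep):
        tree = cd.yule_tree(100, seed=70_000 + s)
        states = cd.simulate_tips(tree, cd.RateModel.er(0.26), 1,
                                  seed=80_000 + s).replicate(0)
        fer = cd.fit(tree, states, "ER")
        fard = cd.fit(tree, states, "ARD")
        assert fer.log_lik <= fard.log_lik + 1e-6
        c = mk.compare_models(fer, fard)
        stats_sum += c.statistic
        if c.p_value < 0.05:
            rejections += 1
    return rejections, n_rep, stats_sum / n_rep


@pytest.fixture(scope="session")
def paper_shaped_dataset():
    """Synthetic stand-in for the study inputs: 80 tips, ER q=0.26, 9 distant
    pairs, 12 unknown-state taxa.  Labelled synthetic: it reproduces the
    study's structure and stated conditions, not its actual tree or data."""
    return cd.generate_dataset(
        n_tips=80,
        model=cd.RateModel.er(0.26),
        n_pairs=9,
        pair_mode="distant",
        missing_fraction=0.15,
        seed=2024,
    )
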
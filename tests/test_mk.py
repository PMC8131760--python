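"""Mk-model core: transition probabilities, pruning likelihood, fits, LRT."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import chardisp as cd
from chardisp import mk
from chardisp.errors import NumericalError, ValidationError

from _oracles import (
    brute_force_loglik,
    random_states,
    random_tree,
    transition_matrix_expm,
)


class TestTransitionMatrix:
    def test_zero_time_is_identity(self):
        for model in (cd.RateModel.er(0.26), cd.RateModel.ard(0.9, 0.1)):
            assert np.allclose(cd.transition_matrix(model, 0.0), np.eye(2))

    def test_er_offdiagonal_closed_form(self):
        P = cd.transition_matrix(cd.RateModel.er(0.26), 1.0)
        expect = 0.5 * (1 - math.exp(-0.52))
        assert P[0, 1] == pytest.approx(expect, abs=1e-12)
        assert P[1, 0] == pytest.approx(expect, abs=1e-12)

    def test_large_time_reaches_stationary(self):
        model = cd.RateModel.ard(0.2351, 0.3007)
        P = cd.transition_matrix(model, 1e4)
        pi = cd.stationary(model)
        assert np.allclose(P, np.vstack([pi, pi]), atol=1e-12)
        assert pi == pytest.approx([0.5612, 0.4388], abs=5e-5)

    def test_frozen_chain(self):
        assert np.allclose(cd.transition_matrix(cd.RateModel.er(0.0), 5.0), np.eye(2))

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            cd.transition_matrix(cd.RateModel.er(0.1), -1.0)

    @given(
        q01=st.floats(0.0, 10.0),
        q10=st.floats(0.0, 10.0),
        t=st.floats(0.0, 20.0),
        s=st.floats(0.0, 20.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_chapman_kolmogorov_and_rows(self, q01, q10, t, s):
        model = cd.RateModel.ard(q01, q10)
        Pt = cd.transition_matrix(model, t)
        Ps = cd.transition_matrix(model, s)
        Pts = cd.transition_matrix(model, t + s)
        assert np.allclose(Pt @ Ps, Pts, atol=1e-12)
        assert np.allclose(Pt.sum(axis=1), 1.0, atol=1e-12)
        assert Pt.min() >= -1e-15

    @given(
        q01=st.floats(0.01, 5.0),
        q10=st.floats(0.01, 5.0),
        t=st.floats(0.0, 10.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_matrix_exponential(self, q01, q10, t):
        mine = cd.transition_matrix(cd.RateModel.ard(q01, q10), t)
        assert np.allclose(mine, transition_matrix_expm(q01, q10, t), atol=1e-10)


class TestStationary:
    def test_er_is_half_half(self):
        assert np.allclose(cd.stationary(cd.RateModel.er(0.7)), [0.5, 0.5])

    def test_absorbing(self):
        assert np.allclose(cd.stationary(cd.RateModel.ard(0.0, 1.0)), [1.0, 0.0])

    def test_both_zero_rejected(self):
        with pytest.raises(ValidationError):
            cd.stationary(cd.RateModel.er(0.0))


class TestLogLikelihood:
    def test_cherry_closed_form(self, cherry):
        # brute force over the root state: ln(0.5*(P00(1)^2 + P10(1)^2))
        model = cd.RateModel.er(0.26)
        P = transition_matrix_expm(0.26, 0.26, 1.0)
        expect = math.log(0.5 * (P[0, 0] ** 2 + P[1, 0] ** 2))
        got = cd.log_likelihood(cherry, cd.TipStates({"A": 0, "B": 0}), model)
        assert got == pytest.approx(expect, abs=1e-12)
        assert got == pytest.approx(-1.083634, abs=1e-6)

    def test_frozen_chain_only_root_draw(self, three_leaf):
        states = cd.TipStates({"A": 0, "B": 0, "C": 0})
        got = cd.log_likelihood(three_leaf, states, cd.RateModel.er(0.0))
        assert got == pytest.approx(math.log(0.5), abs=1e-12)

    def test_unweighted_convention_shifts_by_ln2(self, cherry):
        states = cd.TipStates({"A": 0, "B": 1})
        model = cd.RateModel.er(0.3)
        flat = cd.log_likelihood(cherry, states, model, root_prior="flat")
        unw = cd.log_likelihood(cherry, states, model, root_prior="unweighted")
        assert unw == pytest.approx(flat + math.log(2), abs=1e-12)

    def test_missing_leaf_state_named(self, three_leaf):
        with pytest.raises(ValidationError, match="C"):
            cd.log_likelihood(three_leaf, cd.TipStates({"A": 0, "B": 1}), cd.RateModel.er(0.2))

    def test_marginalized_missing_tip_is_neutral(self, three_leaf):
        # a (1,1) tip partial: the cherry (A,B) alone determines the likelihood
        model = cd.RateModel.er(0.4)
        full = cd.log_likelihood(
            three_leaf, cd.TipStates({"A": 0, "B": 1, "C": None}), model,
            marginalize_missing=True,
        )
        reduced_tree = three_leaf.drop_leaves({"C"})
        reduced = cd.log_likelihood(reduced_tree, cd.TipStates({"A": 0, "B": 1}), model)
        assert full == pytest.approx(reduced, abs=1e-12)

    @pytest.mark.parametrize("case", range(50))
    def test_pruning_equals_enumeration(self, case):
        """Pruning lnL equals brute-force summation over interior states."""
        rng = np.random.default_rng(777 + case)
        tree = random_tree(rng, int(rng.integers(2, 7)))
        states = random_states(rng, tree)
        q01, q10 = rng.uniform(0.05, 2.0, size=2)
        expect = brute_force_loglik(tree, states, q01, q10)
        got = cd.log_likelihood(tree, cd.TipStates(states), cd.RateModel.ard(q01, q10))
        assert got == pytest.approx(expect, abs=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_er_reroot_invariance(self, seed):
        """Under the reversible ER model with a flat root, lnL is a property
        of the unrooted tree: rerooting on any internal edge leaves it fixed."""
        import dendropy

        rng = np.random.default_rng(4200 + seed)
        tree = random_tree(rng, 8, polytomy_prob=0.0)
        states = random_states(rng, tree)
        model = cd.RateModel.er(float(rng.uniform(0.1, 1.0)))
        base = cd.log_likelihood(tree, cd.TipStates(states), model)

        dtree = dendropy.Tree.get(data=tree.to_newick(), schema="newick",
                                  preserve_underscores=True)
        edges = [e for e in dtree.preorder_edge_iter()
                 if e.head_node is not dtree.seed_node and e.length]
        pick = edges[int(rng.integers(len(edges)))]
        dtree.reroot_at_edge(pick, length1=pick.length / 2, length2=pick.length / 2,
                             update_bipartitions=False)
        rerooted = cd.parse_tree(dtree.as_string(schema="newick"))
        again = cd.log_likelihood(rerooted, cd.TipStates(states), model)
        assert again == pytest.approx(base, abs=1e-10)

    def test_deep_tree_does_not_underflow(self):
        tree = cd.yule_tree(300, seed=9)
        states = cd.simulate_tips(tree, cd.RateModel.er(0.5), 1, seed=1).replicate(0)
        lnl = cd.log_likelihood(tree, states, cd.RateModel.er(0.5))
        assert math.isfinite(lnl) and lnl < 0


class TestFit:
    def test_matches_reference_ml_fit(self):
        """Frozen reference: ape::ace on this exact 12-tip fixture gives
        rate 0.1545907 and lnL -3.560398 (their root convention)."""
        newick = (
            "(t1:1.023590444926548,(((((t2:0.11293259401737443,t3:0.11293259401737443)"
            ":0.3258551696150257,(t4:0.24661416419370052,t5:0.24661416419370052)"
            ":0.1921735994386996):0.2712374039383658,(((t6:0.3482361842826459,"
            "t7:0.3482361842826459):0.3160585855781294,(t8:0.5267604511323454,"
            "t9:0.5267604511323454):0.13753431872842992):0.03144902565745977,"
            "t10:0.6957437955182351):0.014281372052530883):0.02914609348401742,"
            "t11:0.7391712610547834):0.01526567995060979,t12:0.7544369410053932)"
            ":0.269153503921155);"
        )
        tree = cd.parse_tree(newick)
        states = cd.TipStates({f"t{i}": 1 for i in range(1, 13)} | {"t8": 0})
        f = cd.fit(tree, states, "ER", root_prior="unweighted")
        assert f.model.q01 == pytest.approx(0.1545907, abs=1e-5)
        assert f.log_lik == pytest.approx(-3.560398, abs=1e-5)

    def test_all_same_state_hits_lower_boundary(self, rng):
        tree = cd.yule_tree(20, seed=5)
        states = cd.TipStates({lab: 0 for lab in tree.leaf_labels})
        f = cd.fit(tree, states, "ER")
        assert f.at_boundary
        assert f.model.q01 <= 1e-6
        assert f.standard_errors is None

    def test_er_nested_in_ard(self, rng):
        for seed in range(5):
            tree = cd.yule_tree(40, seed=seed)
            states = cd.simulate_tips(tree, cd.RateModel.er(0.3), 1, seed=seed).replicate(0)
            fer = cd.fit(tree, states, "ER")
            fard = cd.fit(tree, states, "ARD")
            assert fer.log_lik <= fard.log_lik + 1e-6

    def test_missing_states_require_drop(self, three_leaf):
        with pytest.raises(ValidationError, match="unknown"):
            cd.fit(three_leaf, cd.TipStates({"A": 0, "B": 1, "C": None}), "ER")

    def test_se_positive_at_interior_optimum(self):
        tree = cd.yule_tree(60, seed=2)
        states = cd.simulate_tips(tree, cd.RateModel.er(0.4), 1, seed=2).replicate(0)
        f = cd.fit(tree, states, "ER")
        assert f.converged
        assert not f.at_boundary
        assert f.standard_errors is not None and f.standard_errors[0] > 0


class TestGarbage:
    def test_even_split_closed_form(self):
        states = cd.TipStates({f"x{i}": int(i < 5) for i in range(10)})
        g = cd.garbage_fit(states)
        assert g.p_hat == pytest.approx(0.5)
        assert g.log_lik == pytest.approx(10 * math.log(0.5), abs=1e-12)

    def test_degenerate_all_present(self):
        g = cd.garbage_fit(cd.TipStates({"a": 1, "b": 1, "c": 1}))
        assert g.p_hat == 1.0
        assert g.log_lik == 0.0

    def test_all_missing_rejected(self):
        with pytest.raises(ValidationError):
            cd.garbage_fit(cd.TipStates({"a": None}))

    @pytest.mark.parametrize("n1,n0", [(3, 7), (1, 1), (68, 0), (32, 37)])
    def test_matches_bernoulli_formula(self, n1, n0):
        states = cd.TipStates(
            {f"p{i}": 1 for i in range(n1)} | {f"a{i}": 0 for i in range(n0)}
        )
        g = cd.garbage_fit(states)
        p = n1 / (n1 + n0)
        expect = (n1 * math.log(p) if n1 else 0.0) + (n0 * math.log(1 - p) if n0 else 0.0)
        assert g.log_lik == pytest.approx(expect, abs=1e-12)


class TestCompareModels:
    def _mkfit(self, family, lnl):
        model = cd.RateModel.er(0.1) if family == "ER" else cd.RateModel.ard(0.1, 0.2)
        return mk.MkFit(model=model, log_lik=lnl, standard_errors=None,
                        root_prior="flat", converged=True, at_boundary=False, n_tips=10)

    def test_reported_study_likelihoods_give_their_p(self):
        """With lnLs -35.1983 (ER) vs -34.96077 (ARD): 2*dlnL = 0.47506, p ~ 0.4907."""
        c = cd.compare_models(self._mkfit("ER", -35.1983), self._mkfit("ARD", -34.96077))
        assert c.statistic == pytest.approx(0.47506, abs=1e-5)
        assert c.df == 1
        assert c.p_value == pytest.approx(0.490672, abs=1e-4)

    def test_identical_likelihoods(self):
        c = cd.compare_models(self._mkfit("ER", -10.0), self._mkfit("ARD", -10.0))
        assert c.statistic == 0.0
        assert c.p_value == 1.0

    def test_chi_square_quantile(self):
        c = cd.compare_models(self._mkfit("ER", -10.0), self._mkfit("ARD", -10.0 + 3.8415 / 2))
        assert c.p_value == pytest.approx(0.05, abs=1e-4)

    def test_tiny_negative_clamped(self):
        with pytest.warns(RuntimeWarning):
            c = cd.compare_models(self._mkfit("ER", -10.0), self._mkfit("ARD", -10.0 - 1e-8))
        assert c.statistic == 0.0

    def test_large_negative_raises(self):
        with pytest.raises(NumericalError):
            cd.compare_models(self._mkfit("ER", -10.0), self._mkfit("ARD", -11.0))

    def test_non_nested_rejected(self):
        with pytest.raises(ValidationError):
            cd.compare_models(self._mkfit("ARD", -10.0), self._mkfit("ER", -9.0))
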
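"""F81 transition kernel, pruning likelihood, marginal posteriors, MPPA."""

import numpy as np
import pytest

from slocus_evo.ancestral_states import (
    DEFAULT_TRAIT_STATES,
    F81Params,
    TraitAlphabet,
    TraitTree,
    f81_matrix,
    f81_transition,
    fit_and_reconstruct,
    marginal_posteriors,
    select_states_mppa,
    tree_log_likelihood,
)
from slocus_evo.synthetic_data import gen_trait_history, random_coalescent_tree

from _oracles import brute_force_likelihood_and_posteriors


def params_for(K, rng, rate=None):
    pi = rng.dirichlet(np.ones(K))
    return F81Params(pi=pi, rate=rate or float(rng.uniform(0.2, 2.0)))


def random_trait_tree(rng, n_tips, K, missing_frac=0.0, height=2.0):
    alpha = TraitAlphabet(tuple(f"s{i}" for i in range(K)))
    tree = random_coalescent_tree(n_tips, seed=int(rng.integers(2**31)),
                                  height=height)
    tips = {
        f"t{i + 1}": (
            None
            if rng.random() < missing_frac
            else alpha.states[int(rng.integers(K))]
        )
        for i in range(n_tips)
    }
    return TraitTree(tree, tips, alpha)


class TestTransitionKernel:
    def test_zero_branch_is_identity(self):
        params = F81Params(pi=np.array([0.3, 0.3, 0.4]), rate=1.0)
        assert np.allclose(f81_matrix(0.0, params), np.eye(3))

    def test_long_branch_reaches_stationarity(self):
        params = F81Params(pi=np.array([0.1, 0.2, 0.7]), rate=1.0)
        t = 50.0 / params.mu
        P = f81_matrix(t, params)
        assert np.allclose(P, np.tile(params.pi, (3, 1)), atol=1e-12)

    def test_rows_sum_to_one_and_chapman_kolmogorov(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            params = params_for(int(rng.integers(2, 9)), rng)
            t1, t2 = rng.uniform(0, 3, size=2)
            P1, P2 = f81_matrix(t1, params), f81_matrix(t2, params)
            assert np.allclose(P1.sum(axis=1), 1.0, atol=1e-12)
            assert np.allclose(P1 @ P2, f81_matrix(t1 + t2, params),
                               atol=1e-12)

    def test_two_state_symmetric_closed_form(self):
        # K=2 with pi=(1/2,1/2): mu=2, so the on-diagonal entry is
        # exp(-2*rho*t)/2 + 1/2, the binary symmetric chain
        params = F81Params(pi=np.array([0.5, 0.5]), rate=0.7)
        for t in (0.1, 1.0, 3.0):
            expected = 0.5 * np.exp(-2 * 0.7 * t) + 0.5
            assert f81_transition(0, 0, t, params) == pytest.approx(expected)

    def test_negative_branch_rejected(self):
        params = F81Params(pi=np.array([0.5, 0.5]), rate=1.0)
        with pytest.raises(ValueError):
            f81_matrix(-0.1, params)


class TestLikelihood:
    def test_two_tip_zero_branch_likelihood(self):
        # both ends of a zero-length cherry observed in the same state:
        # the data reduce to one draw from pi
        tt = TraitTree.from_newick(
            "(a:0.0,b:0.0);", {"a": "s0", "b": "s0"},
            TraitAlphabet(("s0", "s1")),
        )
        params = F81Params(pi=np.array([0.3, 0.7]), rate=1.0)
        assert tree_log_likelihood(tt, params) == pytest.approx(np.log(0.3))

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            K = int(rng.integers(2, 9))
            tt = random_trait_tree(rng, int(rng.integers(3, 7)), K)
            params = params_for(K, rng)
            ll = tree_log_likelihood(tt, params)
            bll, _ = brute_force_likelihood_and_posteriors(tt, params)
            assert ll == pytest.approx(bll, rel=1e-10)

    def test_invariant_to_child_order(self):
        params = F81Params(pi=np.array([0.25, 0.75]), rate=0.5)
        tips = {"a": "s0", "b": "s1", "c": "s0"}
        alpha = TraitAlphabet(("s0", "s1"))
        t1 = TraitTree.from_newick("((a:1,b:2):1,c:3);", tips, alpha)
        t2 = TraitTree.from_newick("(c:3,(b:2,a:1):1);", tips, alpha)
        assert tree_log_likelihood(t1, params) == pytest.approx(
            tree_log_likelihood(t2, params), rel=1e-12
        )

    def test_multifurcation_handled(self):
        tt = TraitTree.from_newick(
            "(a:1,b:1,c:1,d:1);",
            {"a": "s0", "b": "s0", "c": "s1", "d": "s0"},
            TraitAlphabet(("s0", "s1")),
        )
        params = F81Params(pi=np.array([0.5, 0.5]), rate=1.0)
        ll = tree_log_likelihood(tt, params)
        bll, _ = brute_force_likelihood_and_posteriors(tt, params)
        assert ll == pytest.approx(bll, rel=1e-10)


class TestPosteriors:
    def test_matches_enumeration_oracle_with_missing_tips(self):
        rng = np.random.default_rng(7)
        for _ in range(15):
            K = int(rng.integers(2, 9))
            tt = random_trait_tree(rng, int(rng.integers(3, 7)), K,
                                   missing_frac=0.25)
            params = params_for(K, rng)
            posts = marginal_posteriors(tt, params)
            _, oracle = brute_force_likelihood_and_posteriors(tt, params)
            for label, expected in oracle.items():
                assert np.allclose(posts[label], expected, atol=1e-10)

    def test_posteriors_are_distributions_and_tips_point_masses(self):
        rng = np.random.default_rng(3)
        tt = random_trait_tree(rng, 6, 4)
        params = params_for(4, rng)
        posts = marginal_posteriors(tt, params)
        for v in posts.values():
            assert v.sum() == pytest.approx(1.0)
            assert (v >= 0).all()
        for tip, state in tt.tip_states.items():
            assert posts[tip][tt.alphabet.index(state)] == pytest.approx(1.0)

    def test_concordant_tips_pull_root_above_prior(self):
        alpha = TraitAlphabet(("A", "B"))
        tt = TraitTree.from_newick("(a:1,b:1);", {"a": "A", "b": "A"}, alpha)
        params = F81Params(pi=np.array([0.3, 0.7]), rate=0.5)
        posts = marginal_posteriors(tt, params)
        assert posts["N1"][0] > 0.3
        assert np.argmax(posts["N1"]) == 0

    def test_identical_tips_short_branches_reconstruct_that_state(self):
        alpha = TraitAlphabet(("A", "B", "C"))
        tt = TraitTree.from_newick(
            "((a:0.01,b:0.01):0.01,(c:0.01,d:0.01):0.01);",
            {x: "B" for x in "abcd"}, alpha,
        )
        params = F81Params(pi=np.array([0.4, 0.3, 0.3]), rate=1.0)
        posts = marginal_posteriors(tt, params)
        for label in ("N1", "N2", "N3"):
            assert alpha.states[np.argmax(posts[label])] == "B"


class TestFitAndReconstruct:
    def test_observed_pi_with_pseudocount(self):
        alpha = TraitAlphabet(("A", "B"))
        newick = "((a:1,b:1):1,(c:1,d:1):1,(e:1,f:1):1,(g:1,h:1):1);"
        tips = dict(zip("abcdefgh", "AABBABAB"))
        tt = TraitTree.from_newick(newick, tips, alpha)
        res = fit_and_reconstruct(tt, pi_mode="observed")
        # 4 A + 4 B with pseudocount 1 each -> exactly (0.5, 0.5)
        assert np.allclose(res.params.pi, [0.5, 0.5])

    def test_all_identical_tips_warns_and_floors_rate(self):
        alpha = TraitAlphabet(("A", "B"))
        tt = TraitTree.from_newick("(a:1,(b:1,c:1):1);",
                                   {"a": "A", "b": "A", "c": "A"}, alpha)
        with pytest.warns(UserWarning, match="unidentifiable"):
            res = fit_and_reconstruct(tt)
        assert res.rate_at_bound

    def test_near_zero_rate_posteriors_approach_prior(self):
        alpha = TraitAlphabet(("A", "B"))
        tt = TraitTree.from_newick("((a:1,b:1):1,c:2);",
                                   {"a": "A", "b": "B", "c": "B"}, alpha)
        pi = np.array([0.6, 0.4])
        posts = marginal_posteriors(tt, F81Params(pi=pi, rate=1e-8))
        # with effectively no substitution the tree demands one shared
        # state: the root posterior collapses onto the tip consensus
        # weighting, which for conflicting tips is 0/0-free but finite
        for label in ("N1", "N2"):
            assert posts[label].sum() == pytest.approx(1.0)

    def test_parameter_recovery_on_simulated_history(self):
        alpha = TraitAlphabet(("A", "B", "C"))
        pi_true = np.array([0.5, 0.3, 0.2])
        params_true = F81Params(pi=pi_true, rate=0.02)
        tree = random_coalescent_tree(50, seed=11, height=100.0)
        skeleton = TraitTree(tree, {f"t{i+1}": None for i in range(50)}, alpha)
        tips, internal = gen_trait_history(skeleton, params_true, seed=5)
        tt = TraitTree(random_coalescent_tree(50, seed=11, height=100.0),
                       tips, alpha)
        res = fit_and_reconstruct(tt)
        assert np.abs(res.params.pi - pi_true).max() < 0.25
        acc = np.mean(
            [res.map_states[k] == v for k, v in internal.items()]
        )
        assert acc > 1.0 / 3  # beats random guessing comfortably


class TestMPPA:
    def test_threshold_rule(self):
        alpha = TraitAlphabet(("A", "B", "C"))
        posts = {
            "n1": np.array([0.9, 0.05, 0.05]),
            "n2": np.array([0.5, 0.45, 0.05]),
            "n3": np.array([1 / 3, 1 / 3, 1 / 3]),
        }
        sel = select_states_mppa(posts, alpha)
        assert sel["n1"] == ["A"]
        assert sel["n2"] == ["A", "B"]
        assert sel["n3"] == ["A", "B", "C"]

    def test_map_always_included(self):
        alpha = TraitAlphabet(("A", "B"))
        sel = select_states_mppa({"x": np.array([0.01, 0.99])}, alpha,
                                 threshold_fraction=1.0)
        assert sel["x"] == ["B"]


def test_default_alphabet_has_eight_si_traits():
    assert len(DEFAULT_TRAIT_STATES) == 8
    assert TraitAlphabet().size == 8
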
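"""Pruning likelihood: closed forms, oracle agreement, caching, invariances."""

import math

import numpy as np
import pytest

from gestaltree import (
    Alignment,
    Allele,
    TargetStatus,
    TreeLikelihood,
    UNEDITED,
    ancestral_state_sets,
    branch_transition_log_probability,
    brute_force_log_likelihood,
    total_status_hazard,
    tree_log_likelihood,
)
from gestaltree.editing import TargetTract, indel_for_detail
from gestaltree.likelihood import NodeState, StateSpaceError
from gestaltree.simulate import simulate_alignment, simulate_pure_birth_n_tips

from conftest import cherry_tree, three_leaf_tree, make_params


@pytest.fixture(scope="module")
def indels3(design3):
    return {
        "focal1": indel_for_detail(TargetTract(1, 1, 1, 1), design3, 1, 1, ""),
        "focal2": indel_for_detail(TargetTract(2, 2, 2, 2), design3, 1, 0, "A"),
        "big13": indel_for_detail(TargetTract(1, 1, 3, 3), design3, 1, 1, ""),
        "long2": indel_for_detail(TargetTract(1, 2, 2, 2), design3, 2, 1, ""),
    }


class TestBranchTransition:
    def test_unedited_survival_closed_form(self, design3, params3):
        h = total_status_hazard(TargetStatus.all_active(3), design3, params3)
        t, r = 0.9, params3.clock_rate
        lp = branch_transition_log_probability(UNEDITED, UNEDITED, t, r,
                                               params3, design3)
        assert lp == pytest.approx(-h * r * t, rel=1e-12)

    def test_zero_branch_identity(self, design3, params3):
        lp = branch_transition_log_probability(UNEDITED, UNEDITED, 0.0, 1.0,
                                               params3, design3)
        assert lp == 0.0

    def test_incompatible_returns_neg_inf(self, design3, params3, indels3):
        a = Allele((indels3["focal1"],))
        lp = branch_transition_log_probability(a, UNEDITED, 1.0, 1.0,
                                               params3, design3)
        assert lp == -math.inf

    def test_matches_oracle_on_single_branch(self, design3, params3, space3,
                                             indels3):
        """P(unedited -> one focal indel) against the full allele chain."""
        from scipy.sparse.linalg import expm_multiply
        t = 0.8
        Q = space3.generator(params3)
        v = np.zeros(len(space3.alleles))
        v[0] = 1.0
        probs = expm_multiply(Q.T * (params3.clock_rate * t), v)
        b = Allele((indels3["focal1"],))
        lp = branch_transition_log_probability(UNEDITED, b, t,
                                               params3.clock_rate,
                                               params3, design3)
        assert lp == pytest.approx(math.log(probs[space3.index[b]]), abs=1e-9)


class TestAncestralStates:
    def test_all_unedited(self, design3, params3):
        tree = three_leaf_tree()
        aln = Alignment(design=design3,
                        cells=[(lab, UNEDITED) for lab in "abc"])
        states = ancestral_state_sets(tree, aln)
        for node in tree.postorder():
            if not node.is_leaf and node is not tree.root:
                assert NodeState(allele=UNEDITED) in states[id(node)]

    def test_shared_indel_candidate(self, design3, indels3):
        tree = three_leaf_tree()
        d = indels3["focal1"]
        aln = Alignment(design=design3, cells=[
            ("a", Allele((d,))), ("b", Allele((d,))), ("c", UNEDITED)])
        states = ancestral_state_sets(tree, aln)
        anc = next(n for n in tree.internal_nodes() if n is not tree.root)
        alleles = {s.allele for s in states[id(anc)]}
        assert UNEDITED in alleles and Allele((d,)) in alleles

    def test_masked_indel_is_candidate(self, design3, indels3):
        """A focal indel strictly inside the sibling leaf's long deletion
        remains an ancestral candidate (it may have been masked)."""
        tree = three_leaf_tree()
        aln = Alignment(design=design3, cells=[
            ("a", Allele((indels3["big13"],))),
            ("b", Allele((indels3["focal2"],))),
            ("c", UNEDITED)])
        states = ancestral_state_sets(tree, aln)
        anc = next(n for n in tree.internal_nodes() if n is not tree.root)
        assert Allele((indels3["focal2"],)) in {s.allele for s in states[id(anc)]}

    def test_max_states_cap_raises(self, design3, indels3):
        tree = three_leaf_tree()
        aln = Alignment(design=design3, cells=[
            ("a", Allele((indels3["focal1"], indels3["focal2"]))),
            ("b", Allele((indels3["focal1"], indels3["focal2"]))),
            ("c", UNEDITED)])
        with pytest.raises(StateSpaceError, match="max_states"):
            ancestral_state_sets(tree, aln, max_states=1)


class TestTreeLikelihood:
    def test_all_unedited_zero_branches(self, design3, params3):
        tree = cherry_tree(t=0.0)
        aln = Alignment(design=design3, cells=[("a", UNEDITED), ("b", UNEDITED)])
        assert tree_log_likelihood(tree, aln, params3) == 0.0

    def test_oracle_agreement_masking(self, design3, params3, space3, indels3):
        tree = three_leaf_tree()
        aln = Alignment(design=design3, cells=[
            ("a", Allele((indels3["big13"],))),
            ("b", Allele((indels3["big13"],))),
            ("c", Allele((indels3["focal2"],)))])
        lp = tree_log_likelihood(tree, aln, params3)
        lo = brute_force_log_likelihood(tree, aln, params3, design3, space=space3)
        assert lp == pytest.approx(lo, abs=1e-6)

    def test_rt_invariance(self, design3, params3, indels3):
        """Doubling the clock with halved branch lengths leaves the
        likelihood unchanged."""
        from dataclasses import replace
        aln = Alignment(design=design3, cells=[
            ("a", Allele((indels3["focal1"],))), ("b", UNEDITED)])
        lp1 = tree_log_likelihood(cherry_tree(t=0.6), aln, params3)
        doubled = replace(params3, clock_rate=2 * params3.clock_rate)
        lp2 = tree_log_likelihood(cherry_tree(t=0.3), aln, doubled)
        assert lp1 == pytest.approx(lp2, rel=1e-12)

    def test_leaf_order_invariance(self, design3, params3, indels3):
        a = Allele((indels3["focal1"],))
        aln1 = Alignment(design=design3, cells=[("a", a), ("b", UNEDITED)])
        aln2 = Alignment(design=design3, cells=[("b", UNEDITED), ("a", a)])
        tree = cherry_tree()
        assert tree_log_likelihood(tree, aln1, params3) == pytest.approx(
            tree_log_likelihood(tree, aln2, params3), rel=1e-12)

    def test_cached_equals_fresh_along_move_sequence(self, design3, params3):
        """Incremental (cached) evaluation tracks from-scratch recomputation
        through a random sequence of node-time changes."""
        rng = np.random.default_rng(4)
        tree = simulate_pure_birth_n_tips(5, birth_rate=1.5, seed=9)
        aln = simulate_alignment(tree, design3, params3, seed=10)
        like = TreeLikelihood(tree, aln, params3)
        for _ in range(10):
            internal = [n for n in tree.internal_nodes() if n is not tree.root]
            node = internal[int(rng.integers(len(internal)))]
            lo = node.parent.time
            hi = min(c.time for c in node.children)
            node.time = float(rng.uniform(lo, hi))
            cached = like.log_likelihood()
            fresh = tree_log_likelihood(tree, aln, params3)
            assert cached == pytest.approx(fresh, abs=1e-9)

    def test_label_mismatch_raises(self, design3, params3):
        tree = cherry_tree(labels=("a", "zzz"))
        aln = Alignment(design=design3, cells=[("a", UNEDITED), ("b", UNEDITED)])
        with pytest.raises(KeyError):
            tree_log_likelihood(tree, aln, params3)


class TestOracleBattery:
    """Randomized pruning-vs-enumeration agreement on simulated instances."""

    def test_random_instances_match_oracle(self, design2, params2, space2, rng):
        n_checked = 0
        for i in range(8):
            lam = rng.uniform(0.5, 1.5, 2)
            params = make_params(2, cut_rates=tuple(lam),
                                 double_cut_weight=float(rng.uniform(0.1, 0.8)),
                                 long_trim_left=float(rng.uniform(0.0, 0.6)),
                                 long_trim_right=float(rng.uniform(0.0, 0.6)),
                                 clock_rate=float(rng.uniform(0.3, 1.5)))
            tree = simulate_pure_birth_n_tips(int(rng.integers(2, 5)),
                                              birth_rate=2.0, seed=rng)
            aln = simulate_alignment(tree, design2, params, seed=rng)
            lp = tree_log_likelihood(tree, aln, params)
            lo = brute_force_log_likelihood(tree, aln, params, design2,
                                            space=space2)
            assert lp == pytest.approx(lo, abs=1e-6)
            n_checked += 1
        assert n_checked == 8
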
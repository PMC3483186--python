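"""Constrained minimum-transition counting vs brute force and Fitch."""

import numpy as np
import pytest

from sciophylo.counting import (
    clade_origin_count,
    constraints_from_asr,
    min_transitions,
)
from sciophylo.mk import MkModel, fit_mk1, marginal_asr
from sciophylo.trees import read_newick

from .oracles import (
    brute_completions,
    brute_pair_counts,
    fitch_length,
    random_bifurcating_newick,
)


def _random_constrained_instance(seed, max_tips=8, k_choices=(2, 3)):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, max_tips + 1))
    tree = read_newick(random_bifurcating_newick(rng, n))
    k = int(rng.choice(k_choices))
    alphabet = tuple(str(i) for i in range(k))
    constraints = {}
    for i in range(tree.n_nodes):
        if tree.nodes[i].is_tip:
            constraints[i] = frozenset({alphabet[rng.integers(k)]})
        else:
            # random nonempty allowed set: singleton, pair, or full
            size = int(rng.integers(1, k + 1))
            chosen = rng.choice(k, size=size, replace=False)
            constraints[i] = frozenset(alphabet[j] for j in chosen)
    return tree, constraints, alphabet, rng


class TestMinTransitions:
    def test_monomorphic_zero_changes(self):
        t = read_newick("((a:1,b:1):1,(c:1,d:1):1);")
        cons = {i: frozenset({"x"}) if t.nodes[i].is_tip
                else frozenset({"x", "y"}) for i in range(t.n_nodes)}
        tc = min_transitions(t, cons, ("x", "y"))
        assert tc.total_changes == 0 and not tc.pair_counts

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_brute_force(self, seed):
        tree, constraints, alphabet, rng = _random_constrained_instance(seed)
        tc = min_transitions(tree, constraints, alphabet)
        best, optima = brute_completions(tree, constraints, alphabet)
        assert tc.total_changes == best
        # per-pair brackets over all optimal completions
        for (a, b) in tc.pair_min:
            lo, hi = brute_pair_counts(tree, optima, alphabet, a, b)
            assert tc.pair_min[(a, b)] == lo
            assert tc.pair_max[(a, b)] == hi

    def test_representative_counts_sum_to_total(self):
        for seed in range(10):
            tree, constraints, alphabet, _ = _random_constrained_instance(
                seed + 500
            )
            tc = min_transitions(tree, constraints, alphabet)
            assert sum(tc.pair_counts.values()) == tc.total_changes

    def test_unconstrained_equals_fitch(self):
        """With free internal nodes the DP reduces to parsimony length."""
        for seed in range(15):
            rng = np.random.default_rng(900 + seed)
            tree = read_newick(random_bifurcating_newick(rng, 12))
            k = int(rng.choice((2, 3, 4)))
            alphabet = tuple(str(i) for i in range(k))
            tips = {lab: alphabet[rng.integers(k)]
                    for lab in tree.tip_labels}
            cons = {}
            for i in range(tree.n_nodes):
                if tree.nodes[i].is_tip:
                    cons[i] = frozenset({tips[tree.nodes[i].label]})
                else:
                    cons[i] = frozenset(alphabet)
            tc = min_transitions(tree, cons, alphabet)
            assert tc.total_changes == fitch_length(tree, tips)

    def test_adding_constraints_is_monotone(self):
        for seed in range(10):
            tree, constraints, alphabet, rng = _random_constrained_instance(
                seed + 700, max_tips=7
            )
            free = {
                i: (constraints[i] if tree.nodes[i].is_tip
                    else frozenset(alphabet))
                for i in range(tree.n_nodes)
            }
            loose = min_transitions(tree, free, alphabet).total_changes
            tight = min_transitions(tree, constraints, alphabet).total_changes
            assert tight >= loose

    def test_scope_restricts_counts(self):
        t = read_newick("(((a:1,b:1):1,c:1):1,d:1);")
        cons = {}
        states = {"a": "x", "b": "x", "c": "y", "d": "y"}
        for i in range(t.n_nodes):
            nd = t.nodes[i]
            cons[i] = (frozenset({states[nd.label]}) if nd.is_tip
                       else frozenset({"x", "y"}))
        clade = t.mrca(["a", "b"])
        scoped = min_transitions(t, cons, ("x", "y"), scope=clade)
        full = min_transitions(t, cons, ("x", "y"))
        assert scoped.total_changes <= full.total_changes


class TestCladeOriginCount:
    def test_monomorphic_clade(self):
        t = read_newick("(((a:1,b:1):1,c:1):1,d:1);")
        clade = t.mrca(["a", "b"])
        states = {"a": "x", "b": "x", "c": "y", "d": "y"}
        cons = {
            i: (frozenset({states[t.nodes[i].label]})
                if t.nodes[i].is_tip else frozenset({"x", "y"}))
            for i in range(t.n_nodes)
        }
        # parent of the clade optimally 'y': one origin of x on the stem
        assert clade_origin_count(t, cons, ("x", "y"), "x", clade) == 1
        # clade state matching its surroundings: zero origins
        assert clade_origin_count(t, cons, ("x", "y"), "y", clade) == 0

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force(self, seed):
        tree, constraints, alphabet, rng = _random_constrained_instance(
            1300 + seed, max_tips=8
        )
        clade = int(rng.choice(tree.internal_indices))
        target = alphabet[int(rng.integers(len(alphabet)))]
        got = clade_origin_count(tree, constraints, alphabet, target, clade)
        best, optima = brute_completions(tree, constraints, alphabet)
        scope = tree.clade_nodes(clade)
        t_idx = alphabet.index(target)
        origins = []
        for assign in optima:
            c = 0
            for i in range(tree.n_nodes):
                p = tree.nodes[i].parent
                if p is None or i not in scope:
                    continue
                if assign[i] == t_idx and assign[p] != t_idx:
                    c += 1
            origins.append(c)
        assert got == min(origins)

    def test_unknown_clade_root_rejected(self):
        t = read_newick("(a:1,b:1);")
        cons = {i: frozenset({"x"}) for i in range(t.n_nodes)}
        with pytest.raises(ValueError, match="clade"):
            clade_origin_count(t, cons, ("x", "y"), "x", 99)


class TestConstraintsFromAsr:
    def test_tip_and_node_mapping(self):
        t = read_newick("((a:1,b:1):1,(c:1,d:1):1);")
        states = {"a": "0", "b": "0", "c": "1", "d": "?"}
        model, _ = fit_mk1(t, states, k=2, alphabet=("0", "1"))
        asr = marginal_asr(t, states, model, ("0", "1"))
        cons = constraints_from_asr(t, asr, states)
        for i in t.tip_indices:
            lab = t.nodes[i].label
            if states[lab] == "?":
                assert cons[i] == frozenset({"0", "1"})
            else:
                assert cons[i] == frozenset({states[lab]})
        for i in t.internal_indices:
            assert cons[i] == frozenset(asr.significant_sets[i])

    def test_dec_widespread_policy(self):
        from sciophylo.dec import DecParams, dec_node_estimates

        t = read_newick("((a:1,b:1):1,c:1);")
        tips = {"a": "A", "b": "AT", "c": "T"}
        est = dec_node_estimates(t, tips, DecParams(d=0.3, e=0.2))
        cons = constraints_from_asr(
            t, est, tips, alphabet=("A", "T"), widespread_policy="either"
        )
        b_idx = [i for i in t.tip_indices if t.nodes[i].label == "b"][0]
        assert cons[b_idx] == frozenset({"A", "T"})
        for i in t.internal_indices:
            assert cons[i] <= frozenset({"A", "T"})
            assert cons[i]
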
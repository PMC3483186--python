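"""Independent brute-force oracles used by the test suite.

These deliberately avoid the pruning/DP recursions of the package: they
enumerate global state assignments (and, for DEC, use explicit matrix
exponentials of the generator), so agreement with the package is a real
two-route check.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.linalg import expm

from sciophylo.dec import _SCENARIOS, DecParams, RANGES
from sciophylo.mk import MkModel, transition_probabilities


def mk_enum_loglik(tree, tip_states, model, alphabet, clamp=None):
    """Exhaustive sum over all interior-node state assignments."""
    k = model.k
    bl = tree.branch_lengths()
    P = {
        i: transition_probabilities(model, bl[i])
        for i in range(tree.n_nodes)
        if i != tree.root
    }
    idx = {s: j for j, s in enumerate(alphabet)}
    internals = tree.internal_indices
    prior = model.prior()
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internals)):
        st = dict(zip(internals, assign))
        if clamp is not None and st[clamp[0]] != clamp[1]:
            continue
        p = prior[st[tree.root]]
        ok = True
        for i in range(tree.n_nodes):
            if i == tree.root:
                continue
            parent = st[tree.nodes[i].parent]
            if tree.nodes[i].is_tip:
                obs = tip_states[tree.nodes[i].label]
                if obs == "?":
                    contrib = 1.0  # sum over child states = row sum = 1
                else:
                    contrib = P[i][parent, idx[obs]]
            else:
                contrib = P[i][parent, st[i]]
            p *= contrib
            if p == 0:
                ok = False
                break
        if ok:
            total += p
    return np.log(total)


def dec_enum_loglik(tree, tip_ranges, params: DecParams):
    """Exhaustive sum over pre-split range assignments.

    For a fixed assignment the cladogenetic scenario sum at each node
    factorizes over nodes, so only the 3^n_internal assignments need
    enumerating; anagenetic factors come from scipy's expm directly.
    """
    Q = params.generator()
    bl = tree.branch_lengths()
    P = {
        i: expm(Q * bl[i]) for i in range(tree.n_nodes) if i != tree.root
    }
    obs = {
        i: RANGES.index(tip_ranges[tree.nodes[i].label])
        for i in tree.tip_indices
    }
    internals = tree.internal_indices
    total = 0.0
    for assign in itertools.product(range(3), repeat=len(internals)):
        st = dict(zip(internals, assign))
        p = 1.0 / 3.0  # uniform root prior over live ranges
        for i in internals:
            c1, c2 = tree.nodes[i].children
            e1 = st[c1] if c1 in st else obs[c1]
            e2 = st[c2] if c2 in st else obs[c2]
            s = sum(
                w * P[c1][a, e1] * P[c2][b, e2]
                for a, b, w in _SCENARIOS[st[i]]
            )
            p *= s
            if p == 0:
                break
        total += p
    return np.log(total) if total > 0 else -np.inf


def dec_enum_clamped(tree, tip_ranges, params, node, state):
    """Enumeration oracle with one internal node's pre-split range fixed."""
    Q = params.generator()
    bl = tree.branch_lengths()
    P = {
        i: expm(Q * bl[i]) for i in range(tree.n_nodes) if i != tree.root
    }
    obs = {
        i: RANGES.index(tip_ranges[tree.nodes[i].label])
        for i in tree.tip_indices
    }
    internals = tree.internal_indices
    total = 0.0
    for assign in itertools.product(range(3), repeat=len(internals)):
        st = dict(zip(internals, assign))
        if st[node] != state:
            continue
        p = 1.0 / 3.0
        for i in internals:
            c1, c2 = tree.nodes[i].children
            e1 = st[c1] if c1 in st else obs[c1]
            e2 = st[c2] if c2 in st else obs[c2]
            p *= sum(
                w * P[c1][a, e1] * P[c2][b, e2]
                for a, b, w in _SCENARIOS[st[i]]
            )
            if p == 0:
                break
        total += p
    return np.log(total) if total > 0 else -np.inf


def brute_completions(tree, constraints, alphabet):
    """All minimum-change completions; yields (assignment, changes)."""
    order = list(range(tree.n_nodes))
    choices = [
        [alphabet.index(s) for s in sorted(constraints[i])] for i in order
    ]
    best = None
    optima = []
    for assign in itertools.product(*choices):
        changes = sum(
            1
            for i in order
            if tree.nodes[i].parent is not None
            and assign[i] != assign[tree.nodes[i].parent]
        )
        if best is None or changes < best:
            best = changes
            optima = [assign]
        elif changes == best:
            optima.append(assign)
    return best, optima


def brute_pair_counts(tree, optima, alphabet, a, b, scope_nodes=None):
    """(min, max) count of a->b branches over optimal completions."""
    ai, bi = alphabet.index(a), alphabet.index(b)
    counts = []
    for assign in optima:
        c = 0
        for i in range(tree.n_nodes):
            p = tree.nodes[i].parent
            if p is None:
                continue
            if scope_nodes is not None and i not in scope_nodes:
                continue
            if assign[p] == ai and assign[i] == bi:
                c += 1
        counts.append(c)
    return min(counts), max(counts)


def fitch_length(tree, tip_states):
    """Unweighted Fitch parsimony length (binary/multistate, no
    constraints); independent of the package's Sankoff DP."""
    sets = {}
    length = 0
    for i in tree.postorder():
        nd = tree.nodes[i]
        if nd.is_tip:
            sets[i] = {tip_states[nd.label]}
        else:
            acc = None
            for c in nd.children:
                if acc is None:
                    acc = sets[c]
                else:
                    inter = acc & sets[c]
                    if inter:
                        acc = inter
                    else:
                        acc = acc | sets[c]
                        length += 1
            sets[i] = acc
    return length


def random_bifurcating_newick(rng, n, min_bl=0.05, max_bl=2.0):
    subs = [f"t{i}" for i in range(n)]
    subs = [f"{s}:{rng.uniform(min_bl, max_bl):.4f}" for s in subs]
    while len(subs) > 1:
        i = rng.integers(len(subs))
        a = subs.pop(int(i))
        j = rng.integers(len(subs))
        b = subs.pop(int(j))
        subs.append(f"({a},{b}):{rng.uniform(min_bl, max_bl):.4f}")
    return subs[0] + ";"
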
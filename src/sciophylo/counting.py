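"""Constrained minimum-transition counting over reconstructed states.

Converts per-node significant-state sets into hard/soft node constraints
and counts, by Sankoff-style dynamic programming, the minimum number of
state changes any completion of the ambiguous nodes requires — the "at
least N independent transitions" semantics.  Because minimal completions
can disagree on *directed* counts, every directed pair is reported with
its minimum and maximum over all minimum-change completions (a second,
lexicographically-encoded DP pass), never a silent point value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .mk import MISSING, AsrResult
from .trees import Tree

__all__ = [
    "constraints_from_asr",
    "min_transitions",
    "clade_origin_count",
    "TransitionCount",
]


def constraints_from_asr(
    tree: Tree,
    result,
    tip_states: Mapping[str, str],
    alphabet: Sequence[str] | None = None,
    widespread_policy: str = "either",
) -> dict[int, frozenset[str]]:
    """Node index -> allowed state set.

    Tips get their observed state (full set when missing); internal nodes
    their significant-state set.  For DEC node estimates the widespread
    range ``AT`` maps, under the default ``"either"`` policy, to allowing
    either single habitat at that node (``"own_state"`` keeps ``AT`` as a
    state of its own).
    """
    if alphabet is None:
        alphabet = result.alphabet
    sets = dict(getattr(result, "significant_sets"))
    full = frozenset(alphabet)
    constraints: dict[int, frozenset[str]] = {}
    for i in tree.tip_indices:
        s = tip_states.get(tree.nodes[i].label, MISSING)
        if s == MISSING:
            constraints[i] = full
        elif s == "AT" and widespread_policy == "either":
            constraints[i] = frozenset({"A", "T"})
        else:
            constraints[i] = frozenset({s})
    for i in tree.internal_indices:
        allowed = set(sets[i])
        if widespread_policy == "either" and "AT" in allowed:
            allowed.discard("AT")
            allowed |= {"A", "T"}
        constraints[i] = frozenset(allowed) & (
            full | frozenset({"A", "T"})
        )
        if not constraints[i]:
            raise ValueError(f"empty constraint set at node {i}")
    return constraints


@dataclass
class TransitionCount:
    """Minimum-change summary under node constraints.

    ``total_changes`` — minimum number of changes on in-scope branches,
    over all globally minimum-change completions.  ``pair_counts`` — counts
    from one representative minimal completion; ``pair_min``/``pair_max``
    bracket each directed pair over all minimal completions.  ``tied`` is
    set when any pair's bracket is not a point.
    """

    total_changes: int
    pair_counts: dict[tuple[str, str], int]
    pair_min: dict[tuple[str, str], int]
    pair_max: dict[tuple[str, str], int]
    representative: dict[int, str]
    tied: bool

    def count(self, a: str, b: str) -> int:
        return self.pair_counts.get((a, b), 0)


def _scope_mask(tree: Tree, scope: int | None) -> np.ndarray:
    """Boolean per-node mask: branch above node counts toward totals."""
    mask = np.zeros(tree.n_nodes, dtype=bool)
    nodes = (
        tree.clade_nodes(scope) if scope is not None
        else set(range(tree.n_nodes))
    )
    for i in nodes:
        if tree.nodes[i].parent is not None:
            mask[i] = True
    return mask


def _sankoff(
    tree: Tree,
    allowed: dict[int, np.ndarray],
    branch_cost: "np.ndarray",
) -> np.ndarray:
    """Generic Sankoff pass.

    ``branch_cost[i]`` is the (k_parent, k_child) additive cost matrix of
    the branch above node i.  Returns the root cost vector (inf outside
    the root's allowed set).
    """
    INF = np.inf
    cost: dict[int, np.ndarray] = {}
    for i in tree.postorder():
        nd = tree.nodes[i]
        k = branch_cost[i].shape[0] if nd.parent is not None else None
        base = np.where(allowed[i], 0.0, INF)
        if not nd.is_tip:
            for c in nd.children:
                # child contribution for each state of i
                contrib = (branch_cost[c] + cost[c][None, :]).min(axis=1)
                base = base + contrib
        cost[i] = base
    return cost[tree.root]


def _prepare(tree, constraints, alphabet):
    k = len(alphabet)
    index = {s: j for j, s in enumerate(alphabet)}
    allowed = {}
    for i in range(tree.n_nodes):
        v = np.zeros(k, dtype=bool)
        for s in constraints[i]:
            v[index[s]] = True
        if not v.any():
            raise ValueError(f"empty constraint set at node {i}")
        allowed[i] = v
    return k, index, allowed


def min_transitions(
    tree: Tree,
    constraints: Mapping[int, frozenset],
    alphabet: Sequence[str],
    scope: int | None = None,
) -> TransitionCount:
    """Constrained minimum-change counting with per-pair brackets.

    ``scope`` restricts the *reported* counts to branches inside the clade
    rooted there (the clade root's own stem branch included); the set of
    minimal completions is always defined by the global minimum.
    """
    k, index, allowed = _prepare(tree, constraints, alphabet)
    mask = _scope_mask(tree, scope)
    change = (1.0 - np.eye(k))
    branch_cost = {
        i: change for i in range(tree.n_nodes) if tree.nodes[i].parent is not None
    }
    root_cost = _sankoff(tree, allowed, branch_cost)
    global_min = int(root_cost.min())

    # big-M encoding: primary = global changes, secondary = scoped quantity
    big = float(tree.n_nodes + 1)

    def scoped_extreme(indicator: np.ndarray, sign: float) -> int:
        bc = {
            i: change * big + (sign * indicator if mask[i] else 0.0)
            for i in branch_cost
        }
        val = _sankoff(tree, allowed, bc).min()
        return int(round(sign * (val - global_min * big)))

    any_change = change
    total_min = scoped_extreme(any_change, +1.0)

    # representative completion: deterministic backtrack of the encoded DP
    # that attains the scoped minimum (ties -> lowest state index)
    bc = {i: change * big + (any_change if mask[i] else 0.0)
          for i in branch_cost}
    cost: dict[int, np.ndarray] = {}
    for i in tree.postorder():
        nd = tree.nodes[i]
        base = np.where(allowed[i], 0.0, np.inf)
        for c in nd.children:
            base = base + (bc[c] + cost[c][None, :]).min(axis=1)
        cost[i] = base
    assign: dict[int, int] = {}
    order = tree.preorder()
    assign[tree.root] = int(np.argmin(cost[tree.root]))
    for i in order:
        if i == tree.root:
            continue
        p = assign[tree.nodes[i].parent]
        assign[i] = int(np.argmin(bc[i][p] + cost[i]))

    pair_counts: dict[tuple[str, str], int] = {}
    for i in range(tree.n_nodes):
        p = tree.nodes[i].parent
        if p is None or not mask[i]:
            continue
        a, b = assign[p], assign[i]
        if a != b:
            key = (alphabet[a], alphabet[b])
            pair_counts[key] = pair_counts.get(key, 0) + 1

    pair_min: dict[tuple[str, str], int] = {}
    pair_max: dict[tuple[str, str], int] = {}
    for a in range(k):
        for b in range(k):
            if a == b:
                continue
            ind = np.zeros((k, k))
            ind[a, b] = 1.0
            lo = scoped_extreme(ind, +1.0)
            hi = scoped_extreme(ind, -1.0)
            if hi > 0 or lo > 0 or (alphabet[a], alphabet[b]) in pair_counts:
                pair_min[(alphabet[a], alphabet[b])] = lo
                pair_max[(alphabet[a], alphabet[b])] = hi

    tied = any(pair_min[p] != pair_max[p] for p in pair_min)
    return TransitionCount(
        total_changes=total_min,
        pair_counts=pair_counts,
        pair_min=pair_min,
        pair_max=pair_max,
        representative={i: alphabet[s] for i, s in assign.items()},
        tied=tied,
    )


def clade_origin_count(
    tree: Tree,
    constraints: Mapping[int, frozenset],
    alphabet: Sequence[str],
    target_state: str,
    clade_root: int,
) -> int:
    """Minimum number of independent origins of ``target_state`` within a
    clade, over all globally minimum-change completions.

    An origin is a branch (clade root's stem included) whose parent state
    is not the target while the child state is.
    """
    if clade_root < 0 or clade_root >= tree.n_nodes:
        raise ValueError(f"unknown clade root {clade_root}")
    k, index, allowed = _prepare(tree, constraints, alphabet)
    if target_state not in index:
        raise ValueError(f"target state {target_state!r} not in alphabet")
    t = index[target_state]
    mask = _scope_mask(tree, clade_root)
    change = 1.0 - np.eye(k)
    branch_cost = {
        i: change
        for i in range(tree.n_nodes)
        if tree.nodes[i].parent is not None
    }
    global_min = _sankoff(tree, allowed, branch_cost).min()
    big = float(tree.n_nodes + 1)
    ind = np.zeros((k, k))
    ind[:, t] = 1.0
    ind[t, t] = 0.0
    bc = {
        i: change * big + (ind if mask[i] else 0.0) for i in branch_cost
    }
    val = _sankoff(tree, allowed, bc).min()
    return int(round(val - global_min * big))
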
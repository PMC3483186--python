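"""Mk-model likelihoods and marginal ancestral-state reconstruction.

Two continuous-time Markov models for a discrete character:

* **Mk1** — k states, one rate ``r``; all off-diagonal entries of the
  generator equal, so P(same) and P(change) have closed forms.
* **AsymmMk** — 2 states with distinct forward (``q01``) and backward
  (``q10``) rates; the natural model when transitions are suspected to be
  directionally biased (e.g. aquatic→terrestrial vs the reverse).

Ancestral states are scored marginally: for each internal node and state
``s``, the log-likelihood of the tip data with that node clamped to ``s``
(model parameters fixed at their MLEs).  States more than ``T`` (default
2) log-units below the node's best state are rejected; nodes whose
surviving set is a singleton are "solid".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import logsumexp

from .trees import Tree

__all__ = [
    "MkModel",
    "AsrResult",
    "transition_probabilities",
    "pruning_loglik",
    "fit_mk1",
    "fit_asymm",
    "marginal_asr",
    "drop_unknowns_rerun",
]

MISSING = "?"
LOG_RATE_BOUNDS = (np.log(1e-8), np.log(1e2))


@dataclass(frozen=True)
class MkModel:
    """Mk1 (``rate`` set) or asymmetric binary (``q01``/``q10`` set).

    ``root_prior``: ``"uniform"`` or ``"stationary"``.  For Mk1 the two
    coincide; for the asymmetric model the stationary law is
    ``(q10, q01) / (q01 + q10)``.
    """

    k: int
    rate: float | None = None
    q01: float | None = None
    q10: float | None = None
    root_prior: str = "uniform"

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k >= 2 required")
        if self.rate is not None:
            if self.rate <= 0:
                raise ValueError("rate must be > 0")
            if self.q01 is not None or self.q10 is not None:
                raise ValueError("give either rate or (q01, q10), not both")
        else:
            if self.q01 is None or self.q10 is None:
                raise ValueError("need rate (Mk1) or q01 and q10 (AsymmMk)")
            if self.k != 2:
                raise ValueError("asymmetric model is only defined for k=2")
            if self.q01 <= 0 or self.q10 <= 0:
                raise ValueError("rates must be > 0")
        if self.root_prior not in ("uniform", "stationary"):
            raise ValueError("root_prior must be 'uniform' or 'stationary'")

    @property
    def is_asymmetric(self) -> bool:
        return self.rate is None

    def prior(self) -> np.ndarray:
        if self.root_prior == "uniform" or not self.is_asymmetric:
            return np.full(self.k, 1.0 / self.k)
        s = self.q01 + self.q10
        return np.array([self.q10 / s, self.q01 / s])


def transition_probabilities(model: MkModel, t: float) -> np.ndarray:
    """k×k stochastic matrix P(t); closed forms, no matrix exponential."""
    if t < 0:
        raise ValueError("branch length must be >= 0")
    k = model.k
    if not model.is_asymmetric:
        e = np.exp(-k * model.rate * t)
        p_same = 1.0 / k + (k - 1) / k * e
        p_diff = (1.0 - e) / k
        P = np.full((k, k), p_diff)
        np.fill_diagonal(P, p_same)
        return P
    q01, q10 = model.q01, model.q10
    s = q01 + q10
    e = np.exp(-s * t)
    return np.array(
        [
            [(q10 + q01 * e) / s, q01 * (1 - e) / s],
            [q10 * (1 - e) / s, (q01 + q10 * e) / s],
        ]
    )


# ----------------------------------------------------------------- pruning

def _tip_log_partials(
    tree: Tree, tip_states: Mapping[str, str], alphabet: Sequence[str]
) -> dict[int, np.ndarray]:
    state_index = {s: i for i, s in enumerate(alphabet)}
    out: dict[int, np.ndarray] = {}
    for i in tree.tip_indices:
        label = tree.nodes[i].label
        if label not in tip_states:
            raise KeyError(f"tip {label!r} absent from character data")
        s = tip_states[label]
        v = np.full(len(alphabet), -np.inf)
        if s == MISSING:
            v[:] = 0.0  # uninformative: all-ones partial
        else:
            if s not in state_index:
                raise ValueError(
                    f"state {s!r} of tip {label!r} not in alphabet"
                )
            v[state_index[s]] = 0.0
        out[i] = v
    return out


def _log_transition_matrices(tree: Tree, model: MkModel) -> dict[int, np.ndarray]:
    bl = tree.branch_lengths()
    cache: dict[float, np.ndarray] = {}
    out = {}
    for i in range(tree.n_nodes):
        if i == tree.root:
            continue
        t = bl[i]
        if t not in cache:
            with np.errstate(divide="ignore"):
                cache[t] = np.log(transition_probabilities(model, t))
        out[i] = cache[t]
    return out


def _downpass(tree, logP, tip_partials):
    """Felsenstein post-order conditional log-likelihood vectors.

    Returns (logD, logMsg): per node, log partials; per non-root node, the
    log message to its parent (indexed by parent state).
    """
    logD: dict[int, np.ndarray] = {}
    logMsg: dict[int, np.ndarray] = {}
    for i in tree.postorder():
        nd = tree.nodes[i]
        if nd.is_tip:
            logD[i] = tip_partials[i]
        else:
            logD[i] = sum(logMsg[c] for c in nd.children)
        if nd.parent is not None:
            logMsg[i] = logsumexp(logP[i] + logD[i][None, :], axis=1)
    return logD, logMsg


def pruning_loglik(
    tree: Tree,
    tip_states: Mapping[str, str],
    model: MkModel,
    alphabet: Sequence[str],
) -> float:
    """Log-likelihood of one character by Felsenstein pruning.

    Missing states (``"?"``) contribute an all-ones partial vector; the
    root is combined with the model's root prior.  Underflow-safe via
    per-node rescaling of the partials.
    """
    if len(alphabet) != model.k:
        raise ValueError("alphabet size does not match model.k")
    state_index = {s: i for i, s in enumerate(alphabet)}
    k = model.k
    bl = tree.branch_lengths()
    Pcache: dict[float, np.ndarray] = {}
    partial: dict[int, np.ndarray] = {}
    logscale = 0.0
    for i in tree.postorder():
        nd = tree.nodes[i]
        if nd.is_tip:
            if nd.label not in tip_states:
                raise KeyError(f"tip {nd.label!r} absent from character data")
            s = tip_states[nd.label]
            v = np.zeros(k)
            if s == MISSING:
                v[:] = 1.0
            else:
                if s not in state_index:
                    raise ValueError(
                        f"state {s!r} of tip {nd.label!r} not in alphabet"
                    )
                v[state_index[s]] = 1.0
        else:
            v = np.ones(k)
            for c in nd.children:
                t = bl[c]
                P = Pcache.get(t)
                if P is None:
                    P = Pcache[t] = transition_probabilities(model, t)
                v = v * (P @ partial[c])
            m = v.max()
            if m <= 0:
                return -np.inf
            v /= m
            logscale += np.log(m)
        partial[i] = v
    return float(np.log(model.prior() @ partial[tree.root]) + logscale)


# ----------------------------------------------------------------- fitting

def fit_mk1(
    tree: Tree,
    tip_states: Mapping[str, str],
    k: int,
    alphabet: Sequence[str] | None = None,
    root_prior: str = "uniform",
    strict: bool = False,
) -> tuple[MkModel, float]:
    """1-D bounded ML fit of the Mk1 rate (search on log rate).

    A monomorphic character pins the rate at the lower bound (warning, or
    an error under ``strict``).
    """
    if alphabet is None:
        alphabet = sorted(
            {s for s in tip_states.values() if s != MISSING}
        )
    observed = {
        tip_states[lab]
        for lab in tree.tip_labels
        if tip_states.get(lab, MISSING) != MISSING
    }
    if len(observed) < 2:
        if strict:
            raise ValueError("character has no variation on this tree")
        warnings.warn("no variation: rate pinned at lower bound")
        model = MkModel(k=k, rate=np.exp(LOG_RATE_BOUNDS[0]),
                        root_prior=root_prior)
        return model, pruning_loglik(tree, tip_states, model, alphabet)

    def neg(lr: float) -> float:
        model = MkModel(k=k, rate=float(np.exp(lr)), root_prior=root_prior)
        return -pruning_loglik(tree, tip_states, model, alphabet)

    res = minimize_scalar(
        neg, bounds=LOG_RATE_BOUNDS, method="bounded",
        options={"xatol": 1e-8},
    )
    model = MkModel(k=k, rate=float(np.exp(res.x)), root_prior=root_prior)
    return model, -float(res.fun)


def fit_asymm(
    tree: Tree,
    tip_states: Mapping[str, str],
    alphabet: Sequence[str],
    root_prior: str = "stationary",
    n_restarts: int = 5,
    seed: int = 0,
) -> tuple[MkModel, float]:
    """2-D ML fit of the asymmetric binary model, multi-start.

    Starting points: the symmetric Mk1 MLE (guaranteeing the nested-model
    inequality up to optimizer tolerance) plus ``n_restarts`` seeded random
    points on the log-rate square.
    """
    if len(alphabet) != 2:
        raise ValueError("asymmetric model requires a binary character")

    def neg(x: np.ndarray) -> float:
        model = MkModel(
            k=2, q01=float(np.exp(x[0])), q10=float(np.exp(x[1])),
            root_prior=root_prior,
        )
        return -pruning_loglik(tree, tip_states, model, alphabet)

    mk1_model, mk1_lnl = fit_mk1(
        tree, tip_states, k=2, alphabet=alphabet, root_prior="uniform"
    )
    lr = np.log(mk1_model.rate)
    rng = np.random.default_rng(seed)
    starts = [np.array([lr, lr])]
    for _ in range(n_restarts):
        starts.append(lr + rng.uniform(-3.0, 3.0, size=2))

    best = None
    for x0 in starts:
        res = minimize(
            neg, x0, method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    lo, hi = LOG_RATE_BOUNDS
    x = np.clip(best.x, lo, hi)
    model = MkModel(
        k=2, q01=float(np.exp(x[0])), q10=float(np.exp(x[1])),
        root_prior=root_prior,
    )
    lnl = pruning_loglik(tree, tip_states, model, alphabet)
    if lnl < mk1_lnl - 1e-4:
        warnings.warn(
            "asymmetric fit below nested Mk1 likelihood: optimizer failure"
        )
    return model, float(lnl)


# ------------------------------------------------------------ marginal ASR

@dataclass
class AsrResult:
    """Marginal ancestral-state reconstruction with the T-rule.

    ``node_logliks[i]`` holds, for internal node ``i``, the log-likelihood
    of all tip data with that node clamped to each state (parameters held
    at their fitted values).  ``significant_sets[i]`` keeps the states
    within ``T`` log-units of the node's best state.
    """

    model: MkModel
    loglik: float
    alphabet: tuple[str, ...]
    T: float
    node_logliks: dict[int, np.ndarray]
    significant_sets: dict[int, tuple[str, ...]] = field(init=False)

    def __post_init__(self):
        self.significant_sets = {
            i: self.states_within(i, self.T) for i in self.node_logliks
        }

    def states_within(self, node: int, T: float) -> tuple[str, ...]:
        v = self.node_logliks[node]
        best = v.max()
        return tuple(
            s for j, s in enumerate(self.alphabet) if best - v[j] < T
        )

    def marginal_probabilities(self, node: int) -> np.ndarray:
        v = self.node_logliks[node]
        return np.exp(v - logsumexp(v))

    def is_solid(self, node: int) -> bool:
        return len(self.significant_sets[node]) == 1

    def to_frame(self, tree: Tree):
        import pandas as pd

        rows = []
        for i, v in sorted(self.node_logliks.items()):
            row = {"node": i, "tips": ";".join(sorted(tree.tip_set(i))[:3])}
            row.update({f"lnL[{s}]": v[j]
                        for j, s in enumerate(self.alphabet)})
            row["significant"] = ";".join(self.significant_sets[i])
            rows.append(row)
        return pd.DataFrame(rows)


def marginal_asr(
    tree: Tree,
    tip_states: Mapping[str, str],
    model: MkModel,
    alphabet: Sequence[str],
    T: float = 2.0,
) -> AsrResult:
    """Per-node clamped log-likelihoods via one down pass + one up pass.

    With ``logD`` the usual pruning partials and ``logG`` the
    complement ("outside") quantity propagated root-to-tips, the data
    log-likelihood with node v clamped to state s is
    ``logG[v][s] + logD[v][s]``; summing over s recovers the global
    log-likelihood at every node (used as an internal consistency check).
    """
    tips = _tip_log_partials(tree, tip_states, alphabet)
    logP = _log_transition_matrices(tree, model)
    logD, logMsg = _downpass(tree, logP, tips)
    with np.errstate(divide="ignore"):
        logG: dict[int, np.ndarray] = {
            tree.root: np.log(model.prior())
        }
    total = float(logsumexp(logG[tree.root] + logD[tree.root]))
    for i in tree.preorder():
        nd = tree.nodes[i]
        if nd.is_tip:
            continue
        sib_sum = sum(logMsg[c] for c in nd.children)
        for c in nd.children:
            # parent-state-indexed outside quantity for child c
            out_j = logG[i] + sib_sum - logMsg[c]
            logG[c] = logsumexp(out_j[:, None] + logP[c], axis=0)
    node_logliks = {
        i: logG[i] + logD[i] for i in tree.internal_indices
    }
    for i, v in node_logliks.items():
        if abs(logsumexp(v) - total) > 1e-6:
            raise AssertionError(
                f"marginal identity violated at node {i}"
            )
    return AsrResult(
        model=model, loglik=total, alphabet=tuple(alphabet), T=T,
        node_logliks=node_logliks,
    )


def drop_unknowns_rerun(
    tree: Tree,
    tip_states: Mapping[str, str],
    alphabet: Sequence[str],
    model: str = "mk1",
    T: float = 2.0,
) -> dict:
    """Re-fit + re-reconstruct with unknown-state tips pruned.

    Returns the paired :class:`AsrResult` objects plus a per-shared-node
    agreement table (significant sets equal / not), keyed by the full
    tree's node index.  Robustness check mirroring the published analysis
    that removing unknown-life-cycle species does not move the
    reconstruction.
    """

    def run(t: Tree, states: Mapping[str, str]) -> AsrResult:
        if model == "mk1":
            m, _ = fit_mk1(t, states, k=len(alphabet), alphabet=alphabet)
        elif model == "asymm":
            m, _ = fit_asymm(t, states, alphabet=alphabet)
        else:
            raise ValueError(f"unknown model spec {model!r}")
        return marginal_asr(t, states, m, alphabet, T=T)

    full = run(tree, tip_states)
    known = [
        lab for lab in tree.tip_labels if tip_states.get(lab) != MISSING
    ]
    pruned_tree = tree.retain_tips(known)
    pruned = run(pruned_tree, tip_states)

    agreement = {}
    for j in pruned_tree.internal_indices:
        tipset = pruned_tree.tip_set(j)
        i = tree.mrca(tipset)
        if tree.tip_set(i) & set(known) != tipset:
            continue  # not the same split once unknowns return
        agreement[i] = (
            full.significant_sets[i] == pruned.significant_sets[j]
        )
    frac = (
        sum(agreement.values()) / len(agreement) if agreement else float("nan")
    )
    return {
        "full": full,
        "pruned": pruned,
        "agreement": agreement,
        "agreement_fraction": frac,
    }
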
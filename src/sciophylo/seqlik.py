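"""Per-site log-likelihoods under partitioned GTR+Γ(+I) on fixed topologies.

Implements the pruning algorithm with an eigendecomposition of the GTR
generator, 4-category discrete gamma rate variation (category means), an
optional invariant-sites class, and per-partition rate multipliers over a
shared set of branch lengths — the site-likelihood machinery feeding the
RELL/AU/SH topology-test battery.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .alignments import Alignment
from .trees import Tree

__all__ = [
    "SubstModel",
    "gtr_generator",
    "gamma_category_rates",
    "site_logliks",
    "partitioned_site_logliks",
    "optimize_branch_lengths",
]


@dataclass(frozen=True)
class SubstModel:
    """GTR+Γ+I parameters for one partition.

    ``exchangeabilities`` — 6 rates in order (AC, AG, AT, CG, CT, GT),
    normalized internally; ``base_freqs`` — (A, C, G, T) summing to 1;
    ``alpha`` — gamma shape (``None`` disables rate variation);
    ``p_inv`` — invariant proportion in [0, 1); ``multiplier`` —
    partition-specific rate scale applied to the shared branch lengths.
    """

    exchangeabilities: tuple = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    base_freqs: tuple = (0.25, 0.25, 0.25, 0.25)
    alpha: float | None = None
    p_inv: float = 0.0
    multiplier: float = 1.0
    n_categories: int = 4

    def __post_init__(self):
        f = np.asarray(self.base_freqs, float)
        if abs(f.sum() - 1.0) > 1e-10 or np.any(f <= 0):
            raise ValueError("base frequencies must be positive and sum to 1")
        if len(self.exchangeabilities) != 6:
            raise ValueError("need 6 GTR exchangeabilities")
        if not 0.0 <= self.p_inv < 1.0:
            raise ValueError("p_inv must lie in [0, 1)")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("gamma shape must be > 0")
        if self.multiplier <= 0:
            raise ValueError("rate multiplier must be > 0")

    @classmethod
    def jukes_cantor(cls) -> "SubstModel":
        return cls()


def gtr_generator(model: SubstModel) -> np.ndarray:
    """4×4 GTR generator scaled to mean rate 1 (before the multiplier)."""
    pi = np.asarray(model.base_freqs, float)
    s = np.zeros((4, 4))
    (s[0, 1], s[0, 2], s[0, 3], s[1, 2], s[1, 3], s[2, 3]) = (
        model.exchangeabilities
    )
    s = s + s.T
    Q = s * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -(pi * np.diag(Q)).sum()
    return Q / mean_rate


def gamma_category_rates(alpha: float, k: int = 4) -> np.ndarray:
    """Mean rate of each of k equal-probability gamma categories (mean 1)."""
    edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a=alpha, scale=1 / alpha)
    # E[X 1{X<x}] for Gamma(alpha, scale=1/alpha) is gammainc(alpha+1, alpha*x)
    cum = gammainc(alpha + 1, alpha * edges)
    cum[0], cum[-1] = 0.0, 1.0
    return k * np.diff(cum)


def _site_rates(model: SubstModel) -> tuple[np.ndarray, np.ndarray]:
    """(rates, weights) of the discrete rate mixture, mean rate 1."""
    if model.alpha is None:
        rates, weights = np.array([1.0]), np.array([1.0])
    else:
        rates = gamma_category_rates(model.alpha, model.n_categories)
        weights = np.full(model.n_categories, 1.0 / model.n_categories)
    if model.p_inv > 0:
        rates = np.concatenate([[0.0], rates / (1.0 - model.p_inv)])
        weights = np.concatenate(
            [[model.p_inv], weights * (1.0 - model.p_inv)]
        )
    return rates, weights


class _Eigen:
    """Eigendecomposition of the GTR generator via π-symmetrization."""

    def __init__(self, model: SubstModel):
        Q = gtr_generator(model)
        pi = np.asarray(model.base_freqs, float)
        sq = np.sqrt(pi)
        S = (Q * sq[:, None]) / sq[None, :]
        lam, V = np.linalg.eigh((S + S.T) / 2)
        self.lam = lam
        self.right = V / sq[:, None] * 1.0
        self.left = (V * sq[:, None]).T
        self.pi = pi

    def P(self, t: float) -> np.ndarray:
        M = (self.right * np.exp(self.lam * t)) @ self.left
        return np.clip(M, 0.0, None)


def _encode_tips(tree: Tree, aln: Alignment, cols: np.ndarray):
    enc = aln.encoded()[:, cols]
    rows = {t: i for i, t in enumerate(aln.taxa)}
    missing = set(tree.tip_labels) - rows.keys()
    if missing:
        raise ValueError(f"alignment lacks tree tips: {sorted(missing)}")
    return {
        i: enc[rows[tree.nodes[i].label]] for i in tree.tip_indices
    }


def site_logliks(
    tree: Tree,
    aln: Alignment,
    model: SubstModel,
    cols: np.ndarray | None = None,
) -> np.ndarray:
    """Per-site log-likelihoods of one partition on a fixed tree.

    Non-ACGT symbols are treated as missing.  Branch lengths are the
    tree's, scaled by the model's rate multiplier.
    """
    cols = cols if cols is not None else np.arange(aln.length)
    tips = _encode_tips(tree, aln, cols)
    eig = _Eigen(model)
    rates, weights = _site_rates(model)
    bl = tree.branch_lengths() * model.multiplier
    L = len(cols)
    pi = eig.pi
    cat_loglik = np.full((len(rates), L), -np.inf)
    for ci, (rate, w) in enumerate(zip(rates, weights)):
        partial: dict[int, np.ndarray] = {}
        scale = np.zeros(L)
        for i in tree.postorder():
            nd = tree.nodes[i]
            if nd.is_tip:
                m = np.zeros((L, 4))
                obs = tips[i]
                known = obs < 4
                m[known, obs[known]] = 1.0
                m[~known, :] = 1.0
                partial[i] = m
            else:
                m = np.ones((L, 4))
                for c in nd.children:
                    P = eig.P(bl[c] * rate) if rate > 0 else np.eye(4)
                    m = m * (partial[c] @ P.T)
                mx = m.max(axis=1)
                mx[mx == 0] = 1.0
                scale += np.log(mx)
                partial[i] = m / mx[:, None]
        root_l = (partial[tree.root] @ pi).clip(1e-300)
        cat_loglik[ci] = np.log(w) + np.log(root_l) + scale
    from scipy.special import logsumexp

    return logsumexp(cat_loglik, axis=0)


def partitioned_site_logliks(
    tree: Tree,
    aln: Alignment,
    models: Mapping[str, SubstModel],
) -> np.ndarray:
    """Per-site log-likelihoods over all partitions, in alignment column
    order."""
    out = np.zeros(aln.length)
    for name, cols in aln.partitions.items():
        if name not in models:
            raise KeyError(f"no substitution model for partition {name!r}")
        out[cols] = site_logliks(tree, aln, models[name], cols)
    return out


def optimize_branch_lengths(
    tree: Tree,
    aln: Alignment,
    models: Mapping[str, SubstModel],
    max_sweeps: int = 50,
    tol: float = 1e-4,
    bounds: tuple[float, float] = (1e-8, 10.0),
) -> tuple[Tree, float]:
    """Cyclic one-dimensional ML optimization of shared branch lengths.

    Returns a tree copy with optimized lengths plus the final total
    log-likelihood; stops when a full sweep improves the log-likelihood by
    less than ``tol`` or after ``max_sweeps``.
    """
    tree = tree.copy()

    def total() -> float:
        return float(partitioned_site_logliks(tree, aln, models).sum())

    current = total()
    branch_nodes = [i for i in range(tree.n_nodes) if i != tree.root]
    for _ in range(max_sweeps):
        previous = current
        for i in branch_nodes:
            node = tree.nodes[i]

            def neg(t: float) -> float:
                node.length = t
                return -total()

            res = minimize_scalar(
                neg, bounds=bounds, method="bounded",
                options={"xatol": 1e-6},
            )
            node.length = float(res.x)
            current = -float(res.fun)
        if current - previous < tol:
            break
    return tree, current
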
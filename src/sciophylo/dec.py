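"""Two-area dispersal–extinction–cladogenesis (DEC) model for habitat.

Ranges are {A} (aquatic), {T} (terrestrial) and {AT} (both); the empty
range is reachable anagenetically (local extinction of a single-area
lineage) but is absorbing and contributes zero tip likelihood.  Anagenetic
rates: range expansion {A}→{AT} at ``ρ·d`` (the aquatic→terrestrial
dispersal direction carries the asymmetry multiplier), {T}→{AT} at ``d``,
range contraction {AT}→{A}, {AT}→{T} and single-area loss at ``e``.  At
each (bifurcating) node a widespread ancestor {AT} splits into the six
equal-weight vicariance/subset-sympatry scenarios; a single-area ancestor
copies itself to both daughters.

The transition-rate asymmetry ``ρ`` is profiled over a grid of ratios
(default 20:1 … 1:1 … 1:20), fitting ``d`` and ``e`` at each, and the
2-log-likelihood rule is applied both to the ratio profile (against the
symmetric null) and to per-node ancestral-range sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize

from .trees import Tree

__all__ = [
    "DecParams",
    "RatioProfile",
    "DecNodeEstimates",
    "dec_loglik",
    "fit_dec",
    "sweep_ratio",
    "dec_node_estimates",
    "default_ratio_grid",
]

RANGES = ("A", "T", "AT")
_EMPTY = 3  # internal index of the empty range
LOG_PARAM_BOUNDS = (np.log(1e-7), np.log(50.0))


@dataclass(frozen=True)
class DecParams:
    """Anagenetic DEC parameters.

    d — base dispersal (range-expansion) rate per unit branch length;
    e — per-area extinction (range-contraction) rate;
    ratio — multiplier on the aquatic→terrestrial expansion {A}→{AT}
    relative to {T}→{AT}.
    """

    d: float
    e: float
    ratio: float = 1.0

    def __post_init__(self):
        if self.d <= 0 or self.e <= 0 or self.ratio <= 0:
            raise ValueError("d, e and ratio must all be > 0")

    def generator(self) -> np.ndarray:
        """4×4 anagenetic generator over (A, T, AT, empty); rows sum to 0."""
        d, e, rho = self.d, self.e, self.ratio
        Q = np.zeros((4, 4))
        Q[0, 2] = rho * d  # {A} gains terrestrial area
        Q[1, 2] = d        # {T} gains aquatic area
        Q[0, _EMPTY] = e
        Q[1, _EMPTY] = e
        Q[2, 0] = e        # lose terrestrial area
        Q[2, 1] = e        # lose aquatic area
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q


#: cladogenetic inheritance: ancestor state -> [(left, right, weight)]
_SCENARIOS = {
    0: [(0, 0, 1.0)],
    1: [(1, 1, 1.0)],
    2: [
        (0, 1, 1 / 6), (1, 0, 1 / 6),
        (0, 2, 1 / 6), (2, 0, 1 / 6),
        (1, 2, 1 / 6), (2, 1, 1 / 6),
    ],
}


def _range_index(code: str) -> int:
    try:
        return RANGES.index(code)
    except ValueError:
        raise ValueError(
            f"tip range {code!r} not one of {RANGES}"
        ) from None


def _transition_cache(tree: Tree, params: DecParams) -> dict[int, np.ndarray]:
    """P(t) per branch; one eigendecomposition of the generator, batched
    over the distinct branch lengths (expm fallback if ill-conditioned)."""
    Q = params.generator()
    bl = tree.branch_lengths()
    lengths = np.unique(bl[np.arange(tree.n_nodes) != tree.root])
    try:
        lam, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        if np.linalg.cond(V) > 1e8:
            raise np.linalg.LinAlgError
        # (n_lengths, 4, 4) batch
        E = np.exp(np.real(lam)[None, :] * lengths[:, None]) * np.exp(
            1j * np.imag(lam)[None, :] * lengths[:, None]
        )
        Ps = np.einsum("ij,tj,jk->tik", V, E, Vinv).real
        cache = {t: np.clip(P, 0.0, None) for t, P in zip(lengths, Ps)}
    except np.linalg.LinAlgError:
        cache = {t: expm(Q * t) for t in lengths}
    return {
        i: cache[bl[i]]
        for i in range(tree.n_nodes)
        if i != tree.root
    }


def _conditional_likelihoods(
    tree: Tree,
    tip_ranges: Mapping[str, str],
    params: DecParams,
    clamp: tuple[int, int] | None = None,
):
    """Post-order DEC conditionals.

    Returns (L, logscale): per node a length-4 vector (A, T, AT, empty) of
    scaled conditional likelihoods of the data below, given the node's
    range immediately *before* cladogenesis, plus the accumulated log
    scaling factor.  ``clamp=(node, state)`` zeroes all other states of
    one node (the constrained split computation behind per-node range
    scoring).
    """
    P = _transition_cache(tree, params)
    L: dict[int, np.ndarray] = {}
    logscale = 0.0
    for i in tree.postorder():
        nd = tree.nodes[i]
        if nd.is_tip:
            if nd.label not in tip_ranges:
                raise KeyError(f"tip {nd.label!r} has no range coding")
            v = np.zeros(4)
            v[_range_index(tip_ranges[nd.label])] = 1.0
        else:
            if len(nd.children) != 2:
                raise ValueError(
                    "DEC cladogenesis requires a bifurcating tree"
                )
            c1, c2 = nd.children
            D1 = P[c1] @ L[c1]
            D2 = P[c2] @ L[c2]
            v = np.zeros(4)
            for s, scen in _SCENARIOS.items():
                v[s] = sum(w * D1[a] * D2[b] for a, b, w in scen)
        if clamp is not None and i == clamp[0]:
            keep = v[clamp[1]]
            v = np.zeros(4)
            v[clamp[1]] = keep
        m = v.max()
        if m <= 0:
            return None, -np.inf  # impossible data under this clamp
        L[i] = v / m
        logscale += np.log(m)
    return L, logscale


def dec_loglik(
    tree: Tree,
    tip_ranges: Mapping[str, str],
    params: DecParams,
    root_prior: str = "uniform",
) -> float:
    """DEC log-likelihood; root prior uniform over the three live ranges."""
    L, logscale = _conditional_likelihoods(tree, tip_ranges, params)
    if L is None:
        return -np.inf
    root = L[tree.root][:3]
    if root_prior == "uniform":
        prior = np.full(3, 1 / 3)
    else:
        raise ValueError(f"unknown root prior {root_prior!r}")
    return float(np.log(prior @ root) + logscale)


def fit_dec(
    tree: Tree,
    tip_ranges: Mapping[str, str],
    ratio: float = 1.0,
    x0: np.ndarray | None = None,
) -> tuple[DecParams, float]:
    """ML fit of (d, e) at fixed ratio; bounded Nelder-Mead on log rates."""
    lo, hi = LOG_PARAM_BOUNDS

    def neg(x: np.ndarray) -> float:
        xd, xe = np.clip(x, lo, hi)
        p = DecParams(d=float(np.exp(xd)), e=float(np.exp(xe)), ratio=ratio)
        return -dec_loglik(tree, tip_ranges, p)

    starts = [x0] if x0 is not None else [
        np.log([0.05, 0.05]), np.log([0.2, 0.02])
    ]
    best = None
    for s in starts:
        res = minimize(
            neg, s, method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    x = np.clip(best.x, lo, hi)
    if np.any(np.abs(x - lo) < 1e-6) or np.any(np.abs(x - hi) < 1e-6):
        warnings.warn("DEC optimizer hit a parameter bound")
    params = DecParams(
        d=float(np.exp(x[0])), e=float(np.exp(x[1])), ratio=ratio
    )
    return params, -float(best.fun)


def default_ratio_grid() -> tuple[float, ...]:
    """20:1 … 2:1, 1:1, 1:2 … 1:20 — 39 ratios covering both directions."""
    return tuple(
        [float(n) for n in range(20, 0, -1)]
        + [1.0 / n for n in range(2, 21)]
    )


@dataclass
class RatioProfile:
    """Profile likelihood of the dispersal-asymmetry ratio."""

    ratios: tuple[float, ...]
    params: tuple[DecParams, ...]
    logliks: tuple[float, ...]
    threshold: float = 2.0
    best_index: int = field(init=False)

    def __post_init__(self):
        self.best_index = int(np.argmax(self.logliks))

    @property
    def best_ratio(self) -> float:
        return self.ratios[self.best_index]

    @property
    def max_loglik(self) -> float:
        return self.logliks[self.best_index]

    @property
    def null_loglik(self) -> float:
        return self.logliks[self.ratios.index(1.0)]

    @property
    def within_threshold(self) -> tuple[float, ...]:
        m = self.max_loglik
        return tuple(
            r for r, l in zip(self.ratios, self.logliks)
            if m - l < self.threshold
        )

    @property
    def significant_vs_null(self) -> bool:
        return (self.max_loglik - self.null_loglik) > self.threshold

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "ratio": self.ratios,
                "d": [p.d for p in self.params],
                "e": [p.e for p in self.params],
                "lnL": self.logliks,
                "delta_vs_null": [
                    l - self.null_loglik for l in self.logliks
                ],
            }
        )


def sweep_ratio(
    tree: Tree,
    tip_ranges: Mapping[str, str],
    grid: Sequence[float] | None = None,
    threshold: float = 2.0,
    fast: bool = False,
) -> RatioProfile:
    """Fit (d, e) at every grid ratio; grid must include the 1:1 null.

    Fits are warm-started from the neighbouring ratio's optimum (the
    profile is smooth in log ratio) and, unless ``fast``, re-fit from the
    cold starts as a guard against a bad warm start.
    """
    grid = tuple(grid) if grid is not None else default_ratio_grid()
    if 1.0 not in grid:
        raise ValueError("ratio grid must include the 1:1 null")
    params: list[DecParams] = []
    lnls: list[float] = []
    x_prev = None
    for rho in grid:
        p, l = fit_dec(tree, tip_ranges, ratio=rho, x0=x_prev)
        if x_prev is not None and not fast:
            p2, l2 = fit_dec(tree, tip_ranges, ratio=rho)
            if l2 > l:
                p, l = p2, l2
        params.append(p)
        lnls.append(l)
        x_prev = np.log([p.d, p.e])
    return RatioProfile(
        ratios=grid, params=tuple(params), logliks=tuple(lnls),
        threshold=threshold,
    )


@dataclass
class DecNodeEstimates:
    """Per-node ancestral-range log-likelihoods and 2-lnL sets."""

    params: DecParams
    loglik: float
    threshold: float
    node_logliks: dict[int, np.ndarray]  # length-3 (A, T, AT)
    reported_sets: dict[int, tuple[str, ...]] = field(init=False)

    def __post_init__(self):
        self.reported_sets = {}
        for i, v in self.node_logliks.items():
            best = v.max()
            self.reported_sets[i] = tuple(
                r for j, r in enumerate(RANGES) if best - v[j] < self.threshold
            )

    def is_unambiguous(self, node: int) -> bool:
        return len(self.reported_sets[node]) == 1

    @property
    def significant_sets(self) -> dict[int, tuple[str, ...]]:
        """Alias so DEC estimates drop into the transition counter."""
        return self.reported_sets

    @property
    def alphabet(self) -> tuple[str, ...]:
        return RANGES


def dec_node_estimates(
    tree: Tree,
    tip_ranges: Mapping[str, str],
    params: DecParams,
    threshold: float = 2.0,
) -> DecNodeEstimates:
    """Ancestral-range score per internal node via clamped recomputation.

    For each internal node and each live range, the data likelihood is
    recomputed with that node's pre-cladogenesis range fixed; ranges more
    than ``threshold`` log-units below the node's best are dropped from
    the reported set.
    """
    total = dec_loglik(tree, tip_ranges, params)
    node_logliks: dict[int, np.ndarray] = {}
    prior = np.full(3, 1 / 3)
    for i in tree.internal_indices:
        v = np.empty(3)
        for s in range(3):
            L, logscale = _conditional_likelihoods(
                tree, tip_ranges, params, clamp=(i, s)
            )
            if L is None:
                v[s] = -np.inf
                continue
            v[s] = np.log(prior @ L[tree.root][:3]) + logscale
        node_logliks[i] = v
    est = DecNodeEstimates(
        params=params, loglik=total, threshold=threshold,
        node_logliks=node_logliks,
    )
    return est
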
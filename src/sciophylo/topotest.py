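"""RELL resampling and the AU/SH/WKH/WSH topology-test battery.

Given a topologies × sites matrix of per-site log-likelihoods, candidate
topologies are compared by resampling estimated log-likelihoods (RELL —
multinomial site resampling with no re-optimization):

* **KH/WKH** — pairwise tests against the best topology, centered
  replicate differences; the weighted variant standardizes by the
  per-pair replicate standard deviation.  KH is computed but flagged as
  inappropriate for a-posteriori comparisons and is excluded from
  headline reports.
* **SH/WSH** — simultaneous comparison against the centered maximum
  statistic over all candidates.
* **AU** — approximately unbiased test: bootstrap probabilities across a
  ladder of resampling scales, z-values fitted by weighted least squares
  to ``d·√r + c/√r``, p = 1 − Φ(d − c).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "SiteLoglikMatrix",
    "TopoTestResult",
    "rell_resample",
    "kh_sh_tests",
    "au_test",
    "topology_tests",
    "DEFAULT_SCALES",
]

DEFAULT_SCALES = tuple(round(0.5 + 0.1 * i, 1) for i in range(10))  # 0.5..1.4


@dataclass
class SiteLoglikMatrix:
    """Per-site log-likelihood rows for each candidate topology."""

    names: list[str]
    matrix: np.ndarray  # (n_topologies, L)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, float)
        if self.matrix.ndim != 2 or len(self.names) != self.matrix.shape[0]:
            raise ValueError("need one row of site log-likelihoods per topology")

    @property
    def totals(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    @property
    def L(self) -> int:
        return self.matrix.shape[1]

    def write(self, path) -> None:
        """Plain-text site-likelihood file: header then one row per
        topology (name followed by per-site lnL)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.names)} {self.L}\n")
            for name, row in zip(self.names, self.matrix):
                fh.write(name + " " + " ".join(f"{v:.6f}" for v in row) + "\n")

    @classmethod
    def read(cls, path) -> "SiteLoglikMatrix":
        with open(path) as fh:
            header = fh.readline().split()
            n, L = int(header[0]), int(header[1])
            names, rows = [], []
            for _ in range(n):
                parts = fh.readline().split()
                names.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        m = cls(names, np.array(rows))
        if m.L != L:
            raise ValueError("site-likelihood file header/body mismatch")
        return m


def rell_resample(
    matrix: SiteLoglikMatrix,
    B: int = 10000,
    scales: Sequence[float] = (1.0,),
    seed: int = 0,
) -> dict[float, np.ndarray]:
    """RELL replicate totals: scale -> (B, n_topologies) array.

    For scale r, each replicate draws round(r·L) sites multinomially with
    replacement and sums their log-likelihoods (no re-optimization).  A
    single seeded generator drives all scales, so results are bit
    reproducible.
    """
    if matrix.matrix.shape[0] < 2:
        raise ValueError("need at least 2 topologies")
    if B < 100:
        warnings.warn("B < 100 gives unstable p-values")
    rng = np.random.default_rng(seed)
    L = matrix.L
    out: dict[float, np.ndarray] = {}
    for r in scales:
        m = max(1, int(round(r * L)))
        counts = rng.multinomial(m, np.full(L, 1.0 / L), size=B)
        out[r] = counts @ matrix.matrix.T
    return out


def _centered(replicates: np.ndarray) -> np.ndarray:
    return replicates - replicates.mean(axis=0, keepdims=True)


def kh_sh_tests(
    matrix: SiteLoglikMatrix,
    replicates: np.ndarray,
    weighted: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """(KH, SH) one-sided p-values per topology from scale-1 replicates.

    KH compares each topology with the observed best; SH compares with
    the centered maximum over all topologies.  ``weighted`` standardizes
    every pairwise difference by its replicate standard deviation (WKH /
    WSH).
    """
    totals = matrix.totals
    n = len(totals)
    R = _centered(replicates)
    best = int(np.argmax(totals))
    B = R.shape[0]

    def sd_pair(i: int, j: int) -> float:
        s = float(np.std(R[:, i] - R[:, j], ddof=1))
        return s if s > 0 else 1.0

    kh = np.ones(n)
    for i in range(n):
        if i == best:
            # compare against runner-up so the best topology is testable
            rival = int(np.argmax(np.delete(totals, i))) + (
                1 if int(np.argmax(np.delete(totals, i))) >= i else 0
            )
        else:
            rival = best
        d_obs = totals[rival] - totals[i]
        diff = R[:, rival] - R[:, i]
        if weighted:
            s = sd_pair(rival, i)
            kh[i] = float(np.mean(diff / s >= d_obs / s))
        else:
            kh[i] = float(np.mean(diff >= d_obs))

    sh = np.ones(n)
    for i in range(n):
        if weighted:
            sds = np.array([sd_pair(j, i) for j in range(n)])
            d_obs = np.max((totals - totals[i]) / sds)
            stat = (R - R[:, i][:, None]) / sds[None, :]
            sh[i] = float(np.mean(stat.max(axis=1) >= d_obs))
        else:
            d_obs = np.max(totals - totals[i])
            stat = R - R[:, i][:, None]
            sh[i] = float(np.mean(stat.max(axis=1) >= d_obs))
    return kh, sh


def au_test(
    matrix: SiteLoglikMatrix,
    replicates_by_scale: dict[float, np.ndarray],
) -> np.ndarray:
    """AU p-value per topology from multiscale bootstrap probabilities.

    For each scale r, the bootstrap probability (BP) of a topology is the
    fraction of replicates in which it attains the maximum total.  The
    normal quantiles z(r) = Φ⁻¹(1 − BP) are regressed on (√r, 1/√r) by
    weighted least squares; p_AU = 1 − Φ(d − c) with d the signal and c
    the curvature coefficient.  Degenerate BP sequences (all 0 or all 1)
    are clamped with a warning.
    """
    scales = sorted(replicates_by_scale)
    if len(scales) < 2:
        raise ValueError("AU needs >= 2 usable scales")
    if len(scales) < 5 or min(scales) >= 1.0 or max(scales) <= 1.0:
        warnings.warn(
            "AU scales should span both sides of 1.0 with >= 5 values"
        )
    n = matrix.matrix.shape[0]
    out = np.empty(n)
    B = {r: replicates_by_scale[r].shape[0] for r in scales}
    bp = np.zeros((len(scales), n))
    for si, r in enumerate(scales):
        R = replicates_by_scale[r]
        winners = np.argmax(R, axis=1)
        # ties are resolved toward the lower index by argmax: fine for
        # continuous log-likelihoods
        for i in range(n):
            bp[si, i] = np.mean(winners == i)
    for i in range(n):
        p = bp[:, i].copy()
        lo = np.array([0.5 / B[r] for r in scales])
        degenerate = np.all(p <= 0) or np.all(p >= 1)
        p = np.clip(p, lo, 1 - lo)
        if degenerate:
            warnings.warn(
                f"degenerate bootstrap probabilities for topology {i}: "
                "AU p clamped"
            )
            out[i] = 1.0 if np.all(bp[:, i] >= 1) else 0.0
            continue
        z = norm.ppf(1 - p)
        X = np.stack(
            [np.sqrt(scales), 1 / np.sqrt(scales)], axis=1
        )
        # WLS weights: delta-method variance of z from binomial BP
        var = p * (1 - p) / np.array([B[r] for r in scales])
        w = norm.pdf(z) ** 2 / var
        W = np.diag(w)
        beta, *_ = np.linalg.lstsq(
            np.sqrt(w)[:, None] * X, np.sqrt(w) * z, rcond=None
        )
        d_hat, c_hat = beta
        out[i] = float(1 - norm.cdf(d_hat - c_hat))
    return out


@dataclass
class TopoTestResult:
    """Per-topology battery results (AU, SH, WKH, WSH headline; KH
    computed but flagged)."""

    names: list[str]
    totals: np.ndarray
    au: np.ndarray
    sh: np.ndarray
    wkh: np.ndarray
    wsh: np.ndarray
    kh: np.ndarray
    B: int
    scales: tuple
    seed: int
    kh_flag: str = (
        "KH is inappropriate for a-posteriori topology comparisons; "
        "reported for completeness only"
    )

    @property
    def delta(self) -> np.ndarray:
        return self.totals.max() - self.totals

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "topology": self.names,
                "lnL": self.totals,
                "delta": self.delta,
                "AU": self.au,
                "SH": self.sh,
                "WKH": self.wkh,
                "WSH": self.wsh,
                "KH(flagged)": self.kh,
            }
        )


def topology_tests(
    matrix: SiteLoglikMatrix,
    B: int = 10000,
    scales: Sequence[float] = DEFAULT_SCALES,
    seed: int = 0,
) -> TopoTestResult:
    """Run the full battery (AU over the scale ladder; KH/SH/WKH/WSH at
    scale 1) on one site-log-likelihood matrix."""
    scales = tuple(scales)
    if 1.0 not in scales:
        scales = tuple(sorted(scales + (1.0,)))
    reps = rell_resample(matrix, B=B, scales=scales, seed=seed)
    kh, sh = kh_sh_tests(matrix, reps[1.0], weighted=False)
    wkh, wsh = kh_sh_tests(matrix, reps[1.0], weighted=True)
    au = au_test(matrix, reps)
    return TopoTestResult(
        names=list(matrix.names), totals=matrix.totals,
        au=au, sh=sh, wkh=wkh, wsh=wsh, kh=kh,
        B=B, scales=scales, seed=seed,
    )
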
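"""Exploratory spatial data analysis: Moran's I, LISA, quantile classing.

Global Moran's I measures whether similar values of an indicator cluster in
space,

    I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2,   z = x - mean(x),

with expectation -1/(n-1) under the null of spatial randomness. The
bivariate variant correlates x at a location with the spatial lag of a
second variable y,

    I_xy = (n / S0) * sum_ij w_ij zx_i zy_j / sum_i zy_i^2.

Local indicators of spatial association (LISA) decompose I per unit,

    I_i = n * z_i * (Wz)_i / sum_k z_k^2,

and classify each unit by Moran-scatterplot quadrant: High-High and Low-Low
clusters (hotspots and coldspots) and High-Low / Low-High spatial outliers.

Inference is by permutation: full random relabelling for global statistics,
conditional permutation (the unit's own value held fixed, the remaining
n - 1 values shuffled onto its neighbours) for local ones. Pseudo p-values
are (M + 1) / (R + 1) with M the permuted statistics at least as extreme as
the observed one, one-sided toward the observed direction, ties inclusive.

Islands participate in the mean and variance but have lag 0 and are always
labelled "Not significant", so n is the same in every statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geoweights import SpatialWeights, spatial_lag

__all__ = [
    "MoranResult",
    "LisaResult",
    "QuantileClassing",
    "moran_global",
    "moran_bivariate",
    "lisa_univariate",
    "lisa_bivariate",
    "classify_clusters",
    "quantile_classes",
]

QUADRANT_LABELS = {1: "HH", 2: "LH", 3: "LL", 4: "HL"}
CLUSTER_NAMES = {
    "HH": "High-High",
    "LL": "Low-Low",
    "HL": "High-Low",
    "LH": "Low-High",
}
SIG_TIERS = (0.05, 0.01, 0.001)


class ZeroVarianceError(ValueError):
    """The variable is constant; Moran statistics are undefined."""


@dataclass
class MoranResult:
    statistic: float
    expected_value: float
    n: int
    permutations: int
    pseudo_p: float
    z_sim: float
    seed: int | None
    sim: np.ndarray | None = None  # permutation distribution (for diagnostics)

    def __repr__(self) -> str:  # keep the array out of the repr
        return (
            f"MoranResult(I={self.statistic:.4f}, E[I]={self.expected_value:.4f}, "
            f"n={self.n}, R={self.permutations}, p_sim={self.pseudo_p:.4g})"
        )


@dataclass
class LisaResult:
    ids: list[str]
    local_i: np.ndarray
    quadrant: list[str]  # HH / LH / LL / HL per unit
    pseudo_p: np.ndarray
    labels: list[str]  # cluster label incl. "Not significant"
    alpha: float
    permutations: int
    seed: int | None

    @property
    def n(self) -> int:
        return len(self.ids)

    def counts(self) -> dict[str, int]:
        out = {v: 0 for v in CLUSTER_NAMES.values()}
        out["Not significant"] = 0
        for lab in self.labels:
            out[lab] += 1
        return out


@dataclass
class QuantileClassing:
    breaks: np.ndarray  # k-1 ascending break points
    classes: np.ndarray  # per-unit class index 0..k-1
    k: int


def _check_variable(x, w: SpatialWeights, name: str = "x") -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape != (w.n,):
        raise ValueError(f"{name} has shape {x.shape}, weights have n={w.n}")
    if np.any(~np.isfinite(x)):
        raise ValueError(f"{name} contains missing values")
    if w.n < 3:
        raise ValueError("need at least 3 spatial units")
    # constant up to rounding (e.g. residuals of a perfect fit) counts too
    if np.ptp(x) <= 1e-10 * max(1.0, float(np.max(np.abs(x)))):
        raise ZeroVarianceError(f"{name} is constant; Moran's I undefined")
    if len(w.islands) == w.n:
        raise ValueError("all units are islands; no spatial structure")
    return x


def _pseudo_p(obs: float, sim: np.ndarray, direction: float) -> float:
    """(M+1)/(R+1), one-sided toward ``direction`` (>=0 means upper tail)."""
    if direction >= 0:
        m = int(np.sum(sim >= obs))
    else:
        m = int(np.sum(sim <= obs))
    return (m + 1) / (len(sim) + 1)


def _moran_stat(zx: np.ndarray, zy_lag: np.ndarray, denom: float, n: int, S0: float) -> float:
    return float(n / S0 * (zx @ zy_lag) / denom)


def moran_global(x, w: SpatialWeights, permutations: int = 999, seed: int | None = None) -> MoranResult:
    """Global Moran's I with permutation inference.

    The null distribution is built by randomly relabelling x over the units
    ``permutations`` times.
    """
    x = _check_variable(x, w)
    n = w.n
    z = x - x.mean()
    denom = float(z @ z)
    S0 = w.S0
    W = w.to_sparse()
    obs = _moran_stat(z, W @ z, denom, n, S0)
    expected = -1.0 / (n - 1)
    sim = np.empty(0)
    p_sim, z_sim = np.nan, np.nan
    if permutations:
        rng = np.random.default_rng(seed)
        sim = np.empty(permutations)
        for r in range(permutations):
            zp = rng.permutation(z)
            sim[r] = _moran_stat(zp, W @ zp, denom, n, S0)
        p_sim = _pseudo_p(obs, sim, obs - expected)
        sd = sim.std(ddof=0)
        z_sim = (obs - sim.mean()) / sd if sd > 0 else np.inf
    return MoranResult(obs, expected, n, permutations, p_sim, z_sim, seed, sim)


def moran_bivariate(x, y, w: SpatialWeights, permutations: int = 999, seed: int | None = None) -> MoranResult:
    """Bivariate Moran's I between x and the spatial lag of y.

    Both variables are z-standardized (population sd) before the statistic
    is formed, the convention of the GeoDa-style bivariate Moran: it makes
    the statistic invariant under positive affine rescaling of either
    variable, and reduces exactly to the univariate statistic when y = x.
    The permutation null holds x fixed at its locations and permutes y.
    """
    x = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError("x contains missing values")
    y = _check_variable(y, w, "y")
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    n = w.n
    zx = _standardize(x)
    zy = _standardize(y)
    denom = float(zy @ zy)
    S0 = w.S0
    W = w.to_sparse()
    obs = _moran_stat(zx, W @ zy, denom, n, S0)
    expected = 0.0
    sim = np.empty(0)
    p_sim, z_sim = np.nan, np.nan
    if permutations:
        rng = np.random.default_rng(seed)
        sim = np.empty(permutations)
        for r in range(permutations):
            zp = rng.permutation(zy)
            sim[r] = _moran_stat(zx, W @ zp, denom, n, S0)
        p_sim = _pseudo_p(obs, sim, obs - expected)
        sd = sim.std(ddof=0)
        z_sim = (obs - sim.mean()) / sd if sd > 0 else np.inf
    return MoranResult(obs, expected, n, permutations, p_sim, z_sim, seed, sim)


def _standardize(v: np.ndarray) -> np.ndarray:
    z = v - v.mean()
    sd = z.std(ddof=0)
    return z / sd if sd > 0 else z


def _quadrants(zx: np.ndarray, lag_z: np.ndarray) -> list[str]:
    """Moran-scatterplot quadrant per unit; zero deviations count as low."""
    out = []
    for zi, li in zip(zx, lag_z):
        if zi > 0:
            out.append("HH" if li > 0 else "HL")
        else:
            out.append("LH" if li > 0 else "LL")
    return out


def _conditional_permutation_lags(
    values: np.ndarray, w: SpatialWeights, permutations: int, rng: np.random.Generator
) -> np.ndarray:
    """R x n matrix of spatial lags under conditional permutation.

    For each unit i, ``values`` of the other n-1 units are shuffled and the
    first k_i take the place of i's neighbours (with i's actual weights).
    Vectorized: one (R, max_k) index pool of draws without replacement from
    range(n-1) is shared across units, as in the standard LISA null.
    """
    n = w.n
    cards = w.cardinalities()
    max_k = int(cards.max())
    lags = np.zeros((permutations, n))
    if max_k == 0:
        return lags
    # R rows of distinct indices into the "other units" arrays
    pool = np.argsort(rng.random((permutations, n - 1)), axis=1)[:, :max_k]
    others = np.empty((n, n - 1), dtype=int)
    base = np.arange(n)
    for i in range(n):
        others[i] = np.concatenate([base[:i], base[i + 1:]])
    for i in range(n):
        k = int(cards[i])
        if k == 0:
            continue
        wrow = np.asarray(w.weights[i], dtype=float)
        draws = values[others[i][pool[:, :k]]]  # (R, k)
        lags[:, i] = draws @ wrow
    return lags


def _lisa(
    zx: np.ndarray,
    zpartner: np.ndarray,
    denom: float,
    w: SpatialWeights,
    permutations: int,
    seed: int | None,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    n = w.n
    lag = spatial_lag(w, zpartner)
    local_i = n * zx * lag / denom
    quad = _quadrants(zx, lag)
    p = np.full(n, 1.0)
    if permutations:
        rng = np.random.default_rng(seed)
        sim_lags = _conditional_permutation_lags(zpartner, w, permutations, rng)
        sim = n * zx[None, :] * sim_lags / denom  # (R, n)
        mean_sim = sim.mean(axis=0)
        upper = local_i >= mean_sim
        m_up = (sim >= local_i[None, :]).sum(axis=0)
        m_lo = (sim <= local_i[None, :]).sum(axis=0)
        p = (np.where(upper, m_up, m_lo) + 1) / (permutations + 1)
    mask = w.island_mask()
    p[mask] = 1.0
    return local_i, quad, p


def lisa_univariate(
    x,
    w: SpatialWeights,
    permutations: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
) -> LisaResult:
    """Local Moran's I per unit with conditional-permutation inference."""
    x = _check_variable(x, w)
    z = x - x.mean()
    denom = float(z @ z)
    local_i, quad, p = _lisa(z, z, denom, w, permutations, seed)
    labels = _labels_from(quad, p, alpha, w)
    return LisaResult(list(w.ids), local_i, quad, p, labels, alpha, permutations, seed)


def lisa_bivariate(
    x,
    y,
    w: SpatialWeights,
    permutations: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
) -> LisaResult:
    """Bivariate local Moran: x at a unit against the lag of y around it.

    As in the global bivariate statistic, both variables are z-standardized
    first (GeoDa convention), so the local values sum to n times the global
    bivariate Moran under row-standardized weights.
    """
    y = _check_variable(y, w, "y")
    x = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError("x contains missing values")
    zx = _standardize(x)
    zy = _standardize(y)
    denom = float(zy @ zy)
    local_i, quad, p = _lisa(zx, zy, denom, w, permutations, seed)
    labels = _labels_from(quad, p, alpha, w)
    return LisaResult(list(w.ids), local_i, quad, p, labels, alpha, permutations, seed)


def _labels_from(quad: list[str], p: np.ndarray, alpha: float, w: SpatialWeights) -> list[str]:
    mask = w.island_mask()
    labels = []
    for k, (q, pi) in enumerate(zip(quad, p)):
        if pi < alpha and not mask[k]:  # strict: p == alpha is not significant
            labels.append(CLUSTER_NAMES[q])
        else:
            labels.append("Not significant")
    return labels


def classify_clusters(lisa: LisaResult, alpha: float | None = None) -> dict:
    """Cluster labels plus the significance-tier map.

    Significant High-High units are hotspots, Low-Low coldspots, and
    High-Low / Low-High spatial outliers. ``sig_tier`` gives the strongest
    tier (0.05 / 0.01 / 0.001) each unit's pseudo p-value clears, 0 when
    none.
    """
    a = lisa.alpha if alpha is None else alpha
    labels = []
    tiers = []
    for q, p in zip(lisa.quadrant, lisa.pseudo_p):
        labels.append(CLUSTER_NAMES[q] if p < a else "Not significant")
        tier = 0.0
        for t in SIG_TIERS:
            if p < t:
                tier = t
        tiers.append(tier)
    counts = {v: 0 for v in CLUSTER_NAMES.values()}
    counts["Not significant"] = 0
    for lab in labels:
        counts[lab] += 1
    return {
        "labels": labels,
        "sig_tier": tiers,
        "hotspots": counts["High-High"],
        "coldspots": counts["Low-Low"],
        "outliers": counts["High-Low"] + counts["Low-High"],
        "counts": counts,
    }


def quantile_classes(x, k: int) -> QuantileClassing:
    """Equal-count classes by sample quantiles, as in a quantile choropleth.

    Ties share a class; with heavy ties the classing degenerates and a
    warning is emitted.
    """
    x = np.asarray(x, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > x.size:
        raise ValueError(f"k={k} exceeds n={x.size}")
    if np.any(~np.isfinite(x)):
        raise ValueError("x contains missing values")
    breaks = np.quantile(x, np.arange(1, k) / k)
    if np.unique(breaks).size < breaks.size:
        warnings.warn("degenerate quantile breaks (heavy ties); classes collapse")
    classes = np.searchsorted(breaks, x, side="left")
    return QuantileClassing(breaks, classes, k)
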
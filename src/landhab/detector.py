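"""Variance-decomposition attribution of spatial heterogeneity.

The q-statistic of a stratification of an outcome surface is
q = 1 − Σ_h N_h σ_h² / (N σ²) with population variances, i.e. one minus
the within-stratum share of the total sum of squares.  The interaction of
two stratifications is the q of their cross-product strata, classified
against the single-factor q values (weaken / enhance taxonomy).

Continuous drivers are discretized with Jenks natural breaks (exact
dynamic program on ≤ ``_JENKS_MAX_POINTS`` support points; larger inputs
are summarized by quantile bins first), quantiles, or equal intervals.
Significance is assessed with a permutation test rather than a parametric
F approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grid import ContinuousRaster

__all__ = [
    "StrataLayer",
    "QResult",
    "jenks_breaks",
    "discretize",
    "factor_q",
    "interaction_q",
    "interaction_matrix",
]

_JENKS_MAX_POINTS = 640


@dataclass
class StrataLayer:
    """Integer stratum label per cell; −1 marks nodata."""

    labels: np.ndarray
    name: str = ""
    method: str = ""
    breaks: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise TypeError("stratum labels must be integers")

    @property
    def mask(self) -> np.ndarray:
        return self.labels < 0

    @property
    def n_strata(self) -> int:
        return int(len(np.unique(self.labels[~self.mask])))


@dataclass
class QResult:
    q: float
    n: int
    n_h: np.ndarray
    var_h: np.ndarray
    variance: float
    p_value: float | None = None
    interaction: str | None = None


def _weighted_support(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sorted distinct support points with weights, capped for the DP."""
    vals, counts = np.unique(values, return_counts=True)
    if len(vals) <= _JENKS_MAX_POINTS:
        return vals, counts.astype(float)
    # summarize by equal-count bins on the sorted sample
    qs = np.linspace(0, 1, _JENKS_MAX_POINTS + 1)
    edges = np.quantile(values, qs)
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.clip(np.searchsorted(edges, values, side="right") - 1, 0,
                  _JENKS_MAX_POINTS - 1)
    w = np.bincount(idx, minlength=_JENKS_MAX_POINTS).astype(float)
    keep = w > 0
    return centers[keep], w[keep]


def jenks_breaks(values: np.ndarray, n_classes: int) -> np.ndarray:
    """Natural-breaks upper boundaries (length ``n_classes``, last = max).

    Minimizes the within-class weighted sum of squared deviations by exact
    dynamic programming over the distinct-value support.
    """
    values = np.asarray(values, dtype=float).ravel()
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("no finite values to classify")
    pts, w = _weighted_support(values)
    k = min(n_classes, len(pts))
    n = len(pts)
    # prefix sums for O(1) within-class SSD of any run [i, j]
    cw = np.concatenate([[0.0], np.cumsum(w)])
    cwx = np.concatenate([[0.0], np.cumsum(w * pts)])
    cwx2 = np.concatenate([[0.0], np.cumsum(w * pts * pts)])

    def ssd(i: int, j: int) -> np.ndarray:
        """Vector of SSDs of runs [i..j] for all i in the given array."""
        tw = cw[j + 1] - cw[i]
        tx = cwx[j + 1] - cwx[i]
        tx2 = cwx2[j + 1] - cwx2[i]
        with np.errstate(invalid="ignore", divide="ignore"):
            out = tx2 - np.where(tw > 0, tx * tx / tw, 0.0)
        return np.maximum(out, 0.0)

    # dp[c][j]: min SSD of first j+1 points in c+1 classes
    dp = np.full((k, n), np.inf)
    back = np.zeros((k, n), dtype=int)
    dp[0] = np.array([ssd(np.array([0]), j)[0] for j in range(n)])
    for c in range(1, k):
        for j in range(c, n):
            starts = np.arange(c, j + 1)
            cand = dp[c - 1][starts - 1] + ssd(starts, j)
            best = int(np.argmin(cand))
            dp[c][j] = cand[best]
            back[c][j] = starts[best]
    # recover break positions
    bounds = np.empty(k)
    j = n - 1
    for c in range(k - 1, -1, -1):
        bounds[c] = pts[j]
        j = back[c][j] - 1
    return bounds


def discretize(
    x: ContinuousRaster,
    n_classes: int = 7,
    method: str = "jenks",
) -> StrataLayer:
    """Discretize a continuous raster into ordered strata.

    Fewer distinct values than classes degrades gracefully (one stratum per
    value, with a warning).
    """
    vals = x.values[x.valid]
    distinct = np.unique(vals)
    if len(distinct) < n_classes:
        warnings.warn(
            f"{x.name or 'raster'}: only {len(distinct)} distinct values; "
            f"reducing strata from {n_classes}"
        )
        n_classes = max(len(distinct), 1)
    if method == "jenks":
        uppers = jenks_breaks(vals, n_classes)
    elif method == "quantile":
        uppers = np.quantile(vals, np.linspace(0, 1, n_classes + 1)[1:])
    elif method == "equal":
        uppers = np.linspace(vals.min(), vals.max(), n_classes + 1)[1:]
    else:
        raise ValueError(f"unknown discretization method {method!r}")
    uppers = np.unique(uppers)
    labels = np.searchsorted(uppers[:-1], x.values, side="left")
    labels = labels.astype(np.int64)
    labels[x.mask] = -1
    return StrataLayer(labels, name=x.name, method=method, breaks=uppers)


def _q_from_groups(y: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray, float]:
    """(q, N_h, σ_h², σ²) with population variances; labels must be 0..L−1."""
    n = y.size
    n_h = np.bincount(labels)
    sum_h = np.bincount(labels, weights=y)
    sum2_h = np.bincount(labels, weights=y * y)
    keep = n_h > 0
    n_h = n_h[keep]
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_h = sum_h[keep] / n_h
        var_h = sum2_h[keep] / n_h - mean_h**2
    var_h = np.maximum(var_h, 0.0)
    var = float(np.var(y))
    ssw = float((n_h * var_h).sum())
    q = 1.0 - ssw / (n * var)
    return q, n_h, var_h, var


def factor_q(
    y: ContinuousRaster | np.ndarray,
    strata: StrataLayer,
    n_permutations: int = 0,
    seed: int | None = None,
) -> QResult:
    """q-statistic of one stratification, optionally with permutation p."""
    if isinstance(y, ContinuousRaster):
        mask = y.mask | strata.mask
        yv = y.values[~mask]
        lab = strata.labels[~mask]
    else:
        y = np.asarray(y, dtype=float)
        mask = strata.mask
        yv = y[~mask]
        lab = strata.labels[~mask]
    if yv.size < 2:
        raise ValueError("need at least two cells")
    if np.var(yv) == 0:
        raise ValueError("outcome is constant; q undefined")
    _, lab = np.unique(lab, return_inverse=True)
    q, n_h, var_h, var = _q_from_groups(yv, lab)
    p_value = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(lab)
            q_p, *_ = _q_from_groups(yv, perm)
            if q_p >= q:
                hits += 1
        p_value = (hits + 1) / (n_permutations + 1)
    return QResult(q=float(q), n=int(yv.size), n_h=n_h, var_h=var_h,
                   variance=var, p_value=p_value)


def _cross_labels(l1: np.ndarray, l2: np.ndarray) -> np.ndarray:
    _, u1 = np.unique(l1, return_inverse=True)
    _, u2 = np.unique(l2, return_inverse=True)
    return u1 * (u2.max() + 1) + u2


def classify_interaction(q1: float, q2: float, q12: float,
                         tol: float = 1e-9) -> str:
    """Standard two-factor interaction taxonomy."""
    lo, hi = min(q1, q2), max(q1, q2)
    if abs(q12 - (q1 + q2)) <= tol:
        return "independent"
    if q12 > q1 + q2:
        return "nonlinear_enhance"
    if q12 > hi:
        return "bivariate_enhance"
    if q12 >= lo:
        return "single_factor_weaken"
    return "nonlinear_weaken"


def interaction_q(
    y: ContinuousRaster | np.ndarray,
    s1: StrataLayer,
    s2: StrataLayer,
) -> QResult:
    """q of the cross-product stratification, with interaction class."""
    cross = StrataLayer(
        np.where(
            s1.mask | s2.mask, -1, _cross_labels(s1.labels, s2.labels)
        ).astype(np.int64),
        name=f"{s1.name}x{s2.name}",
    )
    r1 = factor_q(y, s1)
    r2 = factor_q(y, s2)
    r12 = factor_q(y, cross)
    r12.interaction = classify_interaction(r1.q, r2.q, r12.q)
    return r12


def interaction_matrix(
    y: ContinuousRaster | np.ndarray, layers: dict[str, StrataLayer]
) -> "pd.DataFrame":
    """Symmetric matrix of pairwise interaction q values (diag = factor q)."""
    import pandas as pd

    names = list(layers)
    out = np.full((len(names), len(names)), np.nan)
    for i, a in enumerate(names):
        out[i, i] = factor_q(y, layers[a]).q
        for j in range(i + 1, len(names)):
            out[i, j] = out[j, i] = interaction_q(y, layers[a], layers[names[j]]).q
    return pd.DataFrame(out, index=names, columns=names)
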
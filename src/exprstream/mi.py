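"""B-spline mutual information and context likelihood of relatedness (CLR).

Mutual information between two expression vectors X and Y is

    I(X;Y) = sum_ij p(x_i, y_j) * log2( p(x_i, y_j) / (p(x_i) p(y_j)) )

where the probability mass functions are estimated by B-spline soft
binning: each observation is linearly mapped from its [min, max] range
onto the spline domain [0, M - k + 1] and spreads unit weight over the M
order-k B-spline basis functions (uniform knots with k-fold endpoint
multiplicity). Marginal bin probabilities are the per-bin mean weights;
the joint is the mean outer product. With spline order k = 1 this reduces
to the classical hard-binned histogram estimator; higher orders share each
observation between up to k adjacent bins, which smooths the density
estimate and reduces the variance of the MI estimate.

MI is reported in bits (log base 2). CLR standardizes each pair's MI
against the background MI distributions of both partners, suppressing
promiscuous features: z_i(j) = max(0, (MI_ij - mu_i) / sigma_i) over
feature i's off-diagonal MI values, and CLR_ij = sqrt(z_i(j)^2 + z_j(i)^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import StatisticError

DEFAULT_M = 10
DEFAULT_K = 3


def _knots(M: int, k: int) -> np.ndarray:
    """Uniform knot vector with k-fold endpoint multiplicity (length M + k)."""
    t = np.empty(M + k, dtype=float)
    t[:k] = 0.0
    t[k:M] = np.arange(1, M - k + 1, dtype=float)
    t[M:] = M - k + 1
    return t


def bspline_weights(values, M: int = DEFAULT_M, k: int = DEFAULT_K) -> np.ndarray:
    """Per-observation B-spline basis weights, shape ``(n, M)``.

    Each row is non-negative and sums to 1 (partition of unity). A constant
    input maps every observation to the same point, so all rows are the
    identical weight vector; MI computed from such weights factorizes to 0.
    """
    if not (M >= k >= 1):
        raise ValueError(f"need M >= k >= 1, got M={M}, k={k}")
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be 1-D")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite (drop missing before weighting)")
    lo, hi = x.min(), x.max()
    top = float(M - k + 1)
    if hi > lo:
        z = (x - lo) * (top / (hi - lo))
    else:
        z = np.zeros_like(x)
    t = _knots(M, k)

    # Cox-de Boor recursion, vectorized over observations.
    n_int = len(t) - 1
    B = np.zeros((x.size, n_int))
    for i in range(n_int):
        if t[i] < t[i + 1]:
            B[:, i] = (z >= t[i]) & (z < t[i + 1])
    # right boundary: z == domain max belongs to the last non-empty interval
    last = max(i for i in range(n_int) if t[i] < t[i + 1])
    B[z >= t[-1], :] = 0.0
    B[z >= t[-1], last] = 1.0
    for order in range(2, k + 1):
        nb = len(t) - order
        Bn = np.zeros((x.size, nb))
        for i in range(nb):
            acc = np.zeros(x.size)
            d1 = t[i + order - 1] - t[i]
            if d1 > 0:
                acc += (z - t[i]) / d1 * B[:, i]
            d2 = t[i + order] - t[i + 1]
            if d2 > 0:
                acc += (t[i + order] - z) / d2 * B[:, i + 1]
            Bn[:, i] = acc
        B = Bn
    return B


@dataclass
class BsplineDensityEstimate:
    """Joint and marginal bin probabilities from B-spline soft binning."""

    M: int
    k: int
    weights_x: np.ndarray
    weights_y: np.ndarray
    p_x: np.ndarray
    p_y: np.ndarray
    p_xy: np.ndarray


@dataclass
class MIResult:
    feature_a: str
    feature_b: str
    mi: float
    M: int
    k: int
    n: int
    low_n: bool = False
    p_raw: float | None = None


def _complete_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def bspline_density(x, y, M: int = DEFAULT_M, k: int = DEFAULT_K) -> BsplineDensityEstimate:
    """Estimate joint and marginal pmfs for a complete (finite) pair of vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    wx = bspline_weights(x, M, k)
    wy = bspline_weights(y, M, k)
    n = x.size
    p_x = wx.mean(axis=0)
    p_y = wy.mean(axis=0)
    p_xy = wx.T @ wy / n
    return BsplineDensityEstimate(M, k, wx, wy, p_x, p_y, p_xy)


def mutual_information(
    x,
    y,
    M: int = DEFAULT_M,
    k: int = DEFAULT_K,
    feature_a: str = "x",
    feature_b: str = "y",
) -> MIResult:
    """B-spline MI estimate in bits, on pairwise-complete observations.

    A constant vector factorizes the joint, so MI is exactly 0. Fewer than
    ``M`` complete observations yields a flagged low-n estimate (warning).
    """
    xc, yc = _complete_pair(x, y)
    n = xc.size
    if n == 0:
        raise StatisticError("no pairwise-complete observations")
    low_n = n < M
    if low_n:
        warnings.warn(
            f"only {n} complete observations for M={M} bins; MI estimate is low-n",
            stacklevel=2,
        )
    if n and (np.all(xc == xc[0]) or np.all(yc == yc[0])):
        return MIResult(feature_a, feature_b, 0.0, M, k, n, low_n)
    est = bspline_density(xc, yc, M, k)
    mi = _mi_from_density(est)
    return MIResult(feature_a, feature_b, mi, M, k, n, low_n)


def _mi_from_density(est: BsplineDensityEstimate) -> float:
    pxy = est.p_xy
    outer = np.outer(est.p_x, est.p_y)
    mask = pxy > 0
    return float(np.sum(pxy[mask] * np.log2(pxy[mask] / outer[mask])))


def mi_permutation_pvalue(
    x, y, B: int = 999, seed: int = 0, M: int = DEFAULT_M, k: int = DEFAULT_K
) -> tuple[float, float]:
    """Permutation p-value for MI: shuffle y, recompute, +1/(B+1) convention.

    Per-permutation RNG is counter-based (Philox keyed by (seed, b)), so a
    partitioned parallel run reproduces the serial stream exactly.
    """
    from .multitest import empirical_pvalue

    xc, yc = _complete_pair(x, y)
    obs = mutual_information(xc, yc, M, k).mi
    null = np.empty(B)
    for b in range(B):
        rng = np.random.Generator(np.random.Philox(key=[seed, b]))
        null[b] = mutual_information(xc, rng.permutation(yc), M, k).mi
    return obs, empirical_pvalue(obs, null)


# ----------------------------------------------------------------------
@dataclass
class CLRResult:
    feature_a: str
    feature_b: str
    mi: float
    z_a: float
    z_b: float
    clr: float


def mi_matrix(vectors: dict, M: int = DEFAULT_M, k: int = DEFAULT_K) -> pd.DataFrame:
    """Symmetric pairwise-MI matrix over a dict of ``{feature_id: values}``.

    The diagonal is NaN (self-MI is excluded from CLR backgrounds).
    """
    ids = list(vectors)
    m = len(ids)
    out = np.full((m, m), np.nan)
    for i in range(m):
        for j in range(i + 1, m):
            mi = mutual_information(vectors[ids[i]], vectors[ids[j]], M, k).mi
            out[i, j] = out[j, i] = mi
    return pd.DataFrame(out, index=ids, columns=ids)


def clr(mi_df: pd.DataFrame) -> pd.DataFrame:
    """CLR matrix from a symmetric MI matrix (diagonal ignored).

    Each feature's background mean/sd is over its off-diagonal MI values;
    z-scores are clamped at 0, and a zero-variance background yields z = 0
    (documented degenerate case, not an error).
    """
    a = mi_df.to_numpy(dtype=float).copy()
    if a.shape[0] != a.shape[1]:
        raise ValueError("MI matrix must be square")
    if not np.allclose(a, a.T, equal_nan=True):
        raise ValueError("MI matrix must be symmetric")
    np.fill_diagonal(a, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(a, axis=1)
        sd = np.nanstd(a, axis=1)
    m = a.shape[0]
    z = np.zeros((m, m))
    nz = sd > 0
    z[nz, :] = (a[nz, :] - mu[nz, None]) / sd[nz, None]
    z = np.where(np.isnan(a), 0.0, np.maximum(z, 0.0))
    c = np.sqrt(z**2 + z.T**2)
    np.fill_diagonal(c, 0.0)
    return pd.DataFrame(c, index=mi_df.index, columns=mi_df.columns)
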
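"""Shared statistical primitives: Pearson correlation, BH step-up FDR, two-sample t.

These are deliberately small, explicit implementations so that every number
the pipeline reports can be traced to a formula. Tail areas come from
scipy's t distribution; everything else is plain arithmetic.

Conventions
-----------
* Sample standard deviations use the n-1 denominator throughout.
* A Pearson p-value needs n >= 4 (t reference with n-2 df); below that it is
  reported as ``None`` rather than an uninterpretable 1-df value.
* Benjamini-Hochberg ties receive equal adjusted values (a consequence of
  the suffix-minimum formulation; no randomized tie-breaking).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as _sps

__all__ = ["PearsonResult", "TTestResult", "pearson", "bh_adjust", "two_sample_t"]


@dataclass(frozen=True)
class PearsonResult:
    """Product-moment correlation with its two-sided p-value.

    ``p`` is ``None`` when fewer than 4 observations were available.
    """

    r: float
    p: float | None
    n: int


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    variant: str


def _as_1d(v: Sequence[float] | np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if np.isnan(arr).any():
        raise ValueError(f"{name} contains NaN")
    return arr


def pearson(x: Sequence[float], y: Sequence[float]) -> PearsonResult:
    """Pearson product-moment correlation of two equal-length vectors.

    Parameters
    ----------
    x, y
        Numeric vectors of equal length n >= 3. Neither may be constant.

    Returns
    -------
    PearsonResult
        ``r`` in [-1, 1]; ``p`` is the two-sided tail area of
        t = r * sqrt((n-2)/(1-r^2)) under a t distribution with n-2 degrees
        of freedom when n >= 4, and ``None`` when n == 3.

    Raises
    ------
    ValueError
        On length mismatch, n < 3, or a constant input vector.
    """
    xa = _as_1d(x, "x")
    ya = _as_1d(y, "y")
    if xa.size != ya.size:
        raise ValueError(f"length mismatch: {xa.size} vs {ya.size}")
    n = xa.size
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    dx = xa - xa.mean()
    dy = ya - ya.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0.0:
        raise ValueError("x is constant; correlation undefined")
    if syy == 0.0:
        raise ValueError("y is constant; correlation undefined")
    r = float(dx @ dy) / math.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    if n < 4:
        return PearsonResult(r=r, p=None, n=n)
    # two-sided p from the t reference distribution with n-2 df
    denom = 1.0 - r * r
    if denom <= 0.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / denom)
        p = float(2.0 * _sps.t.sf(abs(t), n - 2))
    return PearsonResult(r=r, p=min(p, 1.0), n=n)


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min_{j >= i} ( p_(j) * m / j ), capped at 1, where p_(1) <= ...
    <= p_(m) is the sorted vector; values are mapped back to the caller's
    order. Equal raw p-values receive equal adjusted values.

    Raises
    ------
    ValueError
        If any value falls outside [0, 1] (or is NaN).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError(f"p-values must be one-dimensional, got shape {p.shape}")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adj_sorted
    return out


def two_sample_t(
    x: Sequence[float],
    y: Sequence[float],
    variant: Literal["welch", "student"] = "welch",
) -> TTestResult:
    """Two-tailed unpaired t test.

    ``welch`` (default) uses the unequal-variance statistic with
    Welch-Satterthwaite degrees of freedom; ``student`` pools variances.
    Degenerate inputs where both groups are constant and equal return
    t = 0, p = 1; constant unequal groups return an infinite t with p = 0.
    """
    xa = _as_1d(x, "x")
    ya = _as_1d(y, "y")
    nx, ny = xa.size, ya.size
    if nx < 2 or ny < 2:
        raise ValueError(f"each group needs >= 2 observations, got {nx} and {ny}")
    if variant not in ("welch", "student"):
        raise ValueError(f"unknown variant {variant!r}")
    mx, my = xa.mean(), ya.mean()
    vx = float(xa.var(ddof=1))
    vy = float(ya.var(ddof=1))
    diff = mx - my
    if variant == "welch":
        se2 = vx / nx + vy / ny
        if se2 == 0.0:
            t = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
            df = float(nx + ny - 2)
        else:
            t = diff / math.sqrt(se2)
            df = se2**2 / (
                (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
            )
    else:
        df = float(nx + ny - 2)
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / df
        se2 = sp2 * (1.0 / nx + 1.0 / ny)
        if se2 == 0.0:
            t = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
        else:
            t = diff / math.sqrt(se2)
    if math.isinf(t):
        p = 0.0
    else:
        p = float(2.0 * _sps.t.sf(abs(t), df))
    return TTestResult(t=float(t), df=float(df), p=min(p, 1.0), variant=variant)
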
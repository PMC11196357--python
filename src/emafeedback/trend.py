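"""LOESS smoothing for idiographic time series.

LOESS (locally estimated scatterplot smoothing) fits, at every
evaluation point, a weighted least-squares line over the k nearest
observations in time, with tricube weights

    w_i = (1 - (d_i / d_max)^3)^3,   d_i = |x_i - x0|,

where k = ceil(span * n) is set by the span (smoothing) parameter in
(0, 1]. Points tied with the k-th nearest distance are all included.
No robustness iterations are performed; the local fit is linear
(degree 1), which reproduces globally linear data exactly.

Series with too few observations are gated out and shown as raw
scatterplots instead of smoothed trendlines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

DEFAULT_SPAN = 0.5
DEFAULT_MIN_OBS = 20


@dataclass
class TrendEstimate:
    grid: np.ndarray
    fitted: np.ndarray | None
    span: float
    degree: int
    gated_out: bool
    n_obs: int


def trend_gate(n_obs: int, min_n: int = DEFAULT_MIN_OBS) -> bool:
    """True when a smoothed trendline may be fit (n_obs >= min_n)."""
    return n_obs >= min_n


def _local_fit(x: np.ndarray, y: np.ndarray, x0: float, k: int, degree: int) -> float:
    d = np.abs(x - x0)
    dmax = np.sort(d)[k - 1]
    if dmax == 0.0:
        # all nearest neighbours sit exactly at x0: plain mean
        sel = d == 0.0
        return float(y[sel].mean())
    sel = d <= dmax  # distance ties include all tied points
    u = d[sel] / dmax
    w = (1.0 - u**3) ** 3
    X = np.vander(x[sel] - x0, N=degree + 1, increasing=True)
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y[sel] * sw, rcond=None)
    return float(beta[0])  # value of the local polynomial at x0


def loess_fit(
    x: np.ndarray,
    y: np.ndarray,
    span: float = DEFAULT_SPAN,
    degree: int = 1,
    grid: np.ndarray | None = None,
    min_n: int = DEFAULT_MIN_OBS,
) -> TrendEstimate:
    """Fit a LOESS trend of ``y`` on ``x``.

    Parameters
    ----------
    x, y : arrays
        Observation times and values; non-finite pairs are dropped and
        the remainder sorted by ``x``.
    span : float in (0, 1]
        Fraction of the data in each local neighbourhood.
    degree : int
        Local polynomial degree (default 1, local linear).
    grid : array, optional
        Evaluation times; defaults to the observation times.
    min_n : int
        Data-sufficiency gate: below this many observations no trend is
        fit and ``gated_out`` is True.
    """
    if not (0.0 < span <= 1.0):
        raise ParameterError(f"span must be in (0, 1], got {span}")
    if degree < 0:
        raise ParameterError(f"degree must be >= 0, got {degree}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    n = len(x)
    if grid is None:
        grid = x.copy()
    else:
        grid = np.asarray(grid, dtype=float)

    k = max(int(math.ceil(span * n)), degree + 2) if n else 0
    if not trend_gate(n, min_n) or n < max(degree + 2, k):
        return TrendEstimate(
            grid=grid, fitted=None, span=span, degree=degree, gated_out=True, n_obs=n
        )
    fitted = np.array([_local_fit(x, y, x0, k, degree) for x0 in grid])
    return TrendEstimate(
        grid=grid, fitted=fitted, span=span, degree=degree, gated_out=False, n_obs=n
    )
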
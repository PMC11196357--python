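"""Kalman-filter imputation of missing EMA observations.

Missing values are filled, per variable, with the posterior mean of a
local-level linear-Gaussian state-space model

    level:        mu_t = mu_{t-1} + w_t,   w_t ~ N(0, q)
    observation:  y_t  = mu_t     + v_t,   v_t ~ N(0, r)

fitted by maximum likelihood (bounded quasi-Newton over log-variances,
with a fixed deterministic start: r0 = sample variance / 2,
q0 = sample variance / 10) and smoothed with the Rauch-Tung-Striebel
recursions. Imputed values are clipped to the item's scale bounds;
observed entries are never modified.

Imputation feeds the network design matrices only; descriptives and
trends always show raw data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .errors import InsufficientDataError

MIN_OBSERVED = 5


@dataclass
class ImputationResult:
    series: np.ndarray
    imputed_mask: np.ndarray
    model_loglik: float
    obs_variance: float
    level_variance: float


def kalman_filter_loglik(
    y: np.ndarray, q: float, r: float, mu0: float, p0: float
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Forward pass of the local-level Kalman filter.

    ``y`` may contain NaN (missing: prediction step only). Returns
    (loglik, filtered means, filtered variances, predicted means,
    predicted variances).
    """
    n = len(y)
    m_pred = np.empty(n)
    p_pred = np.empty(n)
    m_filt = np.empty(n)
    p_filt = np.empty(n)
    ll = 0.0
    m, p = mu0, p0
    for t in range(n):
        if t > 0:
            p = p + q
        m_pred[t], p_pred[t] = m, p
        if np.isfinite(y[t]):
            f = p + r
            innov = y[t] - m
            ll += -0.5 * (np.log(2.0 * np.pi * f) + innov * innov / f)
            gain = p / f
            m = m + gain * innov
            p = p * (1.0 - gain)
        m_filt[t], p_filt[t] = m, p
    return ll, m_filt, p_filt, m_pred, p_pred


def kalman_smooth(
    y: np.ndarray, q: float, r: float, mu0: float, p0: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Rauch-Tung-Striebel smoother for the local-level model.

    Returns (smoothed means, smoothed variances, loglik).
    """
    ll, m_f, p_f, m_p, p_p = kalman_filter_loglik(y, q, r, mu0, p0)
    n = len(y)
    m_s = np.empty(n)
    p_s = np.empty(n)
    m_s[-1], p_s[-1] = m_f[-1], p_f[-1]
    for t in range(n - 2, -1, -1):
        c = p_f[t] / p_p[t + 1] if p_p[t + 1] > 0 else 0.0
        m_s[t] = m_f[t] + c * (m_s[t + 1] - m_p[t + 1])
        p_s[t] = p_f[t] + c * c * (p_s[t + 1] - p_p[t + 1])
    return m_s, p_s, ll


def fit_local_level(y: np.ndarray) -> tuple[float, float, float, float, float]:
    """ML fit of (q, r) for a local-level model on a series with gaps.

    Initial state: mean of observed values with a large (diffuse-like)
    variance tied to the sample variance. Returns (q, r, mu0, p0, ll).
    """
    obs = y[np.isfinite(y)]
    var = float(obs.var(ddof=1)) if len(obs) > 1 else 1.0
    var = max(var, 1e-6)
    mu0 = float(obs.mean())
    p0 = 1e4 * var

    def nll(theta: np.ndarray) -> float:
        q, r = np.exp(theta)
        ll, *_ = kalman_filter_loglik(y, q, r, mu0, p0)
        return -ll

    x0 = np.log([var / 10.0, var / 2.0])
    bounds = [(np.log(var * 1e-8), np.log(var * 1e3))] * 2
    res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
    q, r = np.exp(res.x)
    return float(q), float(r), mu0, p0, -float(res.fun)


def kalman_impute(
    series_with_gaps: np.ndarray, scale_bounds: tuple[float, float]
) -> ImputationResult:
    """Fill NaN entries with the Kalman smoother's posterior mean.

    Requires at least 5 observed values. Imputations are clipped to
    ``scale_bounds``; observed entries are returned bitwise unchanged.
    """
    y = np.asarray(series_with_gaps, dtype=float)
    mask = ~np.isfinite(y)
    n_obs = int((~mask).sum())
    if n_obs < MIN_OBSERVED:
        raise InsufficientDataError(
            f"kalman_impute needs >= {MIN_OBSERVED} observed values, have {n_obs}"
        )
    q, r, mu0, p0, ll = fit_local_level(y)
    m_s, _, _ = kalman_smooth(y, q, r, mu0, p0)
    lo, hi = scale_bounds
    out = y.copy()
    out[mask] = np.clip(m_s[mask], lo, hi)
    return ImputationResult(
        series=out,
        imputed_mask=mask,
        model_loglik=ll,
        obs_variance=r,
        level_variance=q,
    )
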
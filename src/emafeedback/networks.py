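"""Regularized lag-1 VAR models and contemporaneous partial-correlation
networks for single participants.

The model is X_t = B X_{t-1} + eps_t with sparse B and sparse residual
precision K = Cov(eps)^-1. Estimation is a two-stage composition:

1. per-outcome lasso regressions of X_t on all lag-1 predictors over a
   descending penalty grid, penalty selected by the extended BIC (EBIC,
   sparsity parameter gamma); selected coefficients are refit without
   penalty on the active set to de-bias them;
2. graphical lasso on the covariance of the stage-1 residuals, again
   over a penalty grid with EBIC selection, yielding K.

The reported network is the matrix of partial correlations
omega_ij = -kappa_ij / sqrt(kappa_ii kappa_jj): undirected same-occasion
associations after removing lag-1 carry-over. Two variants exist: the
*daily* network pairs consecutive within-day prompts (lag ~ 4 h; never
across nights), the *evening* network pairs consecutive calendar
evenings (lag 24 h).

Networks are only estimated for participants who completed strictly
more than 50% of the relevant surveys, and variables are pre-selected
by per-participant normality (lowest |skewness| + |excess kurtosis|).
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import graphical_lasso
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import lasso_path

from .codebook import DAILY_SLOTS, ResponseTable
from .errors import EstimationError, InsufficientDataError

DEFAULT_EBIC_GAMMA = 0.5
N_PENALTIES = 50
PENALTY_FLOOR = 0.01  # grid runs from lambda_max down to this fraction of it
EDGE_EPS = 1e-8
MIN_PAIRS = 30


def network_gate(completion_fraction: float) -> bool:
    """Strictly-more-than-50% completion gate for network estimation."""
    return completion_fraction > 0.5


def select_network_variables(
    table: ResponseTable, candidates: list[str], k: int
) -> tuple[list[str], bool]:
    """Pick the k most normally distributed candidates for a participant.

    Normality distance d = |skewness| + |excess kurtosis|, computed on
    the participant's observed values; lower is more normal. Ties break
    alphabetically. Returns (selection, all_requested) where the flag is
    False when fewer than k candidates were eligible.
    """
    scored = []
    for name in sorted(candidates):
        vals = pd.to_numeric(table.values_for(name)).to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < 20:
            continue
        d = abs(float(stats.skew(vals))) + abs(float(stats.kurtosis(vals)))
        scored.append((d, name))
    scored.sort()
    chosen = [name for _, name in scored[:k]]
    return chosen, len(scored) >= k


@dataclass
class LagDesign:
    """Stacked (X_{t-1}, X_t) rows for one participant and mode."""

    variables: list[str]
    predictors: np.ndarray  # rows of X_{t-1}
    outcomes: np.ndarray  # rows of X_t
    pair_times: list[tuple[tuple[dt.date, str], tuple[dt.date, str]]]
    mode: str

    @property
    def n_pairs(self) -> int:
        return len(self.pair_times)


@dataclass
class ContemporaneousNetwork:
    variables: list[str]
    beta: np.ndarray  # p x p temporal coefficients (row = outcome)
    kappa: np.ndarray  # p x p residual precision
    pcor: np.ndarray  # p x p partial correlations, zero diagonal
    mode: str
    n_effective: int
    gate_passed: bool = True

    def edges(self) -> list[tuple[str, str, float]]:
        """Nonzero upper-triangle edges as (node_i, node_j, pcor)."""
        out = []
        p = len(self.variables)
        for i in range(p):
            for j in range(i + 1, p):
                w = self.pcor[i, j]
                if abs(w) >= EDGE_EPS:
                    out.append((self.variables[i], self.variables[j], float(w)))
        return out

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {"node_i": a, "node_j": b, "pcor": w, "sign": "+" if w > 0 else "-"}
            for a, b, w in self.edges()
        ]
        return pd.DataFrame(rows, columns=["node_i", "node_j", "pcor", "sign"])


def build_panel(
    table: ResponseTable,
    variables: list[str],
    participant: str | None = None,
) -> pd.DataFrame:
    """Wide (date, slot) x variable panel of numeric responses."""
    df = table.records
    if participant is not None:
        df = df[df["participant_key"] == participant]
    sub = df[df["variable"].isin(variables)].copy()
    sub["value"] = pd.to_numeric(sub["value"])
    panel = sub.pivot_table(
        index=["date", "slot"], columns="variable", values="value", aggfunc="first"
    )
    return panel.reindex(columns=variables)


def impute_panel(panel: pd.DataFrame, schedule_keys: list[tuple[dt.date, str]],
                 scale_bounds: dict[str, tuple[float, float]]) -> pd.DataFrame:
    """Expand a panel to the full prompt grid and Kalman-impute each column."""
    from .imputation import kalman_impute

    idx = pd.MultiIndex.from_tuples(schedule_keys, names=["date", "slot"])
    full = panel.reindex(idx)
    out = full.copy()
    for col in full.columns:
        series = full[col].to_numpy(dtype=float)
        res = kalman_impute(series, scale_bounds[col])
        out[col] = res.series
    return out


def lagged_pairs(
    panel: pd.DataFrame, variables: list[str], mode: str
) -> LagDesign:
    """Build the lag-1 design for one participant.

    ``panel`` is a (date, slot)-indexed wide frame (typically imputed).
    Daily mode pairs consecutive slots within the same calendar day only
    (morning->noon, noon->afternoon, afternoon->evening); evening mode
    pairs evenings of consecutive calendar days (gap exactly 1 day).
    Rows with missing values in either member are dropped.
    """
    if mode not in ("daily", "evening"):
        raise ValueError(f"unknown mode {mode!r}")
    panel = panel.reindex(columns=variables)
    rows = {key: panel.loc[key].to_numpy(dtype=float) for key in panel.index}

    pairs: list[tuple[tuple[dt.date, str], tuple[dt.date, str]]] = []
    if mode == "daily":
        dates = sorted({d for d, _ in rows})
        for d in dates:
            for a, b in zip(DAILY_SLOTS[:-1], DAILY_SLOTS[1:]):
                if (d, a) in rows and (d, b) in rows:
                    pairs.append(((d, a), (d, b)))
    else:
        evenings = sorted(d for d, s in rows if s == "evening")
        for d0, d1 in zip(evenings[:-1], evenings[1:]):
            if (d1 - d0).days == 1:
                pairs.append(((d0, "evening"), (d1, "evening")))

    X_prev, X_next, kept = [], [], []
    for prev_key, next_key in pairs:
        xp, xn = rows[prev_key], rows[next_key]
        if np.all(np.isfinite(xp)) and np.all(np.isfinite(xn)):
            X_prev.append(xp)
            X_next.append(xn)
            kept.append((prev_key, next_key))
    if not kept:
        raise InsufficientDataError(f"no eligible lag-1 pairs in {mode} mode")
    return LagDesign(
        variables=list(variables),
        predictors=np.array(X_prev),
        outcomes=np.array(X_next),
        pair_times=kept,
        mode=mode,
    )


def _standardize(m: np.ndarray) -> np.ndarray:
    mu = m.mean(axis=0)
    sd = m.std(axis=0, ddof=0)
    if np.any(sd < 1e-12):
        bad = [i for i, s in enumerate(sd) if s < 1e-12]
        raise EstimationError(f"constant variables in design (columns {bad})")
    return (m - mu) / sd


def _ebic_regression(rss: float, n: int, k: int, p: int, gamma: float) -> float:
    rss = max(rss, 1e-12)
    return n * np.log(rss / n) + k * np.log(n) + 2.0 * gamma * k * np.log(p)


def _lasso_ebic_row(
    X: np.ndarray, y: np.ndarray, gamma: float
) -> np.ndarray:
    """One VAR equation: lasso path + EBIC selection + OLS refit."""
    n, p = X.shape
    lam_max = np.max(np.abs(X.T @ y)) / n
    if lam_max <= 0:
        return np.zeros(p)
    alphas = np.geomspace(lam_max, PENALTY_FLOOR * lam_max, N_PENALTIES)
    _, coefs, _ = lasso_path(X, y, alphas=alphas)
    best_score, best_beta = np.inf, np.zeros(p)
    seen: set[tuple[int, ...]] = set()
    for j in range(coefs.shape[1]):
        active = tuple(np.nonzero(np.abs(coefs[:, j]) > 1e-10)[0])
        if active in seen:
            continue
        seen.add(active)
        beta = np.zeros(p)
        if active:
            Xa = X[:, list(active)]
            sol, *_ = np.linalg.lstsq(Xa, y, rcond=None)
            beta[list(active)] = sol
        rss = float(np.sum((y - X @ beta) ** 2))
        score = _ebic_regression(rss, n, len(active), p, gamma)
        if score < best_score:
            best_score, best_beta = score, beta
    return best_beta


def _ebic_glasso(S: np.ndarray, n: int, gamma: float) -> np.ndarray:
    """Graphical lasso over a penalty grid with EBIC model selection."""
    p = S.shape[0]
    off = np.abs(S - np.diag(np.diag(S)))
    alpha_max = max(off.max(), 1e-4)
    alphas = np.geomspace(alpha_max, PENALTY_FLOOR * alpha_max, N_PENALTIES)
    best_score, best_K = np.inf, None
    diagnostics = []
    for alpha in alphas:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                _, K = graphical_lasso(S, alpha=float(alpha), max_iter=200)
        except FloatingPointError as exc:  # pragma: no cover - rare
            diagnostics.append((float(alpha), str(exc)))
            continue
        sign, logdet = np.linalg.slogdet(K)
        if sign <= 0:
            diagnostics.append((float(alpha), "non-PD precision"))
            continue
        n_edges = int(np.sum(np.abs(np.triu(K, 1)) > EDGE_EPS))
        ll = (n / 2.0) * (logdet - np.trace(S @ K))
        score = -2.0 * ll + n_edges * np.log(n) + 4.0 * n_edges * gamma * np.log(p)
        if score < best_score:
            best_score, best_K = score, K
    if best_K is None:
        raise EstimationError(f"graphical lasso failed on entire grid: {diagnostics}")
    return best_K


def precision_to_pcor(K: np.ndarray) -> np.ndarray:
    """Partial correlations omega_ij = -kappa_ij / sqrt(kappa_ii kappa_jj)."""
    d = np.sqrt(np.diag(K))
    omega = -K / np.outer(d, d)
    omega = (omega + omega.T) / 2.0
    np.fill_diagonal(omega, 0.0)
    omega[np.abs(omega) < EDGE_EPS] = 0.0
    return omega


def estimate_var_contemporaneous(
    design: LagDesign, ebic_gamma: float = DEFAULT_EBIC_GAMMA
) -> ContemporaneousNetwork:
    """Two-stage sparse VAR(1) + graphical-lasso network estimate.

    Requires at least 30 lag pairs; variables are standardized to mean 0
    and unit variance over the rows used before penalized estimation
    (penalties are not scale-free, partial correlations are).
    """
    if design.n_pairs < MIN_PAIRS:
        raise InsufficientDataError(
            f"need >= {MIN_PAIRS} lag pairs, have {design.n_pairs}"
        )
    X = _standardize(design.predictors)
    Y = _standardize(design.outcomes)
    n, p = X.shape

    B = np.vstack(
        [_lasso_ebic_row(X, Y[:, j], ebic_gamma) for j in range(p)]
    )
    resid = Y - X @ B.T
    S = np.cov(resid, rowvar=False, ddof=0)
    cond = np.linalg.cond(S)
    if not np.isfinite(cond) or cond > 1e10:
        sds = np.sqrt(np.diag(S))
        bad = [design.variables[i] for i in np.argsort(sds)[:2]]
        raise EstimationError(
            f"degenerate residual covariance (condition {cond:.2e}); "
            f"check variables {bad}"
        )
    K = _ebic_glasso(S, n, ebic_gamma)
    K = (K + K.T) / 2.0
    return ContemporaneousNetwork(
        variables=list(design.variables),
        beta=B,
        kappa=K,
        pcor=precision_to_pcor(K),
        mode=design.mode,
        n_effective=n,
    )


@dataclass
class PlausibilityReport:
    """Cohort-level edge-sign sanity check.

    Within-class associations between negative affect items (NA-NA) and
    between positive affect items (PA-PA) are expected positive;
    cross-class (PA-NA) associations are expected negative. Only
    nonzero estimated edges are counted.
    """

    classes: dict[str, tuple[int, int, float]] = field(default_factory=dict)
    empty_pool: bool = False

    def proportion(self, cls: str) -> float:
        return self.classes[cls][2]


EXPECTED_SIGN = {"NA-NA": 1, "PA-PA": 1, "PA-NA": -1}


def edge_sign_plausibility(
    networks: list[ContemporaneousNetwork],
    pa_items: set[str],
    na_items: set[str],
) -> PlausibilityReport:
    """Pool nonzero edges over networks and count sign deviations per class."""
    counts = {c: [0, 0] for c in EXPECTED_SIGN}  # class -> [n_edges, n_deviating]
    for net in networks:
        for a, b, w in net.edges():
            if a in pa_items and b in pa_items:
                cls = "PA-PA"
            elif a in na_items and b in na_items:
                cls = "NA-NA"
            elif (a in pa_items and b in na_items) or (
                a in na_items and b in pa_items
            ):
                cls = "PA-NA"
            else:
                continue
            counts[cls][0] += 1
            if np.sign(w) != EXPECTED_SIGN[cls]:
                counts[cls][1] += 1
    classes = {
        c: (n, d, (d / n if n else 0.0)) for c, (n, d) in counts.items()
    }
    total = sum(n for n, _, _ in classes.values())
    return PlausibilityReport(classes=classes, empty_pool=total == 0)
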
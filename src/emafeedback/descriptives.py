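"""Descriptive report content: item means, relative frequencies,
peak-affect prompt, and best/worst recap weeks.

These summaries deliberately stay at raw-data level: means use only
observed values (no imputation), frequencies are simple shares, and the
display jitter applied to scatterplot points never touches stored
values. Ties are always broken toward earlier dates so reports are
deterministic.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codebook import DAILY_SLOTS, ResponseTable, VariableCodebook
from .errors import InsufficientDataError, ParameterError

#: fixed slot ordering for tie-breaks within a date
_SLOT_ORDER = {s: i for i, s in enumerate(DAILY_SLOTS + ("weekly",))}

JITTER_AMPLITUDE = 0.25  # scale units, display only


@dataclass
class ItemSummary:
    variable: str
    n_obs: int
    mean: float  # nan when n_obs == 0
    values_with_jitter: list[tuple[pd.Timestamp, float]]

    @property
    def has_mean(self) -> bool:
        return self.n_obs > 0


@dataclass
class RelFreqTable:
    variable: str
    n_obs: int
    frequencies: dict[str, float]


@dataclass
class PeakAffect:
    """The prompt, day, and slot with the highest mean positive affect."""

    prompt: tuple[dt.date, str]
    prompt_mean: float
    best_day: dt.date
    best_day_mean: float
    best_slot: str
    best_slot_mean: float


@dataclass
class RecapResult:
    best_week: tuple[dt.date, dt.date]
    worst_week: tuple[dt.date, dt.date]
    best_week_mean: float
    worst_week_mean: float
    overall_mean: float


def _likert_records(
    table: ResponseTable, variables: list[str]
) -> pd.DataFrame:
    df = table.records
    sub = df[df["variable"].isin(variables)].copy()
    sub["value"] = pd.to_numeric(sub["value"])
    return sub


def continuous_summary(
    table: ResponseTable,
    variables: list[str],
    codebook: VariableCodebook | None = None,
    jitter_seed: int = 0,
) -> list[ItemSummary]:
    """Arithmetic means over observed values plus jittered display points.

    Jitter is uniform in ±0.25 scale units and exists only in the
    returned display copies. A variable without observations yields
    ``n_obs == 0`` and a NaN mean rather than an error.
    """
    if codebook is not None:
        for v in variables:
            if codebook[v].kind != "likert":
                raise ParameterError(f"{v} is not a likert item")
    rng = np.random.default_rng(jitter_seed)
    out = []
    for var in variables:
        sub = _likert_records(table, [var])
        n = len(sub)
        mean = float(sub["value"].mean()) if n else float("nan")
        jitter = rng.uniform(-JITTER_AMPLITUDE, JITTER_AMPLITUDE, size=n)
        pts = [
            (ts, float(v) + j)
            for ts, v, j in zip(sub["timestamp"], sub["value"], jitter)
        ]
        out.append(ItemSummary(variable=var, n_obs=n, mean=mean, values_with_jitter=pts))
    return out


def categorical_frequencies(
    table: ResponseTable, variable: str, codebook: VariableCodebook | None = None
) -> RelFreqTable:
    """Relative frequency of each category; zero-count categories included."""
    categories: list[str] = []
    if codebook is not None:
        spec = codebook[variable]
        if spec.kind != "categorical":
            raise ParameterError(f"{variable} is not categorical")
        categories = list(spec.categories)
    values = table.values_for(variable).astype(str)
    n = len(values)
    counts = values.value_counts()
    all_cats = categories or sorted(counts.index.tolist())
    freqs = {c: (counts.get(c, 0) / n if n else 0.0) for c in all_cats}
    return RelFreqTable(variable=variable, n_obs=n, frequencies=freqs)


def _prompt_means(table: ResponseTable, items: list[str]) -> pd.DataFrame:
    """Mean over the given likert items per (date, slot) prompt."""
    sub = _likert_records(table, items)
    if sub.empty:
        raise InsufficientDataError("no observations on the requested affect items")
    g = sub.groupby(["date", "slot"], as_index=False)["value"].mean()
    g["slot_order"] = g["slot"].map(_SLOT_ORDER)
    return g


def peak_affect(table: ResponseTable, positive_items: list[str]) -> PeakAffect:
    """Find the prompt with the highest mean positive affect.

    Also reports the best day (mean over all that day's positive-item
    observations) and the best slot (mean pooled across days). Ties go
    to the earlier date, then the earlier slot in the daily ordering.
    """
    g = _prompt_means(table, positive_items)
    g = g.sort_values(["date", "slot_order"], kind="stable")
    i_best = g["value"].values.argmax()  # argmax: first occurrence wins the tie
    row = g.iloc[i_best]

    sub = _likert_records(table, positive_items)
    day_means = sub.groupby("date")["value"].mean().sort_index()
    best_day = day_means.index[day_means.values.argmax()]
    slot_means = sub.groupby("slot")["value"].mean()
    slot_means = slot_means.reindex(
        [s for s in DAILY_SLOTS + ("weekly",) if s in slot_means.index]
    )
    best_slot = slot_means.index[slot_means.values.argmax()]
    return PeakAffect(
        prompt=(row["date"], row["slot"]),
        prompt_mean=float(row["value"]),
        best_day=best_day,
        best_day_mean=float(day_means.max()),
        best_slot=str(best_slot),
        best_slot_mean=float(slot_means.max()),
    )


def week_start_of(day: dt.date, week_start: int = 0) -> dt.date:
    """Start date of the fixed calendar week containing ``day``."""
    return day - dt.timedelta(days=(day.weekday() - week_start) % 7)


def recap_weeks(
    table: ResponseTable,
    positive_items: list[str],
    week_start: int = 0,
    min_obs_per_week: int = 4,
) -> RecapResult:
    """Best and worst calendar weeks by mean positive affect.

    Weeks are fixed blocks (default Monday..Sunday). A week qualifies
    when it holds at least ``min_obs_per_week`` positive-item
    observations. Requires >= 2 qualifying weeks; ties prefer the
    earliest week.
    """
    sub = _likert_records(table, positive_items)
    if sub.empty:
        raise InsufficientDataError("no positive-affect observations")
    sub["week"] = sub["date"].map(lambda d: week_start_of(d, week_start))
    stats = sub.groupby("week")["value"].agg(["mean", "count"])
    qual = stats[stats["count"] >= min_obs_per_week].sort_index()
    if len(qual) < 2:
        raise InsufficientDataError(
            f"need >= 2 weeks with >= {min_obs_per_week} observations, "
            f"have {len(qual)}"
        )
    means = qual["mean"].values
    best_w = qual.index[means.argmax()]
    worst_w = qual.index[means.argmin()]
    span = dt.timedelta(days=6)
    return RecapResult(
        best_week=(best_w, best_w + span),
        worst_week=(worst_w, worst_w + span),
        best_week_mean=float(means.max()),
        worst_week_mean=float(means.min()),
        overall_mean=float(sub["value"].mean()),
    )


def filter_week(table: ResponseTable, week: tuple[dt.date, dt.date]) -> ResponseTable:
    """Restrict a table to one calendar week (for week-specific recaps)."""
    start, end = week
    df = table.records
    mask = (df["date"] >= start) & (df["date"] <= end)
    return ResponseTable(df[mask].reset_index(drop=True))
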
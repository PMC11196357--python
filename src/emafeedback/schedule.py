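"""Prompt schedules and compliance analytics.

An EMA study window is covered by four semi-random daily prompts
(morning, noon, afternoon, evening) plus one weekly prompt on a fixed
weekday (default Sunday, attached to the evening window). For the
85-day study window 2021-12-06..2022-02-28 this yields
4 x 85 + 12 = 352 scheduled prompts.

Compliance is prompt-level: a scheduled prompt counts as completed when
at least one response record exists for its (date, slot), regardless of
how many items were answered.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .codebook import DAILY_SLOTS, ResponseTable
from .errors import ParameterError

#: Default clock-time windows for each slot (start, end), local time.
DEFAULT_SLOT_WINDOWS: dict[str, tuple[dt.time, dt.time]] = {
    "morning": (dt.time(8, 0), dt.time(11, 0)),
    "noon": (dt.time(11, 30), dt.time(14, 30)),
    "afternoon": (dt.time(15, 0), dt.time(18, 0)),
    "evening": (dt.time(18, 30), dt.time(21, 30)),
    # the weekly survey rides along with the evening prompt window
    "weekly": (dt.time(18, 30), dt.time(21, 30)),
}

SUNDAY = 6  # datetime.date.weekday() convention (Monday == 0)


@dataclass
class EMASchedule:
    """All scheduled prompts for one study window.

    ``prompts`` columns: date (datetime.date), slot (str), window_start,
    window_end (datetime.time), drawn_time (datetime.time) — the
    semi-random send time drawn uniformly within the window.
    """

    prompts: pd.DataFrame

    def __len__(self) -> int:
        return len(self.prompts)

    def dates(self) -> list[dt.date]:
        return sorted(self.prompts["date"].unique().tolist())

    def slots(self) -> list[str]:
        order = list(DAILY_SLOTS) + ["weekly"]
        present = set(self.prompts["slot"])
        return [s for s in order if s in present]

    def subset(self, slots: list[str]) -> "EMASchedule":
        sub = self.prompts[self.prompts["slot"].isin(slots)]
        return EMASchedule(sub.reset_index(drop=True))

    def prompt_keys(self) -> set[tuple[dt.date, str]]:
        return set(zip(self.prompts["date"], self.prompts["slot"]))

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        df = self.prompts.copy()
        for col in ("window_start", "window_end", "drawn_time"):
            df[col] = df[col].map(lambda t: t.isoformat())
        df["date"] = df["date"].map(lambda d: d.isoformat())
        df.to_csv(path, index=False, encoding="utf-8")
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "EMASchedule":
        df = pd.read_csv(path, dtype=str)
        df["date"] = pd.to_datetime(df["date"]).dt.date
        for col in ("window_start", "window_end", "drawn_time"):
            df[col] = df[col].map(dt.time.fromisoformat)
        return cls(df)


def build_schedule(
    start_date: dt.date,
    end_date: dt.date,
    daily_slots: tuple[str, ...] = DAILY_SLOTS,
    weekly_day: int = SUNDAY,
    seed: int = 0,
    slot_windows: dict[str, tuple[dt.time, dt.time]] | None = None,
) -> EMASchedule:
    """Build the full prompt schedule for [start_date, end_date].

    Every day gets one prompt per daily slot at a time drawn uniformly
    within the slot's clock window (reproducible via ``seed``); every
    occurrence of ``weekly_day`` additionally gets the weekly prompt.
    """
    if end_date < start_date:
        raise ParameterError(f"end_date {end_date} before start_date {start_date}")
    windows = dict(DEFAULT_SLOT_WINDOWS)
    if slot_windows:
        windows.update(slot_windows)
    rng = np.random.default_rng(seed)
    rows = []
    day = start_date
    while day <= end_date:
        slots = list(daily_slots)
        if day.weekday() == weekly_day:
            slots.append("weekly")
        for slot in slots:
            w0, w1 = windows[slot]
            t0 = w0.hour * 3600 + w0.minute * 60 + w0.second
            t1 = w1.hour * 3600 + w1.minute * 60 + w1.second
            drawn = int(rng.integers(t0, t1 + 1))
            rows.append(
                {
                    "date": day,
                    "slot": slot,
                    "window_start": w0,
                    "window_end": w1,
                    "drawn_time": dt.time(drawn // 3600, (drawn % 3600) // 60, drawn % 60),
                }
            )
        day += dt.timedelta(days=1)
    return EMASchedule(pd.DataFrame(rows))


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero-free: half-up."""
    return int(math.floor(x + 0.5))


def format_percent(numerator: float, denominator: float, decimals: int = 1) -> str:
    """Render a share as a percentage string at fixed decimals (76/880 -> '8.6%')."""
    if denominator == 0:
        return "–"
    return f"{100.0 * numerator / denominator:.{decimals}f}%"


@dataclass
class ComplianceSummary:
    """Per-participant prompt completion counts."""

    n_scheduled: int
    n_completed: int
    per_slot_counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    per_day: pd.Series | None = None

    @property
    def fraction(self) -> float:
        return self.n_completed / self.n_scheduled if self.n_scheduled else 0.0

    @property
    def percent_rounded(self) -> int:
        return round_half_up(100.0 * self.fraction)


@dataclass
class CompletionMatrix:
    """Date x slot boolean completion grid (the missing-data heatmap)."""

    dates: list[dt.date]
    slots: list[str]
    completed: np.ndarray  # bool, shape (len(dates), len(slots))

    @property
    def n_completed(self) -> int:
        return int(self.completed.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.completed, index=self.dates, columns=self.slots)


def _answered_keys(table: ResponseTable, participant: str) -> set[tuple[dt.date, str]]:
    sub = table.records[table.records["participant_key"] == participant]
    return set(zip(sub["date"], sub["slot"]))


def compliance_summary(
    table: ResponseTable, schedule: EMASchedule, participant: str
) -> ComplianceSummary:
    """Count completed prompts for one participant against the schedule.

    An unknown participant yields an all-zero summary, not an error.
    """
    if len(schedule) == 0:
        raise ParameterError("empty schedule")
    answered = _answered_keys(table, participant)
    sched_keys = list(zip(schedule.prompts["date"], schedule.prompts["slot"]))
    done = [k for k in sched_keys if k in answered]
    per_slot: dict[str, tuple[int, int]] = {}
    for slot in schedule.slots():
        s = sum(1 for _, sl in sched_keys if sl == slot)
        c = sum(1 for _, sl in done if sl == slot)
        per_slot[slot] = (s, c)
    per_day = (
        pd.Series([d for d, _ in done]).value_counts().sort_index()
        if done
        else pd.Series(dtype=int)
    )
    return ComplianceSummary(
        n_scheduled=len(sched_keys),
        n_completed=len(done),
        per_slot_counts=per_slot,
        per_day=per_day,
    )


def completion_matrix(
    table: ResponseTable, schedule: EMASchedule, participant: str
) -> CompletionMatrix:
    """Boolean grid of completed prompts (dates x slots in the schedule)."""
    if len(schedule) == 0:
        raise ParameterError("empty schedule")
    answered = _answered_keys(table, participant)
    dates = schedule.dates()
    slots = schedule.slots()
    sched_keys = schedule.prompt_keys()
    grid = np.zeros((len(dates), len(slots)), dtype=bool)
    for i, d in enumerate(dates):
        for j, s in enumerate(slots):
            grid[i, j] = (d, s) in sched_keys and (d, s) in answered
    return CompletionMatrix(dates=dates, slots=slots, completed=grid)


def cohort_completion_distribution(
    table: ResponseTable, schedule: EMASchedule, bin_width: int = 5
) -> pd.Series:
    """Histogram of completion percentages across participants.

    Bins have fixed width (default 5) with left-closed edges 0, 5, ...;
    100% falls in the terminal bin [100, 100+width). The index holds the
    left bin edges; counts sum to the number of participants.
    """
    participants = table.participants()
    if not participants:
        raise ParameterError("no participants in table")
    pcts = [
        100.0 * compliance_summary(table, schedule, p).fraction for p in participants
    ]
    edges = np.arange(0, 100 + 2 * bin_width, bin_width)
    counts, _ = np.histogram(pcts, bins=edges)
    return pd.Series(counts, index=edges[:-1].astype(int))
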
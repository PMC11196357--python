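"""Variable codebook and long-format EMA response tables.

The codebook declares every variable an EMA study collects: Likert mood
items on a bounded integer scale, and categorical context items (location,
activity, ...). Each variable belongs to a prompt block (``daily`` items
are asked four times a day, ``morning``/``evening`` items once in the
corresponding slot, ``weekly`` items in the Sunday survey) and Likert
items may carry an affect class (``positive`` / ``negative``) used by the
network plausibility check.

Responses travel in one canonical long format: CSV with columns
``participant_key, date, slot, timestamp, variable, value``, UTF-8,
ISO 8601 timestamps with zone. Reading validates every record against the
codebook and keeps only the valid ones; :func:`validate_responses` reports
(never raises on) content problems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .errors import CodebookError, EmptyTableError, MissingColumnError

DAILY_SLOTS = ("morning", "noon", "afternoon", "evening")
ALL_SLOTS = DAILY_SLOTS + ("weekly",)
BLOCKS = ("daily", "evening", "weekly", "morning")
AFFECT_CLASSES = ("positive", "negative", "none")

RESPONSE_COLUMNS = ["participant_key", "date", "slot", "timestamp", "variable", "value"]


@dataclass(frozen=True)
class VariableSpec:
    """One codebook entry.

    Parameters
    ----------
    name : str
        Unique identifier used in the response table.
    kind : {"likert", "categorical"}
    scale_min, scale_max : int
        Inclusive response bounds for Likert items (default 1..7).
    block : {"daily", "evening", "weekly", "morning"}
        Which prompts ask this item.
    affect_class : {"positive", "negative", "none"}
        Positive/negative affect tag; only meaningful for Likert items.
    categories : tuple of str
        Allowed labels for categorical items.
    label : mapping locale -> display text
    """

    name: str
    kind: str
    scale_min: int = 1
    scale_max: int = 7
    block: str = "daily"
    affect_class: str = "none"
    categories: tuple[str, ...] = ()
    label: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("likert", "categorical"):
            raise CodebookError(f"{self.name}: unknown kind {self.kind!r}")
        if self.block not in BLOCKS:
            raise CodebookError(f"{self.name}: unknown block {self.block!r}")
        if self.affect_class not in AFFECT_CLASSES:
            raise CodebookError(
                f"{self.name}: unknown affect_class {self.affect_class!r}"
            )
        if self.kind == "likert":
            if self.scale_min >= self.scale_max:
                raise CodebookError(
                    f"{self.name}: scale_min must be < scale_max "
                    f"({self.scale_min} >= {self.scale_max})"
                )
        else:
            if len(self.categories) < 2:
                raise CodebookError(
                    f"{self.name}: categorical items need >= 2 categories"
                )
            if self.affect_class != "none":
                raise CodebookError(
                    f"{self.name}: affect_class applies to likert items only"
                )

    def display_label(self, locale: str = "en") -> str:
        return dict(self.label).get(locale, self.name.replace("_", " "))


@dataclass(frozen=True)
class VariableCodebook:
    """Ordered collection of :class:`VariableSpec` with unique names."""

    entries: tuple[VariableSpec, ...]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise CodebookError(f"duplicate variable names: {dupes}")

    def __contains__(self, name: str) -> bool:
        return any(e.name == name for e in self.entries)

    def __getitem__(self, name: str) -> VariableSpec:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def likert_names(self, block: str | None = None) -> list[str]:
        return [
            e.name
            for e in self.entries
            if e.kind == "likert" and (block is None or e.block == block)
        ]

    def categorical_names(self) -> list[str]:
        return [e.name for e in self.entries if e.kind == "categorical"]

    def affect_items(self, affect_class: str, block: str | None = None) -> list[str]:
        return [
            e.name
            for e in self.entries
            if e.affect_class == affect_class
            and (block is None or e.block == block)
        ]

    def block_items(self, block: str) -> list[str]:
        return [e.name for e in self.entries if e.block == block]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "VariableCodebook":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        raw = yaml.safe_load(path.read_text(encoding="utf-8"))
        if not isinstance(raw, dict) or "variables" not in raw:
            raise CodebookError(f"{path}: expected a top-level 'variables' list")
        entries = []
        for item in raw["variables"]:
            item = dict(item)
            if "categories" in item:
                item["categories"] = tuple(item["categories"])
            entries.append(VariableSpec(**item))
        return cls(entries=tuple(entries))

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        out = {"variables": []}
        for e in self.entries:
            d: dict = {"name": e.name, "kind": e.kind, "block": e.block}
            if e.kind == "likert":
                d["scale_min"] = e.scale_min
                d["scale_max"] = e.scale_max
                if e.affect_class != "none":
                    d["affect_class"] = e.affect_class
            else:
                d["categories"] = list(e.categories)
            if e.label:
                d["label"] = dict(e.label)
            out["variables"].append(d)
        path.write_text(yaml.safe_dump(out, sort_keys=False), encoding="utf-8")
        return path


@dataclass
class ResponseTable:
    """Long-format EMA responses.

    ``records`` is a DataFrame with columns ``participant_key`` (str),
    ``date`` (datetime.date), ``slot`` (str), ``timestamp`` (tz-aware
    pandas Timestamp), ``variable`` (str), ``value`` (int for Likert
    items, str for categorical items).
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in RESPONSE_COLUMNS if c not in self.records.columns]
        if missing:
            raise MissingColumnError(f"response table missing columns: {missing}")
        self.records = self.records[RESPONSE_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ResponseTable):
            return NotImplemented
        if len(self) != len(other):
            return False
        a = self.records.reset_index(drop=True)
        b = other.records.reset_index(drop=True)
        return all(a[c].tolist() == b[c].tolist() for c in RESPONSE_COLUMNS)

    def participants(self) -> list[str]:
        return sorted(self.records["participant_key"].unique().tolist())

    def for_participant(self, key: str) -> "ResponseTable":
        sub = self.records[self.records["participant_key"] == key]
        return ResponseTable(sub.reset_index(drop=True))

    def values_for(self, variable: str) -> pd.Series:
        return self.records.loc[self.records["variable"] == variable, "value"]


@dataclass
class ValidationReport:
    """Outcome of validating a response table against a codebook."""

    n_records: int
    issues: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.issues)

    @property
    def ok(self) -> bool:
        return self.n_rejected == 0


def _check_record(row: pd.Series, codebook: VariableCodebook) -> str | None:
    """Return the violated rule for one parsed record, or None."""
    var = row["variable"]
    if var not in codebook:
        return "not in codebook"
    spec = codebook[var]
    if row["slot"] not in ALL_SLOTS:
        return "unknown slot"
    value = row["value"]
    if spec.kind == "likert":
        try:
            v = int(value)
        except (TypeError, ValueError):
            return "non-integer likert value"
        if not (spec.scale_min <= v <= spec.scale_max):
            return (
                f"likert value {v} outside "
                f"[{spec.scale_min}, {spec.scale_max}]"
            )
    else:
        if str(value) not in spec.categories:
            return f"unknown category {value!r}"
    return None


def validate_responses(
    table: ResponseTable, codebook: VariableCodebook
) -> ValidationReport:
    """Validate every record; report issues, never raise on content.

    Rules: variable must exist in the codebook; Likert values within the
    item's scale bounds; categorical values among the declared categories;
    at most one record per (participant, date, slot, variable) — the
    record with the earliest timestamp is kept, later duplicates are
    rejected (ties broken by row order).
    """
    issues: list[tuple[int, str]] = []
    df = table.records
    for idx, row in df.iterrows():
        rule = _check_record(row, codebook)
        if rule is not None:
            issues.append((int(idx), rule))

    bad = {i for i, _ in issues}
    good = df.loc[[i for i in df.index if i not in bad]]
    if len(good):
        order = good.sort_values("timestamp", kind="stable")
        dup = order.duplicated(
            subset=["participant_key", "date", "slot", "variable"], keep="first"
        )
        for idx in order.index[dup]:
            issues.append((int(idx), "duplicate (participant, date, slot, variable)"))
    issues.sort(key=lambda t: t[0])
    return ValidationReport(n_records=len(df), issues=issues)


def _parse_long(df: pd.DataFrame, codebook: VariableCodebook, tz: str) -> pd.DataFrame:
    missing = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"missing required columns: {missing}")
    df = df[RESPONSE_COLUMNS].copy()
    df["participant_key"] = df["participant_key"].astype(str)
    df["slot"] = df["slot"].astype(str)
    df["variable"] = df["variable"].astype(str)
    ts = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    df["timestamp"] = ts.dt.tz_convert(tz)
    df["date"] = pd.to_datetime(df["date"], format="ISO8601").dt.date

    # restore value typing: ints for likert items, strings otherwise
    def _coerce(row):
        var = row["variable"]
        if var in codebook and codebook[var].kind == "likert":
            try:
                return int(row["value"])
            except (TypeError, ValueError):
                return row["value"]
        return str(row["value"])

    df["value"] = df.apply(_coerce, axis=1)
    return df


def read_ema_long(
    path: str | Path, codebook: VariableCodebook, tz: str = "UTC"
) -> ResponseTable:
    """Read a long-format EMA CSV, returning only validated records.

    Timestamps are parsed as ISO 8601 and stored time-zone-aware in the
    study zone ``tz`` (default UTC); prompt slots are local-time concepts
    so dates are taken from the file's ``date`` column as written.

    Raises
    ------
    FileNotFoundError, MissingColumnError, EmptyTableError
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = _parse_long(raw, codebook, tz)
    if df.empty:
        raise EmptyTableError(f"{path}: no records")
    table = ResponseTable(df)
    report = validate_responses(table, codebook)
    rejected = {i for i, _ in report.issues}
    kept = df.loc[[i for i in df.index if i not in rejected]].reset_index(drop=True)
    if kept.empty:
        raise EmptyTableError(f"{path}: no records survive validation")
    out = ResponseTable(kept)
    out.validation = report  # type: ignore[attr-defined]
    return out


def write_ema_long(table: ResponseTable, path: str | Path) -> Path:
    """Write the canonical long-format CSV; round-trips with read."""
    if len(table) == 0:
        raise EmptyTableError("refusing to write an empty response table")
    path = Path(path)
    df = table.records.copy()
    df["timestamp"] = df["timestamp"].map(lambda t: t.isoformat())
    df["date"] = df["date"].map(lambda d: d.isoformat())
    df.to_csv(path, index=False, encoding="utf-8")
    return path


def from_records(records: Iterable[dict], tz: str = "UTC") -> ResponseTable:
    """Build a ResponseTable from an iterable of record dicts (test helper)."""
    df = pd.DataFrame(list(records), columns=RESPONSE_COLUMNS)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True).dt.tz_convert(tz)
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return ResponseTable(df)
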
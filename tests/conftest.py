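import datetime as dt

import pandas as pd
import pytest

from emafeedback.codebook import ResponseTable, VariableCodebook, VariableSpec


@pytest.fixture
def codebook() -> VariableCodebook:
    """Small codebook: PA/NA daily items plus one categorical item."""
    return VariableCodebook(
        entries=(
            VariableSpec(name="happy", kind="likert", affect_class="positive"),
            VariableSpec(name="motivated", kind="likert", affect_class="positive"),
            VariableSpec(name="sad", kind="likert", affect_class="negative"),
            VariableSpec(name="stressed", kind="likert", affect_class="negative"),
            VariableSpec(
                name="location",
                kind="categorical",
                categories=("home", "work", "outside"),
            ),
        )
    )


def make_table(rows: list[tuple]) -> ResponseTable:
    """Rows: (participant, 'YYYY-MM-DD', slot, 'HH:MM', variable, value)."""
    records = []
    for key, date, slot, hhmm, var, value in rows:
        d = dt.date.fromisoformat(date)
        h, m = map(int, hhmm.split(":"))
        ts = pd.Timestamp(
            dt.datetime.combine(d, dt.time(h, m)), tz="UTC"
        )
        records.append(
            {
                "participant_key": key,
                "date": d,
                "slot": slot,
                "timestamp": ts,
                "variable": var,
                "value": value,
            }
        )
    df = pd.DataFrame(
        records,
        columns=["participant_key", "date", "slot", "timestamp", "variable", "value"],
    )
    return ResponseTable(df)


@pytest.fixture
def table_maker():
    return make_table
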
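"""Item summaries, relative frequencies, peak affect, and recap weeks."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emafeedback.descriptives import (
    categorical_frequencies,
    continuous_summary,
    filter_week,
    peak_affect,
    recap_weeks,
    week_start_of,
)
from emafeedback.errors import InsufficientDataError

from conftest import make_table

PA = ["happy", "motivated"]


def _rows_daily(values_by_prompt, variable="happy", key="P1"):
    """values_by_prompt: {(iso_date, slot): value}"""
    return [
        (key, d, s, "09:00", variable, v) for (d, s), v in values_by_prompt.items()
    ]


class TestContinuousSummary:
    def test_constant_series_mean(self):
        rows = [("P1", "2022-01-10", s, "09:00", "happy", 5)
                for s in ("morning", "noon", "afternoon")]
        (s,) = continuous_summary(make_table(rows), ["happy"])
        assert s.mean == 5.0 and s.n_obs == 3

    def test_symmetric_extremes(self):
        rows = [
            ("P1", "2022-01-10", "morning", "09:00", "happy", 1),
            ("P1", "2022-01-10", "noon", "12:00", "happy", 7),
        ]
        (s,) = continuous_summary(make_table(rows), ["happy"])
        assert s.mean == 4.0

    def test_mean_matches_direct_sum_oracle(self):
        rng = np.random.default_rng(0)
        vals = rng.integers(1, 8, size=200)
        dates = [dt.date(2022, 1, 3) + dt.timedelta(days=i // 4) for i in range(200)]
        slots = ["morning", "noon", "afternoon", "evening"] * 50
        rows = [
            ("P1", d.isoformat(), s, "09:00", "happy", int(v))
            for d, s, v in zip(dates, slots, vals)
        ]
        (s,) = continuous_summary(make_table(rows), ["happy"])
        assert abs(s.mean - vals.sum() / 200) < 1e-12

    def test_zero_observations_flagged_not_raised(self):
        rows = [("P1", "2022-01-10", "morning", "09:00", "sad", 3)]
        (s,) = continuous_summary(make_table(rows), ["happy"])
        assert s.n_obs == 0 and not s.has_mean

    def test_jitter_bounded_and_display_only(self):
        rows = [("P1", "2022-01-10", "morning", "09:00", "happy", 4)]
        table = make_table(rows * 1)
        (s,) = continuous_summary(table, ["happy"])
        for _, v in s.values_with_jitter:
            assert abs(v - 4) <= 0.25
        # stored value untouched
        assert table.records["value"].iloc[0] == 4


class TestCategoricalFrequencies:
    def test_simple_shares(self, codebook):
        rows = [
            ("P1", "2022-01-10", "morning", "09:00", "location", "home"),
            ("P1", "2022-01-10", "noon", "12:00", "location", "home"),
            ("P1", "2022-01-10", "afternoon", "15:00", "location", "home"),
            ("P1", "2022-01-10", "evening", "19:00", "location", "work"),
        ]
        ft = categorical_frequencies(make_table(rows), "location", codebook)
        assert ft.frequencies["home"] == 0.75
        assert ft.frequencies["work"] == 0.25
        assert ft.frequencies["outside"] == 0.0  # zero-count category included

    def test_single_observation(self, codebook):
        rows = [("P1", "2022-01-10", "noon", "12:00", "location", "outside")]
        ft = categorical_frequencies(make_table(rows), "location", codebook)
        assert ft.frequencies["outside"] == 1.0

    @settings(max_examples=30, deadline=None)
    @given(counts=st.lists(st.integers(0, 20), min_size=3, max_size=3))
    def test_frequencies_sum_to_one(self, counts):
        from emafeedback.codebook import VariableCodebook, VariableSpec

        codebook = VariableCodebook(
            entries=(
                VariableSpec(name="location", kind="categorical",
                             categories=("home", "work", "outside")),
            )
        )
        cats = ["home", "work", "outside"]
        rows = []
        i = 0
        for cat, k in zip(cats, counts):
            for _ in range(k):
                rows.append(
                    ("P1", (dt.date(2022, 1, 3) + dt.timedelta(days=i // 4)).isoformat(),
                     ["morning", "noon", "afternoon", "evening"][i % 4],
                     "09:00", "location", cat)
                )
                i += 1
        if not rows:
            return
        ft = categorical_frequencies(make_table(rows), "location", codebook)
        assert abs(sum(ft.frequencies.values()) - 1.0) < 1e-9
        assert all(f >= 0 for f in ft.frequencies.values())


class TestPeakAffect:
    def test_strict_maximum(self):
        vals = {("2022-01-10", "morning"): 3, ("2022-01-10", "noon"): 7,
                ("2022-01-11", "evening"): 5}
        res = peak_affect(make_table(_rows_daily(vals)), ["happy"])
        assert res.prompt == (dt.date(2022, 1, 10), "noon")

    def test_tie_goes_to_earlier_date(self):
        vals = {("2022-01-12", "morning"): 7, ("2022-01-10", "morning"): 7}
        res = peak_affect(make_table(_rows_daily(vals)), ["happy"])
        assert res.prompt == (dt.date(2022, 1, 10), "morning")

    def test_no_observations_raises(self):
        rows = [("P1", "2022-01-10", "morning", "09:00", "sad", 3)]
        with pytest.raises(InsufficientDataError):
            peak_affect(make_table(rows), ["happy"])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(40):
            d = dt.date(2022, 1, 3) + dt.timedelta(days=i // 4)
            slot = ["morning", "noon", "afternoon", "evening"][i % 4]
            for var in PA:
                if rng.random() < 0.8:
                    rows.append(("P1", d.isoformat(), slot, "09:00", var,
                                 int(rng.integers(1, 8))))
        table = make_table(rows)
        res = peak_affect(table, PA)
        # brute force over all (date, slot) means
        df = table.records[table.records["variable"].isin(PA)].copy()
        df["value"] = df["value"].astype(float)
        means = df.groupby(["date", "slot"])["value"].mean()
        assert res.prompt_mean == pytest.approx(means.max())
        assert means[res.prompt] == pytest.approx(means.max())


class TestRecapWeeks:
    def _week_rows(self, week_values):
        """week_values: list of (monday_iso, [values])"""
        rows = []
        for monday, vals in week_values:
            start = dt.date.fromisoformat(monday)
            for i, v in enumerate(vals):
                d = start + dt.timedelta(days=i // 4)
                slot = ["morning", "noon", "afternoon", "evening"][i % 4]
                rows.append(("P1", d.isoformat(), slot, "09:00", "happy", v))
        return rows

    def test_best_and_worst_identified(self):
        rows = self._week_rows(
            [("2022-01-03", [3] * 5), ("2022-01-10", [6] * 5)]
        )
        res = recap_weeks(make_table(rows), ["happy"])
        assert res.best_week[0] == dt.date(2022, 1, 10)
        assert res.worst_week[0] == dt.date(2022, 1, 3)
        assert res.best_week_mean == 6.0 and res.worst_week_mean == 3.0
        assert res.worst_week_mean <= res.overall_mean <= res.best_week_mean

    def test_identical_weeks_tie_to_earliest(self):
        rows = self._week_rows(
            [("2022-01-03", [4] * 5), ("2022-01-10", [4] * 5)]
        )
        res = recap_weeks(make_table(rows), ["happy"])
        assert res.best_week[0] == res.worst_week[0] == dt.date(2022, 1, 3)

    def test_insufficient_weeks_raises(self):
        rows = self._week_rows([("2022-01-03", [4] * 5)])
        with pytest.raises(InsufficientDataError):
            recap_weeks(make_table(rows), ["happy"])
        # a week below the 4-observation floor does not qualify
        rows += self._week_rows([("2022-01-10", [7] * 3)])
        with pytest.raises(InsufficientDataError):
            recap_weeks(make_table(rows), ["happy"])

    def test_matches_exhaustive_weekly_oracle(self):
        rng = np.random.default_rng(11)
        rows = []
        start = dt.date(2022, 1, 3)
        for i in range(12 * 28):  # 12 weeks x 7 days x 4 prompts
            d = start + dt.timedelta(days=i // 4)
            slot = ["morning", "noon", "afternoon", "evening"][i % 4]
            if rng.random() < 0.7:
                rows.append(("P1", d.isoformat(), slot, "09:00", "happy",
                             int(rng.integers(1, 8))))
        table = make_table(rows)
        res = recap_weeks(table, ["happy"])
        df = table.records.copy()
        df["value"] = df["value"].astype(float)
        df["week"] = df["date"].map(week_start_of)
        g = df.groupby("week")["value"].agg(["mean", "count"])
        g = g[g["count"] >= 4]
        assert res.best_week_mean == pytest.approx(g["mean"].max())
        assert res.worst_week_mean == pytest.approx(g["mean"].min())

    def test_filter_week_restricts_dates(self):
        rows = self._week_rows(
            [("2022-01-03", [3] * 5), ("2022-01-10", [6] * 5)]
        )
        table = make_table(rows)
        wk = filter_week(table, (dt.date(2022, 1, 10), dt.date(2022, 1, 16)))
        assert set(wk.records["date"]) <= {
            dt.date(2022, 1, 10) + dt.timedelta(days=k) for k in range(7)
        }
        assert len(wk) == 5
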
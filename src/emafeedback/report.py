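"""Per-participant report bundles.

A bundle is the static counterpart of an interactive feedback app: an
ordered list of sections (meta-information, continuous overview,
categorical overview, time series, recap, networks), each with plain-
language body text and figure references. Sections whose analysis is
gated out (too little data, completion below the network threshold)
stay in the bundle with an explanatory text instead of figures; any
stage failure downgrades only its own section.

Rendering writes one self-contained HTML document per participant plus
PNG figures; filenames derive only from the pseudonymous participant
key.
"""

from __future__ import annotations

import base64
import datetime as dt
import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import figures as fig_mod
from ._text import text
from .codebook import DAILY_SLOTS, ResponseTable, VariableCodebook
from .descriptives import (
    categorical_frequencies,
    continuous_summary,
    peak_affect,
    recap_weeks,
)
from .errors import EMAError, EstimationError, InsufficientDataError
from .imputation import kalman_impute
from .networks import (
    ContemporaneousNetwork,
    estimate_var_contemporaneous,
    lagged_pairs,
    network_gate,
    select_network_variables,
)
from .schedule import EMASchedule, compliance_summary, completion_matrix
from .trend import DEFAULT_MIN_OBS, DEFAULT_SPAN, loess_fit

logger = logging.getLogger("emafeedback")

SECTION_ORDER = ["meta", "continuous", "categorical", "timeseries", "recap", "network"]


@dataclass
class ReportConfig:
    codebook: VariableCodebook
    locale: str = "en"
    loess_span: float = DEFAULT_SPAN
    trend_min_obs: int = DEFAULT_MIN_OBS
    ebic_gamma: float = 0.5
    n_network_variables: int = 6
    week_start: int = 0  # Monday
    timeseries_variables: list[str] | None = None

    def positive_items(self) -> list[str]:
        return self.codebook.affect_items("positive", block="daily")

    def network_candidates(self, mode: str) -> list[str]:
        block = "daily" if mode == "daily" else "evening"
        # evening networks may also use daily items observed at the evening prompt
        if mode == "evening":
            return self.codebook.likert_names("daily") + self.codebook.likert_names(
                "evening"
            )
        return self.codebook.likert_names("daily")


@dataclass
class Section:
    id: str
    title: str
    body: str
    figure_refs: list[str] = field(default_factory=list)
    included: bool = True


@dataclass
class ReportBundle:
    participant_key: str
    sections: list[Section]
    locale: str
    figures: dict[str, "object"] = field(default_factory=dict)  # name -> Figure
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    networks: dict[str, ContemporaneousNetwork] = field(default_factory=dict)


def _fmt_week(week: tuple[dt.date, dt.date]) -> str:
    return f"{week[0].isoformat()} – {week[1].isoformat()}"


def _timeseries_values(table: ResponseTable, variable: str):
    sub = table.records[table.records["variable"] == variable]
    times = list(sub["timestamp"])
    values = pd.to_numeric(sub["value"]).tolist()
    return times, values


def network_for_participant(
    table: ResponseTable,
    schedule: EMASchedule,
    participant: str,
    config: ReportConfig,
    mode: str,
) -> ContemporaneousNetwork:
    """Gate, select variables, impute, and estimate one network mode.

    The completion gate counts only the surveys relevant to the mode:
    all four daily prompts for the daily network, evening prompts for
    the evening network.
    """
    relevant = schedule.subset(
        list(DAILY_SLOTS) if mode == "daily" else ["evening"]
    )
    comp = compliance_summary(table, relevant, participant)
    if not network_gate(comp.fraction):
        return ContemporaneousNetwork(
            variables=[], beta=np.zeros((0, 0)), kappa=np.zeros((0, 0)),
            pcor=np.zeros((0, 0)), mode=mode, n_effective=0, gate_passed=False,
        )
    sub = table.for_participant(participant)
    candidates = config.network_candidates(mode)
    chosen, _ = select_network_variables(sub, candidates, config.n_network_variables)
    if len(chosen) < 2:
        raise InsufficientDataError("fewer than 2 eligible network variables")

    from .networks import build_panel

    panel = build_panel(sub, chosen)
    keys = [
        (d, s)
        for d, s in zip(relevant.prompts["date"], relevant.prompts["slot"])
    ]
    idx = pd.MultiIndex.from_tuples(keys, names=["date", "slot"])
    full = panel.reindex(idx)
    for col in full.columns:
        spec = config.codebook[col]
        res = kalman_impute(
            full[col].to_numpy(dtype=float), (spec.scale_min, spec.scale_max)
        )
        full[col] = res.series
    design = lagged_pairs(full, chosen, mode)
    return estimate_var_contemporaneous(design, ebic_gamma=config.ebic_gamma)


def estimate_cohort_networks(
    table: ResponseTable,
    schedule: EMASchedule,
    config: ReportConfig,
    modes: tuple[str, ...] = ("daily", "evening"),
) -> list[ContemporaneousNetwork]:
    """Estimate every gate-passing participant network in the cohort.

    Participants failing the completion gate or whose fit degenerates
    are skipped with a logged notice; the returned list holds only
    successful fits.
    """
    nets: list[ContemporaneousNetwork] = []
    for key in table.participants():
        for mode in modes:
            try:
                net = network_for_participant(table, schedule, key, config, mode)
            except (InsufficientDataError, EstimationError) as exc:
                logger.info("skipping %s %s network: %s", key, mode, exc)
                continue
            if net.gate_passed:
                nets.append(net)
    return nets


def assemble_report(
    table: ResponseTable,
    schedule: EMASchedule,
    participant: str,
    config: ReportConfig,
) -> ReportBundle:
    """Run the full pipeline for one participant and build the bundle."""
    if participant not in table.participants():
        raise EMAError(f"participant {participant!r} not present in table")
    loc = config.locale
    sub = table.for_participant(participant)
    sections: list[Section] = []
    figures: dict[str, object] = {}
    tables: dict[str, pd.DataFrame] = {}
    networks: dict[str, ContemporaneousNetwork] = {}

    # --- meta / compliance -------------------------------------------------
    comp = compliance_summary(table, schedule, participant)
    matrix = completion_matrix(table, schedule, participant)
    figures["completion"] = fig_mod.plot_completion_heatmap(matrix)
    tables["compliance"] = pd.DataFrame(
        [
            {
                "n_scheduled": comp.n_scheduled,
                "n_completed": comp.n_completed,
                "fraction": comp.fraction,
                "percent_rounded": comp.percent_rounded,
            }
        ]
    )
    sections.append(
        Section(
            id="meta",
            title=text("meta.title", loc),
            body=text(
                "meta.body", loc,
                n_scheduled=comp.n_scheduled, n_completed=comp.n_completed,
                percent=comp.percent_rounded,
            ),
            figure_refs=["completion"],
        )
    )
    has_data = len(sub) > 0

    # --- continuous overview ----------------------------------------------
    likert_vars = [v for v in config.codebook.likert_names()
                   if len(sub.values_for(v))]
    if has_data and likert_vars:
        summaries = continuous_summary(sub, likert_vars, config.codebook)
        figures["item_means"] = fig_mod.plot_item_summaries(summaries)
        tables["item_means"] = pd.DataFrame(
            [{"variable": s.variable, "n_obs": s.n_obs, "mean": s.mean}
             for s in summaries]
        )
        body = text("continuous.body", loc)
        try:
            peak = peak_affect(sub, config.positive_items())
            body += " " + text(
                "continuous.peak", loc,
                best_day=peak.best_day.isoformat(), best_slot=peak.best_slot,
            )
        except InsufficientDataError:
            pass
        sections.append(
            Section(id="continuous", title=text("continuous.title", loc),
                    body=body, figure_refs=["item_means"])
        )
    else:
        sections.append(
            Section(id="continuous", title=text("continuous.title", loc),
                    body=text("section.no_data", loc), included=False)
        )

    # --- categorical overview ----------------------------------------------
    cat_vars = [v for v in config.codebook.categorical_names()
                if len(sub.values_for(v))]
    if has_data and cat_vars:
        refs = []
        freq_rows = []
        for v in cat_vars:
            ft = categorical_frequencies(sub, v, config.codebook)
            name = f"freq_{v}"
            figures[name] = fig_mod.plot_frequencies(ft)
            refs.append(name)
            for c, f in ft.frequencies.items():
                freq_rows.append({"variable": v, "category": c, "frequency": f})
        tables["frequencies"] = pd.DataFrame(freq_rows)
        sections.append(
            Section(id="categorical", title=text("categorical.title", loc),
                    body=text("categorical.body", loc), figure_refs=refs)
        )
    else:
        sections.append(
            Section(id="categorical", title=text("categorical.title", loc),
                    body=text("section.no_data", loc), included=False)
        )

    # --- time series --------------------------------------------------------
    ts_vars = config.timeseries_variables or config.codebook.affect_items(
        "positive", "daily"
    ) + config.codebook.affect_items("negative", "daily")
    ts_vars = [v for v in ts_vars if len(sub.values_for(v))]
    if has_data and ts_vars:
        refs = []
        gated = []
        trend_rows = []
        for v in ts_vars:
            times, values = _timeseries_values(sub, v)
            import matplotlib.dates as mdates

            x = mdates.date2num(times)
            trend = loess_fit(
                np.asarray(x), np.asarray(values, dtype=float),
                span=config.loess_span, min_n=config.trend_min_obs,
            )
            name = f"ts_{v}"
            spec = config.codebook[v]
            figures[name] = fig_mod.plot_time_series(
                times, values, trend, v, (spec.scale_min, spec.scale_max)
            )
            refs.append(name)
            if trend.gated_out:
                gated.append(v)
            else:
                for g, f in zip(trend.grid, trend.fitted):
                    trend_rows.append({"variable": v, "time": g, "fitted": f})
        if trend_rows:
            tables["trends"] = pd.DataFrame(trend_rows)
        body = text("timeseries.body", loc)
        if gated:
            body += " " + text("timeseries.gated", loc, min_n=config.trend_min_obs)
        sections.append(
            Section(id="timeseries", title=text("timeseries.title", loc),
                    body=body, figure_refs=refs)
        )
    else:
        sections.append(
            Section(id="timeseries", title=text("timeseries.title", loc),
                    body=text("section.no_data", loc), included=False)
        )

    # --- recap ---------------------------------------------------------------
    try:
        recap = recap_weeks(sub, config.positive_items(), config.week_start)
        sections.append(
            Section(
                id="recap", title=text("recap.title", loc),
                body=text(
                    "recap.body", loc,
                    best_week=_fmt_week(recap.best_week),
                    worst_week=_fmt_week(recap.worst_week),
                    best_mean=f"{recap.best_week_mean:.2f}",
                    worst_mean=f"{recap.worst_week_mean:.2f}",
                    overall_mean=f"{recap.overall_mean:.2f}",
                ),
            )
        )
        tables["recap"] = pd.DataFrame(
            [
                {
                    "best_week_start": recap.best_week[0],
                    "worst_week_start": recap.worst_week[0],
                    "best_week_mean": recap.best_week_mean,
                    "worst_week_mean": recap.worst_week_mean,
                    "overall_mean": recap.overall_mean,
                }
            ]
        )
    except (InsufficientDataError, EMAError):
        sections.append(
            Section(id="recap", title=text("recap.title", loc),
                    body=text("recap.gated", loc), included=False)
        )

    # --- networks -----------------------------------------------------------
    net_refs = []
    net_bodies = []
    for mode in ("daily", "evening"):
        try:
            net = network_for_participant(table, schedule, participant, config, mode)
        except (InsufficientDataError, EstimationError) as exc:
            logger.info("network (%s) for %s not estimated: %s",
                        mode, participant, exc)
            net_bodies.append(text("network.failed", loc))
            continue
        if not net.gate_passed:
            net_bodies.append(text("network.not_estimated", loc))
            continue
        networks[mode] = net
        name = f"network_{mode}"
        figures[name] = fig_mod.plot_network(net)
        net_refs.append(name)
        tables[f"network_{mode}_edges"] = net.edge_frame()
    if net_refs:
        body = text("network.body", loc)
        if net_bodies:
            body += " " + " ".join(net_bodies)
        sections.append(
            Section(id="network", title=text("network.title", loc),
                    body=body, figure_refs=net_refs)
        )
    else:
        sections.append(
            Section(id="network", title=text("network.title", loc),
                    body=" ".join(net_bodies) or text("network.not_estimated", loc),
                    included=False)
        )

    order = {sid: i for i, sid in enumerate(SECTION_ORDER)}
    sections.sort(key=lambda s: order[s.id])
    return ReportBundle(
        participant_key=participant, sections=sections, locale=loc,
        figures=figures, tables=tables, networks=networks,
    )


def write_artifacts(bundle: ReportBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle's data tables as CSV plus a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    key = bundle.participant_key
    paths: dict[str, Path] = {}
    for name, df in bundle.tables.items():
        p = out_dir / f"{key}_{name}.csv"
        df.to_csv(p, index=False, float_format="%.10g")
        paths[name] = p
    manifest = {
        "participant_key": key,
        "locale": bundle.locale,
        "sections": [
            {"id": s.id, "title": s.title, "included": s.included,
             "figures": s.figure_refs, "body": s.body}
            for s in bundle.sections
        ],
        "tables": {k: p.name for k, p in paths.items()},
    }
    mpath = out_dir / f"{key}_manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")
    paths["manifest"] = mpath
    return paths


def render_bundle(bundle: ReportBundle, out_dir: str | Path) -> list[Path]:
    """Render one self-contained HTML document plus PNG figure files.

    Filenames derive only from the pseudonymous participant key;
    re-rendering overwrites idempotently.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    key = bundle.participant_key
    written: list[Path] = []

    encoded: dict[str, str] = {}
    for name, fig in bundle.figures.items():
        png = out_dir / f"{key}_{name}.png"
        fig.savefig(png, dpi=110, metadata={"Software": None})
        written.append(png)
        buf = io.BytesIO()
        fig.savefig(buf, format="png", dpi=110, metadata={"Software": None})
        encoded[name] = base64.b64encode(buf.getvalue()).decode("ascii")

    parts = [
        "<!DOCTYPE html>",
        "<html><head><meta charset='utf-8'>",
        f"<title>Personal report {key}</title>",
        "<style>body{font-family:sans-serif;max-width:52rem;margin:2rem auto;}"
        "h2{border-bottom:1px solid #ccc;} .muted{color:#666;}</style>",
        "</head><body>",
        f"<h1>Personal report</h1><p class='muted'>Participant {key}</p>",
    ]
    for s in bundle.sections:
        parts.append(f"<section id='{s.id}'>")
        parts.append(f"<h2>{s.title}</h2>")
        cls = "" if s.included else " class='muted'"
        parts.append(f"<p{cls}>{s.body}</p>")
        for ref in s.figure_refs:
            if ref in encoded:
                parts.append(
                    f"<img alt='{ref}' style='max-width:100%'"
                    f" src='data:image/png;base64,{encoded[ref]}'>"
                )
        parts.append("</section>")
    parts.append("</body></html>")
    doc = out_dir / f"{key}.html"
    doc.write_text("\n".join(parts), encoding="utf-8")
    written.append(doc)
    return written
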
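"""Synthetic EMA cohort generator.

Emulates a three-month EMA protocol: Likert affect items on a 1-7 scale
sampled four times a day, morning sleep items, evening and weekly
items, categorical context items, and participant-level missingness
spanning near-total dropout to near-perfect compliance.

The daily affect items follow a latent VAR(1)

    x_t = B x_{t-1} + eps_t,    eps_t ~ N(0, K^-1)

whose innovation precision K carries the sign structure the network
plausibility check expects (positive partial correlations within the
positive-affect and within the negative-affect blocks, negative across
blocks). Latents are standardized by their stationary variances and cut
at fixed symmetric thresholds into 1..7 responses. Other Likert items
follow independent AR(1) latents; categorical items are drawn i.i.d.
per prompt.

Completion is participant-level: each participant draws a completion
fraction from a normal (default mean 0.58, SD 0.20, clipped to
[0.01, 0.99] — matching a cohort that averages 58% compliance with a
1%-99% range) and prompts are kept Bernoulli-wise. An optional
``evening_bias`` tilts missingness against evening prompts (MAR
stress-testing).

Everything is reproducible from (seed, participant_index): each
participant gets an integer-indexed substream.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_discrete_lyapunov

from .codebook import (
    DAILY_SLOTS,
    ResponseTable,
    VariableCodebook,
    VariableSpec,
)
from .errors import ParameterError
from .schedule import SUNDAY, EMASchedule, build_schedule

#: symmetric 1..7 thresholds on the standardized latent scale
DEFAULT_THRESHOLDS = (-1.5, -0.9, -0.3, 0.3, 0.9, 1.5)

PA_ITEMS = ("happy", "motivated", "relaxed")
NA_ITEMS = ("overwhelmed", "stressed", "sad")


def default_codebook() -> VariableCodebook:
    """Illustrative default codebook: affect, sleep, context, recap items."""
    entries: list[VariableSpec] = []
    for name in PA_ITEMS:
        entries.append(VariableSpec(name=name, kind="likert", affect_class="positive"))
    for name in NA_ITEMS:
        entries.append(VariableSpec(name=name, kind="likert", affect_class="negative"))
    entries.append(VariableSpec(name="tired", kind="likert", block="daily"))
    entries.append(VariableSpec(name="sleep_quality", kind="likert", block="morning"))
    entries.append(VariableSpec(name="rested", kind="likert", block="morning"))
    entries.append(
        VariableSpec(name="content", kind="likert", block="evening",
                     affect_class="positive")
    )
    entries.append(
        VariableSpec(name="lonely", kind="likert", block="evening",
                     affect_class="negative")
    )
    entries.append(
        VariableSpec(name="life_satisfaction", kind="likert", block="weekly")
    )
    entries.append(
        VariableSpec(
            name="location",
            kind="categorical",
            block="daily",
            categories=("home", "work_school", "outside", "transit", "other"),
        )
    )
    entries.append(
        VariableSpec(
            name="activity",
            kind="categorical",
            block="daily",
            categories=(
                "social", "active_leisure", "passive_leisure", "work_study",
                "chores", "nothing",
            ),
        )
    )
    entries.append(
        VariableSpec(
            name="negative_event",
            kind="categorical",
            block="evening",
            categories=(
                "education_work", "social", "health", "societal_political", "other",
            ),
        )
    )
    return VariableCodebook(entries=tuple(entries))


def default_true_beta(p: int = 6, phi: float = 0.3) -> np.ndarray:
    return np.eye(p) * phi


def default_true_kappa(
    within: float = 0.3, cross: float = 0.1
) -> np.ndarray:
    """6x6 innovation precision with PA/NA-conforming partial correlations.

    Ordering follows PA_ITEMS + NA_ITEMS. Off-diagonal kappa = -within
    inside each 3-item affect block (=> positive partial correlations)
    and +cross across blocks (=> negative partial correlations).
    """
    K = np.eye(6)
    blocks = [range(0, 3), range(3, 6)]
    for blk in blocks:
        for i in blk:
            for j in blk:
                if i != j:
                    K[i, j] = -within
    for i in blocks[0]:
        for j in blocks[1]:
            K[i, j] = cross
            K[j, i] = cross
    if np.linalg.eigvalsh(K).min() <= 0:
        raise ParameterError("default_true_kappa parameters give a non-PD matrix")
    return K


@dataclass
class CompletionModel:
    mean_completion: float = 0.58
    between_participant_sd: float = 0.20
    evening_bias: float = 0.0  # >0 makes evening prompts more likely missed
    min_completion: float = 0.01
    max_completion: float = 0.99


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic cohort; defaults mirror the emulated study."""

    n_participants: int = 10
    start_date: dt.date = dt.date(2021, 12, 6)
    end_date: dt.date = dt.date(2022, 2, 28)
    weekly_day: int = SUNDAY
    variables: VariableCodebook = field(default_factory=default_codebook)
    true_beta: np.ndarray = field(default_factory=default_true_beta)
    true_kappa: np.ndarray = field(default_factory=default_true_kappa)
    likert_thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    completion_model: CompletionModel = field(default_factory=CompletionModel)
    ar_phi_other: float = 0.4  # AR(1) coefficient for non-network likert items
    categorical_probs: dict[str, tuple[float, ...]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ParameterError("n_participants must be >= 1")
        if self.end_date < self.start_date:
            raise ParameterError("end_date before start_date")
        B = np.asarray(self.true_beta, dtype=float)
        if np.max(np.abs(np.linalg.eigvals(B))) >= 1.0:
            raise ParameterError("true_beta: spectral radius must be < 1")
        K = np.asarray(self.true_kappa, dtype=float)
        if np.linalg.eigvalsh(K).min() <= 0:
            raise ParameterError("true_kappa must be positive definite")
        p = len(self.network_items())
        if B.shape != (p, p) or K.shape != (p, p):
            raise ParameterError(
                f"true_beta/true_kappa must be {p}x{p} to match the "
                f"daily affect items"
            )
        cm = self.completion_model
        if not (0.0 <= cm.min_completion <= cm.max_completion <= 1.0):
            raise ParameterError("completion bounds must satisfy 0<=min<=max<=1")

    def network_items(self) -> list[str]:
        """Daily Likert affect items driven by the joint latent VAR."""
        return [
            e.name
            for e in self.variables.entries
            if e.kind == "likert" and e.block == "daily" and e.affect_class != "none"
        ]

    def category_probs(self, spec: VariableSpec) -> np.ndarray:
        if self.categorical_probs and spec.name in self.categorical_probs:
            p = np.asarray(self.categorical_probs[spec.name], dtype=float)
            if len(p) != len(spec.categories) or abs(p.sum() - 1.0) > 1e-9:
                raise ParameterError(
                    f"categorical_probs[{spec.name}]: bad probability vector"
                )
            return p
        k = len(spec.categories)
        return np.full(k, 1.0 / k)


def _participant_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, index]))


def _discretize(z: np.ndarray, thresholds: tuple[float, ...]) -> np.ndarray:
    return np.searchsorted(np.asarray(thresholds), z) + 1


def _simulate_var(
    rng: np.random.Generator, B: np.ndarray, K: np.ndarray, n: int, burn: int = 50
) -> np.ndarray:
    """Simulate a stationary VAR(1), standardized by stationary SDs."""
    p = B.shape[0]
    sigma = np.linalg.inv(K)
    chol = np.linalg.cholesky(sigma)
    x = np.zeros(p)
    out = np.empty((n, p))
    for t in range(-burn, n):
        x = B @ x + chol @ rng.standard_normal(p)
        if t >= 0:
            out[t] = x
    stat_cov = solve_discrete_lyapunov(B, sigma)
    return out / np.sqrt(np.diag(stat_cov))


def _simulate_ar1(
    rng: np.random.Generator, phi: float, n: int, burn: int = 50
) -> np.ndarray:
    innov_sd = np.sqrt(1.0 - phi * phi)  # unit stationary variance
    x = 0.0
    out = np.empty(n)
    for t in range(-burn, n):
        x = phi * x + innov_sd * rng.standard_normal()
        if t >= 0:
            out[t] = x
    return out


def simulate_participant(
    config: SyntheticConfig,
    participant_index: int,
    schedule: EMASchedule | None = None,
) -> ResponseTable:
    """Simulate one participant's full response table.

    Deterministic in (config.seed, participant_index). The schedule may
    be passed in to avoid rebuilding it per participant.
    """
    rng = _participant_rng(config.seed, participant_index)
    if schedule is None:
        schedule = build_schedule(
            config.start_date, config.end_date, weekly_day=config.weekly_day,
            seed=config.seed,
        )
    cb = config.variables
    prompts = schedule.prompts

    cm = config.completion_model
    completion = float(
        np.clip(
            rng.normal(cm.mean_completion, cm.between_participant_sd),
            cm.min_completion,
            cm.max_completion,
        )
    )

    # latent series on the full prompt grids
    net_items = config.network_items()
    daily_prompts = prompts[prompts["slot"].isin(DAILY_SLOTS)].reset_index(drop=True)
    z_net = _simulate_var(
        rng, np.asarray(config.true_beta, float),
        np.asarray(config.true_kappa, float), len(daily_prompts),
    )
    net_likert = {
        name: _discretize(z_net[:, i], config.likert_thresholds)
        for i, name in enumerate(net_items)
    }

    other_likert: dict[str, dict[str, np.ndarray]] = {}
    for spec in cb.entries:
        if spec.kind != "likert" or spec.name in net_items:
            continue
        block_prompts = _prompts_for_block(prompts, spec.block)
        z = _simulate_ar1(rng, config.ar_phi_other, len(block_prompts))
        other_likert[spec.name] = {
            "values": _discretize(z, config.likert_thresholds),
            "block": spec.block,
        }

    # per-prompt completion draws
    keep_u = rng.random(len(prompts))

    records: list[dict] = []
    key = f"SP{participant_index:04d}"
    daily_pos = {
        (row.date, row.slot): i for i, row in enumerate(daily_prompts.itertuples())
    }
    block_pos: dict[str, dict[tuple, int]] = {"daily": daily_pos}
    for block in ("morning", "evening", "weekly"):
        bp = _prompts_for_block(prompts, block)
        block_pos[block] = {
            (row.date, row.slot): i for i, row in enumerate(bp.itertuples())
        }

    for pi, row in enumerate(prompts.itertuples()):
        keep_p = completion
        if cm.evening_bias and row.slot == "evening":
            keep_p = max(0.0, completion - cm.evening_bias)
        if keep_u[pi] > keep_p:
            continue
        ts = pd.Timestamp.combine(row.date, row.drawn_time).tz_localize("UTC")
        for spec in cb.entries:
            if not _item_in_prompt(spec.block, row.slot):
                continue
            if spec.kind == "categorical":
                probs = config.category_probs(spec)
                value: object = str(
                    spec.categories[rng.choice(len(probs), p=probs)]
                )
            elif spec.name in net_likert:
                value = int(net_likert[spec.name][daily_pos[(row.date, row.slot)]])
            elif spec.name in other_likert:
                pos = block_pos[spec.block].get((row.date, row.slot))
                if pos is None:
                    continue
                value = int(other_likert[spec.name]["values"][pos])
            else:  # pragma: no cover - every likert item is mapped above
                continue
            records.append(
                {
                    "participant_key": key,
                    "date": row.date,
                    "slot": row.slot,
                    "timestamp": ts,
                    "variable": spec.name,
                    "value": value,
                }
            )
    df = pd.DataFrame(
        records,
        columns=["participant_key", "date", "slot", "timestamp", "variable", "value"],
    )
    return ResponseTable(df)


def _prompts_for_block(prompts: pd.DataFrame, block: str) -> pd.DataFrame:
    if block == "daily":
        sub = prompts[prompts["slot"].isin(DAILY_SLOTS)]
    elif block == "weekly":
        sub = prompts[prompts["slot"] == "weekly"]
    else:  # morning / evening
        sub = prompts[prompts["slot"] == block]
    return sub.reset_index(drop=True)


def _item_in_prompt(block: str, slot: str) -> bool:
    if block == "daily":
        return slot in DAILY_SLOTS
    if block == "weekly":
        return slot == "weekly"
    return slot == block  # morning / evening items in their own slot


def simulate_cohort(
    config: SyntheticConfig, schedule: EMASchedule | None = None
) -> ResponseTable:
    """Simulate all participants and concatenate their tables."""
    if schedule is None:
        schedule = build_schedule(
            config.start_date, config.end_date, weekly_day=config.weekly_day,
            seed=config.seed,
        )
    tables = [
        simulate_participant(config, i, schedule=schedule)
        for i in range(config.n_participants)
    ]
    frames = [t.records for t in tables if len(t.records)]
    if not frames:
        frames = [tables[0].records]
    df = pd.concat(frames, ignore_index=True)
    return ResponseTable(df)
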
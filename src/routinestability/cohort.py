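"""Synthetic cohort generator with known ground-truth routine stability.

Emulates the structure of a year-long passive-sensing study of people with
schizophrenia-spectrum disorders: per participant, a latent daily symptom
level follows an AR(1) process; each behavior realizes a personal routine
template (a few characteristic times of day) whose daily timing jitter
scales log-linearly with the latent symptom level,

    sigma_eff(day) = sigma_b * exp(beta_b * s_day),

so ``beta_b > 0`` means worse symptoms loosen that behavior's routine
(lower Stability Index) and ``beta_b < 0`` tightens it.  Daily behavior
volumes are drawn from moment-matched lognormals, independent of the
latent process, so timing information and volume information are separable
by construction.  EMA questionnaires are emitted every Monday, Wednesday
and Friday, with configurable missingness, by monotone thresholding of the
latent level into 10 items.

The default magnitudes, schedule and missingness mirror a real cohort of
this kind: ~3.4 incoming messages and ~467 still minutes per day, EMA
missing ~37% of the time, 13 participants followed for 365 days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from datetime import date, datetime, time, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .behavior_data import (
    BehaviorEvent,
    CoverageRecord,
    DayActivityVector,
    EmaResponse,
    write_coverage,
    write_ema,
    write_streams,
)
from .behaviors import (
    BEHAVIORS,
    DAILY_MAGNITUDES,
    EVENT_BEHAVIORS,
    MINUTES_PER_DAY,
    SCALAR_BEHAVIORS,
)

import pandas as pd

#: EMA item thresholds on the (noisy, standardized) latent scale; chosen so
#: item marginals are spread over 0..3 rather than collapsing to one level.
_ITEM_CUTPOINTS = (-0.8, 0.3, 1.3)

#: Default symptom-coupling coefficients: positive beta (more symptoms ->
#: more jitter -> lower SI -> negative SI/symptom correlation) for the
#: social/device behaviors, negative for stillness and ambient non-voice
#: sound, zero elsewhere.
DEFAULT_COUPLINGS: dict[str, float] = {
    # sparse count behaviors carry little timing information per day (one or
    # two spikes), so their coupling is stronger to yield effects comparable
    # to the dense period behaviors
    "incoming_messages": 1.2,
    "outgoing_messages": 1.2,
    "call": 0.6,
    "unlock": 0.6,
    "still": -0.6,
    "ambient_nonvoice": -0.6,
}

_DEFAULT_SLOTS: dict[str, int] = {
    "incoming_messages": 4,
    "outgoing_messages": 4,
    "call": 3,
    "unlock": 6,
    "conversation": 4,
    "ambient_light": 6,
    "ambient_sound_volume": 6,
    "ambient_voice": 4,
    "ambient_nonvoice": 4,
    "ambient_silence": 4,
    "sleep": 2,
    "on_bike": 1,
    "walk": 3,
    "in_vehicle": 2,
    "tilting": 4,
    "still": 5,
    "unknown_activity": 4,
}


@dataclass
class BehaviorModel:
    """Generative parameters for one behavior."""

    kind: str  # "event" | "period" | "scalar"
    daily_mean: float  # mean of the daily total (count / minutes / sensor units)
    daily_sd: float
    n_slots: int  # routine template size: characteristic event times per day
    jitter_sd: float  # baseline timing jitter sigma_b, minutes
    coupling: float = 0.0  # beta_b: latent symptom level -> log jitter scale

    def __post_init__(self) -> None:
        if self.kind not in ("event", "period", "scalar"):
            raise ValueError(f"unknown behavior kind {self.kind!r}")
        if self.daily_mean < 0 or self.daily_sd < 0 or self.jitter_sd < 0:
            raise ValueError("behavior magnitudes and jitter must be non-negative")
        if self.n_slots < 1:
            raise ValueError("n_slots must be >= 1")


def default_behavior_models(
    behaviors: Sequence[str] = BEHAVIORS,
    jitter_sd: float | None = None,
    couplings: dict[str, float] | None = None,
) -> dict[str, BehaviorModel]:
    """Table-scale magnitude defaults with the default coupling sign pattern."""
    couplings = DEFAULT_COUPLINGS if couplings is None else couplings
    models = {}
    for b in behaviors:
        mean, sd = DAILY_MAGNITUDES[b]
        kind = "event" if b in EVENT_BEHAVIORS else "scalar" if b in SCALAR_BEHAVIORS else "period"
        beta = couplings.get(b, 0.0)
        sigma = jitter_sd if jitter_sd is not None else (30.0 if beta != 0.0 else 20.0)
        models[b] = BehaviorModel(
            kind=kind,
            daily_mean=mean,
            daily_sd=sd,
            n_slots=_DEFAULT_SLOTS[b],
            jitter_sd=sigma,
            coupling=beta,
        )
    return models


@dataclass
class SyntheticCohortConfig:
    """Full generative specification of a synthetic cohort."""

    n_participants: int = 13
    n_days: int = 365
    start_date: date = date(2015, 1, 5)  # a Monday, so the EMA schedule starts day 1
    behaviors: dict[str, BehaviorModel] = field(default_factory=default_behavior_models)
    ar_phi: float = 0.8  # AR(1) persistence of the latent symptom level
    ar_sd: float = 0.6  # innovation SD (stationary SD = 1.0 with phi = 0.8)
    participant_offset_sd: float = 1.0  # trait-level symptom offset across participants
    ema_missing_rate: float = 0.37
    ema_item_noise: float = 0.5  # item-level latent noise SD
    coverage_dropout_scale: float = 2.0  # sensed_hours = 24 - Exponential(scale) hours
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1 < self.ar_phi < 1:
            raise ValueError("AR(1) coefficient must satisfy |phi| < 1")
        if not 0 <= self.ema_missing_rate <= 1:
            raise ValueError("ema_missing_rate must lie in [0, 1]")
        if self.n_days < 15:
            raise ValueError("n_days must exceed the window length")
        for b, m in self.behaviors.items():
            if b not in BEHAVIORS:
                raise ValueError(f"unknown behavior {b!r} in config")
            if not isinstance(m, BehaviorModel):
                raise TypeError("behaviors values must be BehaviorModel instances")

    @property
    def latent_stationary_sd(self) -> float:
        return self.ar_sd / math.sqrt(1.0 - self.ar_phi**2)


def default_config(seed: int = 0, **overrides) -> SyntheticCohortConfig:
    return SyntheticCohortConfig(seed=seed, **overrides)


@dataclass
class Cohort:
    """Generated data plus ground truth."""

    streams: list[BehaviorEvent]
    coverage: list[CoverageRecord]
    ema: list[EmaResponse]
    truth: pd.DataFrame  # participant_id, date, latent, offset, sigma_<behavior>...
    config: SyntheticCohortConfig


def _lognormal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Lognormal draws with the given arithmetic mean and SD (exact moments)."""
    if mean <= 0:
        return np.zeros(size)
    if sd <= 0:
        return np.full(size, mean)
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size)


def _stochastic_round(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Unbiased randomized rounding to integers."""
    lo = np.floor(x)
    return (lo + (rng.random(len(x)) < (x - lo))).astype(int)


def _minute_to_datetime(day: date, minute: float) -> datetime:
    return datetime.combine(day, time()) + timedelta(
        microseconds=round(minute * 60_000_000)
    )


def _participant_rng(seed: int, p_idx: int, stream: int) -> np.random.Generator:
    # fixed seed tree: adding participants or behaviors never disturbs
    # previously generated participants/behaviors
    return np.random.default_rng(np.random.SeedSequence((seed, p_idx, stream)))


def generate_cohort(config: SyntheticCohortConfig) -> Cohort:
    """Generate streams, coverage, EMA responses and the latent ground truth."""
    behaviors = list(config.behaviors)
    streams: list[BehaviorEvent] = []
    coverage: list[CoverageRecord] = []
    ema: list[EmaResponse] = []
    truth_rows: list[dict] = []
    sd_stat = config.latent_stationary_sd
    days = [config.start_date + timedelta(days=i) for i in range(config.n_days)]

    for p_idx in range(config.n_participants):
        pid = f"P{p_idx + 1:02d}"
        rng_latent = _participant_rng(config.seed, p_idx, 10_000)
        # latent symptom level = trait offset + AR(1) state; the offset flows
        # through everything downstream (routine jitter and EMA alike), so
        # chronically worse symptoms mean chronically looser routines
        offset = float(rng_latent.normal(0.0, config.participant_offset_sd))
        s = np.empty(config.n_days)
        s[0] = offset + rng_latent.normal(0.0, sd_stat)
        innov = rng_latent.normal(0.0, config.ar_sd, config.n_days - 1)
        for t in range(1, config.n_days):
            s[t] = offset + config.ar_phi * (s[t - 1] - offset) + innov[t - 1]

        sigmas = {
            b: m.jitter_sd * np.exp(m.coupling * s) for b, m in config.behaviors.items()
        }
        for t, d in enumerate(days):
            row = {"participant_id": pid, "date": d, "latent": s[t], "offset": offset}
            for b in behaviors:
                row[f"sigma_{b}"] = sigmas[b][t]
            truth_rows.append(row)

        for b_idx, b in enumerate(BEHAVIORS):
            if b not in config.behaviors:
                continue
            model = config.behaviors[b]
            rng = _participant_rng(config.seed, p_idx, b_idx)
            slots = np.sort(rng.uniform(60.0, 1380.0, model.n_slots))  # personal routine template
            totals = _lognormal(rng, model.daily_mean, model.daily_sd, config.n_days)
            for t, d in enumerate(days):
                sig = sigmas[b][t]
                if model.kind == "event":
                    count = int(_stochastic_round(totals[t : t + 1], rng)[0])
                    if count == 0:
                        continue
                    # cycle through the sorted template deterministically so
                    # day-to-day timing variation reflects jitter, not random
                    # slot selection
                    mins = slots[np.arange(count) % model.n_slots] + rng.normal(0.0, sig, count)
                    mins = np.clip(mins, 0.0, MINUTES_PER_DAY - 1e-3)
                    for m in np.sort(mins):
                        ts = _minute_to_datetime(d, float(m))
                        streams.append(BehaviorEvent(pid, b, ts, ts, 1.0))
                elif model.kind == "scalar":
                    if totals[t] <= 0:
                        continue
                    mag = totals[t] / model.n_slots
                    mins = slots + rng.normal(0.0, sig, model.n_slots)
                    mins = np.clip(mins, 0.0, MINUTES_PER_DAY - 1e-3)
                    for m in np.sort(mins):
                        ts = _minute_to_datetime(d, float(m))
                        streams.append(BehaviorEvent(pid, b, ts, ts, mag))
                else:  # period
                    if totals[t] <= 0:
                        continue
                    dur = totals[t] / model.n_slots
                    starts = slots + rng.normal(0.0, sig, model.n_slots)
                    starts = np.clip(starts, 0.0, MINUTES_PER_DAY - 1e-3)
                    for m in np.sort(starts):
                        ts = _minute_to_datetime(d, float(m))
                        # may cross midnight; the binner splits it
                        streams.append(
                            BehaviorEvent(pid, b, ts, ts + timedelta(minutes=dur), dur)
                        )

        rng_cov = _participant_rng(config.seed, p_idx, 10_001)
        dropout = rng_cov.exponential(config.coverage_dropout_scale, config.n_days)
        for t, d in enumerate(days):
            coverage.append(CoverageRecord(pid, d, float(np.clip(24.0 - dropout[t], 0.0, 24.0))))

        rng_ema = _participant_rng(config.seed, p_idx, 10_002)
        for t, d in enumerate(days):
            if d.weekday() not in (0, 2, 4):  # Monday, Wednesday, Friday
                continue
            missing = rng_ema.random() < config.ema_missing_rate
            z = s[t] / sd_stat
            noise = rng_ema.normal(0.0, config.ema_item_noise, 10)
            if missing:
                continue
            items = []
            for i in range(10):
                latent = (z if i < 5 else -z) + noise[i]
                items.append(int(np.searchsorted(_ITEM_CUTPOINTS, latent, side="right")))
            ema.append(EmaResponse(pid, d, tuple(items)))

    truth = pd.DataFrame(truth_rows)
    return Cohort(streams=streams, coverage=coverage, ema=ema, truth=truth, config=config)


def perturb_schedule(day: DayActivityVector, delta_minutes: int) -> DayActivityVector:
    """Shift every minute's mass later by exactly ``delta_minutes``.

    Errors if any mass would leave the day; total activity is conserved.
    """
    if delta_minutes < 0:
        raise ValueError("delta_minutes must be non-negative")
    a = day.amounts
    if delta_minutes == 0:
        return DayActivityVector(day.participant_id, day.behavior, day.date, a.copy())
    if delta_minutes >= len(a) or np.any(a[-delta_minutes:] > 0):
        raise ValueError(f"shifting by {delta_minutes} min would push activity past midnight")
    out = np.zeros_like(a)
    out[delta_minutes:] = a[:-delta_minutes]
    return DayActivityVector(day.participant_id, day.behavior, day.date, out)


# ---------------------------------------------------------------------------
# YAML config and cohort output
# ---------------------------------------------------------------------------


def config_to_yaml(config: SyntheticCohortConfig, path: str | Path) -> None:
    d = asdict(config)
    d["start_date"] = config.start_date.isoformat()
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def config_from_yaml(path: str | Path) -> SyntheticCohortConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if "start_date" in d:
        d["start_date"] = date.fromisoformat(d["start_date"])
    if "behaviors" in d:
        d["behaviors"] = {b: BehaviorModel(**m) for b, m in d["behaviors"].items()}
    return SyntheticCohortConfig(**d)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write streams.csv, coverage.csv, ema.csv, truth.csv and config.yaml."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "streams": out_dir / "streams.csv",
        "coverage": out_dir / "coverage.csv",
        "ema": out_dir / "ema.csv",
        "truth": out_dir / "truth.csv",
        "config": out_dir / "config.yaml",
    }
    write_streams(cohort.streams, paths["streams"])
    write_coverage(cohort.coverage, paths["coverage"])
    write_ema(cohort.ema, paths["ema"])
    truth = cohort.truth.copy()
    truth["date"] = truth["date"].map(lambda d: d.isoformat())
    truth.to_csv(paths["truth"], index=False)
    config_to_yaml(cohort.config, paths["config"])
    return paths
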
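"""EMA scoring, quality filtering, and windowed feature extraction.

Each EMA response anchors one candidate observation window: the 14 (or 7)
calendar days strictly preceding ``anchor - lead`` days.  A window is
retained when it contains at least ``min_good_days`` good days — days with
more than 19 hours of sensing coverage.  Per behavior the window yields
three features computed over the good days only: the Stability Index, and
the mean and (population) SD of the per-day totals.  The prediction target
is the EMA composite at the anchor; the previous-EMA feature is the
composite of the response dated exactly seven days earlier, when present.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .behavior_data import BehaviorEvent, CoverageRecord, EmaResponse, bin_events_by_day
from .behaviors import BEHAVIORS

logger = logging.getLogger(__name__)

GOOD_DAY_HOURS = 19.0  # strict: a 19.0 h day is not good
DEFAULT_WINDOW_DAYS = 14
DEFAULT_MIN_GOOD_DAYS = 7
DEFAULT_MIN_EMA = 25


def ema_composite(items: Sequence[int]) -> int:
    """Composite symptom score: sum of the 5 negative items minus the 5 positive.

    Items must be 10 integers in 0..3; the result lies in [-15, 15], higher
    meaning greater symptom severity and poorer functioning.
    """
    resp = EmaResponse(participant_id="_", date=date(2000, 1, 1), items=tuple(items))
    return resp.composite


def is_good_day(record: CoverageRecord, threshold_hours: float = GOOD_DAY_HOURS) -> bool:
    """True iff strictly more than ``threshold_hours`` of sensing were collected."""
    return record.sensed_hours > threshold_hours


@dataclass
class ObservationWindow:
    """One (participant, EMA anchor, lead) unit of analysis."""

    participant_id: str
    anchor_date: date
    lead_days: int
    window_days: int
    good_dates: frozenset[date]
    #: behavior -> {"si": float|None, "mean": float, "sd": float[, "abs_si": float|None]}
    features: dict[str, dict[str, float | None]] = field(repr=False)
    target: int = 0
    prev_ema: int | None = None


def _dedupe_ema(ema: Iterable[EmaResponse]) -> dict[tuple[str, date], EmaResponse]:
    out: dict[tuple[str, date], EmaResponse] = {}
    dupes = 0
    for r in ema:
        key = (r.participant_id, r.date)
        if key in out:
            dupes += 1
        out[key] = r  # keep the last by file order
    if dupes:
        logger.warning("dropped %d duplicate EMA response(s), keeping last by file order", dupes)
    return out


def build_windows(
    events: Iterable[BehaviorEvent],
    coverage: Iterable[CoverageRecord],
    ema: Iterable[EmaResponse],
    *,
    lead_days: int = 0,
    window_days: int = DEFAULT_WINDOW_DAYS,
    min_good_days: int = DEFAULT_MIN_GOOD_DAYS,
    behaviors: Sequence[str] = BEHAVIORS,
    include_absolute: bool = False,
    sd_ddof: int = 0,
) -> list[ObservationWindow]:
    """Construct observation windows for every EMA response that passes filtering.

    Features are computed over the good days of the half-open interval
    ``[anchor - lead - window, anchor - lead)``.  With ``include_absolute``
    the volume-sensitive absolute Stability Index is computed alongside for
    diagnostics.
    """
    if not 1 <= min_good_days <= window_days:
        raise ValueError("min_good_days must lie in 1..window_days")
    if lead_days < 0:
        raise ValueError("lead_days must be non-negative")

    responses = _dedupe_ema(ema)
    good: dict[str, set[date]] = {}
    for rec in coverage:
        if is_good_day(rec):
            good.setdefault(rec.participant_id, set()).add(rec.date)

    events_by_pb: dict[str, dict[str, list[BehaviorEvent]]] = {}
    n_events = 0
    for ev in events:
        events_by_pb.setdefault(ev.participant_id, {}).setdefault(ev.behavior, []).append(ev)
        n_events += 1

    windows: list[ObservationWindow] = []
    n_rejected = 0
    participants = sorted({pid for pid, _ in responses})
    for pid in participants:
        pid_responses = sorted(
            (r for (p, _), r in responses.items() if p == pid), key=lambda r: r.date
        )
        pid_good = good.get(pid, set())

        candidates: list[tuple[EmaResponse, list[date]]] = []
        for resp in pid_responses:
            hi = resp.date - timedelta(days=lead_days)  # exclusive
            lo = hi - timedelta(days=window_days)  # inclusive
            gdates = sorted(d for d in pid_good if lo <= d < hi)
            if len(gdates) >= min_good_days:
                candidates.append((resp, gdates))
            else:
                n_rejected += 1
        if not candidates:
            continue

        needed = sorted({d for _, gdates in candidates for d in gdates})
        per_behavior = {}
        for b in behaviors:
            per_behavior[b] = _behavior_window_stats(
                events_by_pb.get(pid, {}).get(b, []), needed, include_absolute
            )

        for resp, gdates in candidates:
            feats: dict[str, dict[str, float | None]] = {}
            for b in behaviors:
                cums, abscums, totals = per_behavior[b]
                day_totals = np.array([totals[d] for d in gdates])
                entry: dict[str, float | None] = {
                    "si": _pairwise_si([cums[d] for d in gdates]),
                    "mean": float(day_totals.mean()),
                    "sd": float(day_totals.std(ddof=sd_ddof)),
                }
                if include_absolute:
                    # same usable-day set as the normalized index
                    entry["abs_si"] = _pairwise_si(
                        [abscums[d] if totals[d] > 0 else None for d in gdates]
                    )
                feats[b] = entry
            prev = responses.get((pid, resp.date - timedelta(days=7)))
            windows.append(
                ObservationWindow(
                    participant_id=pid,
                    anchor_date=resp.date,
                    lead_days=lead_days,
                    window_days=window_days,
                    good_dates=frozenset(gdates),
                    features=feats,
                    target=resp.composite,
                    prev_ema=None if prev is None else prev.composite,
                )
            )
    logger.info(
        "built %d window(s) (lead %d) from %d events; %d candidate(s) rejected "
        "for insufficient good days",
        len(windows), lead_days, n_events, n_rejected,
    )
    return windows


def _behavior_window_stats(
    events: list[BehaviorEvent], needed_dates: list[date], include_absolute: bool
):
    """Per-date cumulatives (normalized and absolute) and totals for one behavior."""
    by_day = bin_events_by_day(events)
    cums: dict[date, np.ndarray | None] = {}
    abscums: dict[date, np.ndarray] = {}
    totals: dict[date, float] = {}
    for d in needed_dates:
        a = by_day.get(d)
        if a is None:
            totals[d] = 0.0
            cums[d] = None
            if include_absolute:
                abscums[d] = None
            continue
        total = float(a.sum())
        totals[d] = total
        if total > 0:
            c = np.cumsum(a)
            if include_absolute:
                abscums[d] = c
            cums[d] = c / total
            cums[d][-1] = 1.0
        else:
            cums[d] = None
            if include_absolute:
                abscums[d] = None
    return cums, abscums, totals


def _pairwise_si(curves: list[np.ndarray | None]) -> float | None:
    """1 - median pairwise mean-absolute-difference over the defined curves."""
    usable = [c for c in curves if c is not None]
    n = len(usable)
    if n < 2:
        return None
    stacked = np.stack(usable)
    iu, ju = np.triu_indices(n, k=1)
    dists = np.abs(stacked[iu] - stacked[ju]).mean(axis=1)
    return float(1.0 - np.median(dists))


# ---------------------------------------------------------------------------
# Flat feature tables
# ---------------------------------------------------------------------------

KEY_COLUMNS = ["participant_id", "anchor_date", "lead_days", "target", "prev_ema"]


def feature_columns(behaviors: Sequence[str] = BEHAVIORS, include_absolute: bool = False):
    cols = []
    for b in behaviors:
        cols += [f"{b}_si", f"{b}_mean", f"{b}_sd", f"{b}_si_missing"]
        if include_absolute:
            cols.append(f"{b}_abs_si")
    return cols


def windows_to_frame(
    windows: Sequence[ObservationWindow], behaviors: Sequence[str] = BEHAVIORS
) -> pd.DataFrame:
    """Flatten windows to one row per (participant, anchor, lead), fixed column order."""
    include_absolute = bool(windows) and "abs_si" in next(iter(windows)).features[behaviors[0]]
    rows = []
    for w in windows:
        row: dict = {
            "participant_id": w.participant_id,
            "anchor_date": w.anchor_date,
            "lead_days": w.lead_days,
            "target": w.target,
            "prev_ema": np.nan if w.prev_ema is None else float(w.prev_ema),
        }
        for b in behaviors:
            f = w.features[b]
            row[f"{b}_si"] = np.nan if f["si"] is None else f["si"]
            row[f"{b}_mean"] = f["mean"]
            row[f"{b}_sd"] = f["sd"]
            row[f"{b}_si_missing"] = int(f["si"] is None)
            if include_absolute:
                row[f"{b}_abs_si"] = np.nan if f["abs_si"] is None else f["abs_si"]
        rows.append(row)
    cols = KEY_COLUMNS + feature_columns(behaviors, include_absolute)
    df = pd.DataFrame(rows, columns=cols)
    if df.duplicated(subset=["participant_id", "anchor_date", "lead_days"]).any():
        raise ValueError("duplicate (participant, anchor, lead) keys in feature table")
    return df


def build_feature_table(events, coverage, ema, **kwargs) -> pd.DataFrame:
    """Convenience wrapper: :func:`build_windows` then :func:`windows_to_frame`."""
    behaviors = kwargs.get("behaviors", BEHAVIORS)
    return windows_to_frame(build_windows(events, coverage, ema, **kwargs), behaviors)


def retain_participants(table: pd.DataFrame, min_ema: int = DEFAULT_MIN_EMA) -> pd.DataFrame:
    """Keep participants with strictly more than ``min_ema`` usable windows."""
    counts = table.groupby("participant_id").size()
    keep = counts[counts > min_ema].index
    out = table[table["participant_id"].isin(keep)].reset_index(drop=True)
    logger.info(
        "retained %d of %d participant(s) with > %d windows",
        len(keep), counts.size, min_ema,
    )
    return out


def align_lead_datasets(tables: Mapping[int, pd.DataFrame]) -> dict[int, pd.DataFrame]:
    """Restrict each lead's table to the (participant, anchor) keys present at all leads."""
    key_sets = {
        lead: set(zip(t["participant_id"], t["anchor_date"])) for lead, t in tables.items()
    }
    common = set.intersection(*key_sets.values()) if key_sets else set()
    out = {}
    for lead, t in tables.items():
        mask = [k in common for k in zip(t["participant_id"], t["anchor_date"])]
        out[lead] = t[mask].reset_index(drop=True)
    logger.info(
        "aligned lead datasets to %d common key(s) (from %s)",
        len(common), {lead: len(s) for lead, s in key_sets.items()},
    )
    return out


def write_features(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    out["anchor_date"] = out["anchor_date"].map(
        lambda d: d.isoformat() if isinstance(d, date) else str(d)
    )
    out.to_csv(path, index=False)


def read_features(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str})
    df["anchor_date"] = df["anchor_date"].map(date.fromisoformat)
    return df
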
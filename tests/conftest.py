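"""Shared synthetic cohorts and feature tables (session-scoped: they are
the expensive part of the suite and are reused across test modules)."""

from __future__ import annotations

import numpy as np
import pytest

import routinestability as rs
from routinestability.cohort import DEFAULT_COUPLINGS


@pytest.fixture(scope="session")
def tiny_cohort():
    """3 participants, 60 days: fast end-to-end pipeline checks."""
    return rs.generate_cohort(rs.default_config(seed=11, n_participants=3, n_days=60))


@pytest.fixture(scope="session")
def tiny_table(tiny_cohort):
    c = tiny_cohort
    return rs.build_feature_table(c.streams, c.coverage, c.ema)


@pytest.fixture(scope="session")
def coupled_cohort():
    """5 participants, 180 days, default couplings; yields > 200 windows."""
    return rs.generate_cohort(rs.default_config(seed=12, n_participants=5, n_days=180))


@pytest.fixture(scope="session")
def coupled_table(coupled_cohort):
    c = coupled_cohort
    return rs.build_feature_table(c.streams, c.coverage, c.ema, include_absolute=True)


@pytest.fixture(scope="session")
def full_cohort_table():
    """The study-scale cohort: 13 participants, 365 days, Mon/Wed/Fri EMA
    with 37% missingness, magnitude defaults at cohort scale."""
    c = rs.generate_cohort(rs.default_config(seed=1))
    table = rs.build_feature_table(c.streams, c.coverage, c.ema)
    return rs.retain_participants(table)


@pytest.fixture(scope="session")
def hetero_table():
    """Cohort with large trait-level symptom offsets across participants and
    uncoupled behaviors: the offsets live in the symptom reports alone, so no
    model can recover a stranger's level from behavioral features."""
    c = rs.generate_cohort(
        rs.default_config(seed=3, n_participants=8, n_days=150,
                          participant_offset_sd=2.0,
                          behaviors=rs.default_behavior_models(couplings={}))
    )
    return rs.build_feature_table(c.streams, c.coverage, c.ema)


@pytest.fixture(scope="session")
def exchangeable_table():
    """Exchangeable participants in the regime where the shared feature-target
    mapping, not temporal recency, carries the signal: no offsets, weak latent
    persistence, strong timing coupling, low item noise."""
    strong = {b: 2.0 * v for b, v in DEFAULT_COUPLINGS.items()}
    cfg = rs.default_config(
        seed=4,
        n_participants=8,
        n_days=150,
        participant_offset_sd=0.0,
        ar_phi=0.4,
        ar_sd=float(np.sqrt(1 - 0.4**2)),
        behaviors=rs.default_behavior_models(couplings=strong),
        ema_item_noise=0.25,
    )
    c = rs.generate_cohort(cfg)
    return rs.build_feature_table(c.streams, c.coverage, c.ema)


@pytest.fixture(scope="session")
def timing_table():
    """Strongly coupled cohort whose symptom signal enters solely through
    timing jitter: daily totals are held constant, so SI carries all the
    symptom information and mean/SD carry none."""
    strong = {b: 2.0 * v for b, v in DEFAULT_COUPLINGS.items()}
    models = rs.default_behavior_models(couplings=strong)
    for m in models.values():
        m.daily_sd = 0.0
    cfg = rs.default_config(seed=13, n_participants=5, n_days=180,
                            behaviors=models, ema_item_noise=0.25)
    c = rs.generate_cohort(cfg)
    return rs.build_feature_table(c.streams, c.coverage, c.ema)
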
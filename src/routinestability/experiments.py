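"""Correlation and prediction experiments on windowed feature tables.

Two analytic designs operate on the feature tables produced by
:mod:`routinestability.features`:

* pooled Pearson correlations between a per-behavior feature (Stability
  Index, mean, SD, or the absolute-SI diagnostic) and the EMA composite,
  Bonferroni-corrected over the behavior family; and
* personalized symptom prediction with gradient-boosted regression trees
  (300 trees, depth 3, learning rate 0.17 — fixed for all experiments),
  evaluated by pooled mean absolute error on each participant's 10 most
  recent windows, with percentile bootstrap confidence intervals and
  Wilcoxon signed-rank comparisons between model arms.

Undefined Stability Index values (a behavior absent from a whole window)
are imputed as 0 — an out-of-range sentinel, since attainable SI values
exceed 1/1440 — only at model-fitting time; the feature tables carry an
explicit per-behavior missingness indicator alongside.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingRegressor

from .behaviors import BEHAVIORS

logger = logging.getLogger(__name__)

GBRT_N_TREES = 300
GBRT_MAX_DEPTH = 3
GBRT_LEARNING_RATE = 0.17

N_TEST_POINTS = 10
DEFAULT_N_BOOT = 1000

MODELS = (
    "prev_ema",
    "mean_sd",
    "si",
    "si_mean_sd",
    "baseline_population_mean",
)

FEATURE_KINDS = ("si", "mean", "sd", "absolute_si")


def model_feature_columns(model: str, behaviors: Sequence[str] = BEHAVIORS) -> list[str]:
    """Feature columns used by each named model arm."""
    si = [f"{b}_si" for b in behaviors] + [f"{b}_si_missing" for b in behaviors]
    mean_sd = [c for b in behaviors for c in (f"{b}_mean", f"{b}_sd")]
    if model == "prev_ema":
        return ["prev_ema"]
    if model == "mean_sd":
        return mean_sd
    if model == "si":
        return si
    if model == "si_mean_sd":
        return si + mean_sd
    if model == "baseline_population_mean":
        return []
    raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------


def correlation_table(
    features: pd.DataFrame,
    kind: str = "si",
    behaviors: Sequence[str] = BEHAVIORS,
    family_size: int | None = None,
) -> pd.DataFrame:
    """Pooled Pearson correlation of one feature kind against the EMA composite.

    One row per behavior with the raw and Bonferroni-corrected two-sided
    p-value (family = number of behaviors tested unless overridden).
    Zero-variance or too-small samples yield an undefined ``r`` with the
    ``degenerate`` flag set.
    """
    if kind not in FEATURE_KINDS:
        raise ValueError(f"unknown feature kind {kind!r}; expected one of {FEATURE_KINDS}")
    suffix = {"si": "_si", "mean": "_mean", "sd": "_sd", "absolute_si": "_abs_si"}[kind]
    family = family_size if family_size is not None else len(behaviors)
    rows = []
    for b in behaviors:
        col = f"{b}{suffix}"
        if col not in features.columns:
            raise KeyError(f"feature column {col!r} absent from table")
        sub = features[[col, "target"]].dropna()
        x, y = sub[col].to_numpy(float), sub["target"].to_numpy(float)
        n = len(sub)
        if n < 3 or np.std(x) == 0 or np.std(y) == 0:
            rows.append(
                dict(behavior=b, kind=kind, r=np.nan, p_raw=np.nan,
                     p_bonferroni=np.nan, n=n, degenerate=True)
            )
            continue
        r, p = stats.pearsonr(x, y)
        rows.append(
            dict(behavior=b, kind=kind, r=float(r), p_raw=float(p),
                 p_bonferroni=float(min(1.0, p * family)), n=n, degenerate=False)
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GBRT fitting
# ---------------------------------------------------------------------------


def _design_matrix(frame: pd.DataFrame, columns: Sequence[str]) -> np.ndarray:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ValueError(f"feature column(s) {missing} absent from table")
    return frame[list(columns)].fillna(0.0).to_numpy(float)


def fit_predict(
    train: pd.DataFrame,
    test: pd.DataFrame,
    feature_columns: Sequence[str],
    seed: int = 0,
) -> np.ndarray:
    """Fit the fixed-hyperparameter GBRT on ``train`` and predict ``test``."""
    if len(train) == 0:
        raise ValueError("empty training set")
    X = _design_matrix(train, feature_columns)
    y = train["target"].to_numpy(float)
    model = GradientBoostingRegressor(
        n_estimators=GBRT_N_TREES,
        max_depth=GBRT_MAX_DEPTH,
        learning_rate=GBRT_LEARNING_RATE,
        random_state=seed,
    )
    model.fit(X, y)
    return model.predict(_design_matrix(test, feature_columns))


# ---------------------------------------------------------------------------
# Experiment harness
# ---------------------------------------------------------------------------


@dataclass
class ExperimentResult:
    """Pooled prediction errors for one model arm."""

    model: str
    lead_days: int
    n_train: int
    errors: dict[tuple[str, date], float] = field(repr=False)
    mae: float = np.nan
    ci95: tuple[float, float] = (np.nan, np.nan)
    seed: int = 0
    n_skipped: int = 0
    n_participants: int = 0

    def to_json_dict(self) -> dict:
        return {
            "model": self.model,
            "lead_days": self.lead_days,
            "n_train": self.n_train,
            "mae": self.mae,
            "ci95": list(self.ci95),
            "seed": self.seed,
            "n_skipped_participants": self.n_skipped,
            "n_participants": self.n_participants,
            "n_test_points": len(self.errors),
            "errors": {f"{pid}|{d.isoformat()}": e for (pid, d), e in self.errors.items()},
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1, sort_keys=True)


def _finalize(result: ExperimentResult, n_boot: int) -> ExperimentResult:
    errs = np.array(list(result.errors.values()))
    if len(errs):
        result.mae = float(errs.mean())
        result.ci95 = bootstrap_ci(errs, n_boot=n_boot, seed=result.seed)
    return result


def _sorted_participant(df: pd.DataFrame) -> pd.DataFrame:
    # anchor dates are unique per participant after window deduplication;
    # participant_id breaks nothing but keeps the sort total
    return df.sort_values(["anchor_date", "participant_id"], kind="mergesort")


def _split(df_p: pd.DataFrame, n_train: int, n_test: int):
    """(train, test) blocks: test = n_test most recent, train = the n_train before."""
    if len(df_p) < n_train + n_test:
        return None
    df_p = _sorted_participant(df_p)
    test = df_p.iloc[-n_test:]
    train = df_p.iloc[-(n_test + n_train) : -n_test] if n_train else df_p.iloc[0:0]
    return train, test


def _error_dict(test: pd.DataFrame, preds: np.ndarray) -> dict[tuple[str, date], float]:
    y = test["target"].to_numpy(float)
    keys = list(zip(test["participant_id"], test["anchor_date"]))
    return dict(zip(keys, np.abs(y - preds)))


def run_individual_experiment(
    features: pd.DataFrame,
    model: str,
    n_train: int,
    seed: int = 0,
    n_test: int = N_TEST_POINTS,
    n_boot: int = DEFAULT_N_BOOT,
) -> ExperimentResult:
    """Personalized prediction: one GBRT per participant, errors pooled.

    Test points are each participant's ``n_test`` most recent windows;
    training uses the ``n_train`` windows immediately preceding them.  The
    ``baseline_population_mean`` arm predicts the mean target of all pooled
    training rows; the ``prev_ema`` arm is evaluated only on rows where a
    response exactly 7 days before the anchor exists.
    """
    cols = model_feature_columns(model)
    df = features
    if model == "prev_ema":
        df = df[df["prev_ema"].notna()]
    lead = int(df["lead_days"].iloc[0]) if len(df) else 0

    splits = {}
    n_skipped = 0
    for pid, df_p in features.groupby("participant_id", sort=True):
        split = _split(df_p, n_train, n_test)
        if split is None:
            n_skipped += 1
            logger.warning("participant %s skipped: fewer than %d windows", pid, n_train + n_test)
            continue
        train, test = split
        if model == "prev_ema":
            train = train[train["prev_ema"].notna()]
            test = test[test["prev_ema"].notna()]
            if len(train) == 0 or len(test) == 0:
                n_skipped += 1
                continue
        splits[pid] = (train, test)

    result = ExperimentResult(
        model=model, lead_days=lead, n_train=n_train, errors={},
        seed=seed, n_skipped=n_skipped, n_participants=len(splits),
    )
    if not splits:
        return result

    if model == "baseline_population_mean":
        pooled = pd.concat([tr for tr, _ in splits.values()])
        mean_target = float(pooled["target"].mean())
        for _, (_, test) in splits.items():
            result.errors.update(_error_dict(test, np.full(len(test), mean_target)))
        return _finalize(result, n_boot)

    for pid, (train, test) in splits.items():
        preds = fit_predict(train, test, cols, seed=seed)
        result.errors.update(_error_dict(test, preds))
    return _finalize(result, n_boot)


def run_population_experiment(
    features: pd.DataFrame,
    model: str,
    n_user: int,
    seed: int = 0,
    n_test: int = N_TEST_POINTS,
    n_pop_train: int = 15,
    n_boot: int = DEFAULT_N_BOOT,
) -> dict[str, ExperimentResult]:
    """Individual-only vs individual+population vs population-only arms.

    For each target participant the population pool is every *other*
    participant's ``n_pop_train`` training points (their blocks immediately
    preceding their own test windows, so no test row ever enters training).
    The combined arm appends a binary same-individual indicator; the
    individual-only arm with ``n_user = 0`` falls back to predicting the
    pooled training-target mean.  All three arms share identical test sets.
    """
    if not 0 <= n_user <= n_pop_train:
        raise ValueError("n_user must lie in 0..n_pop_train")
    cols = model_feature_columns(model)
    if model in ("baseline_population_mean", "prev_ema"):
        raise ValueError(f"population experiment is not defined for model {model!r}")

    splits = {}
    n_skipped = 0
    for pid, df_p in features.groupby("participant_id", sort=True):
        split = _split(df_p, n_pop_train, n_test)
        if split is None:
            n_skipped += 1
            continue
        splits[pid] = split
    if len(splits) < 2:
        raise ValueError("population experiment requires at least 2 eligible participants")

    lead = int(features["lead_days"].iloc[0])
    arms = {
        name: ExperimentResult(
            model=f"{model}:{name}", lead_days=lead, n_train=n_user, errors={},
            seed=seed, n_skipped=n_skipped, n_participants=len(splits),
        )
        for name in ("individual_only", "individual_plus_population", "population_only")
    }
    pooled_train_mean = float(
        pd.concat([tr for tr, _ in splits.values()])["target"].mean()
    )

    for pid, (train_p, test) in splits.items():
        user_train = train_p.iloc[len(train_p) - n_user :] if n_user else train_p.iloc[0:0]
        pop_train = pd.concat([tr for q, (tr, _) in splits.items() if q != pid])

        # individual-only, with population-mean fallback at n_user = 0
        if n_user == 0:
            preds = np.full(len(test), pooled_train_mean)
        else:
            preds = fit_predict(user_train, test, cols, seed=seed)
        arms["individual_only"].errors.update(_error_dict(test, preds))

        # individual + population with same-individual indicator
        combo = pd.concat([user_train, pop_train]).copy()
        combo["same_individual"] = [1.0] * len(user_train) + [0.0] * len(pop_train)
        test_ind = test.copy()
        test_ind["same_individual"] = 1.0
        preds = fit_predict(combo, test_ind, list(cols) + ["same_individual"], seed=seed)
        arms["individual_plus_population"].errors.update(_error_dict(test, preds))

        # population-only
        preds = fit_predict(pop_train, test, cols, seed=seed)
        arms["population_only"].errors.update(_error_dict(test, preds))

    return {name: _finalize(res, n_boot) for name, res in arms.items()}


def run_lead_experiment(
    tables: Mapping[int, pd.DataFrame],
    model: str,
    n_train: int,
    seed: int = 0,
    n_test: int = N_TEST_POINTS,
    n_boot: int = DEFAULT_N_BOOT,
) -> tuple[dict[int, ExperimentResult], dict[tuple[int, int], dict]]:
    """Prediction at multiple lead times on key-aligned tables.

    Raises if the (participant, anchor) key sets differ across leads; the
    per-lead results are compared pairwise by two-sided Wilcoxon signed-rank
    tests on the matched per-point absolute errors.
    """
    key_sets = {
        lead: set(zip(t["participant_id"], t["anchor_date"])) for lead, t in tables.items()
    }
    leads = sorted(tables)
    for lead in leads[1:]:
        if key_sets[lead] != key_sets[leads[0]]:
            raise ValueError(
                f"lead {lead} table keys differ from lead {leads[0]}; "
                "run align_lead_datasets first"
            )
    results = {
        lead: run_individual_experiment(
            tables[lead], model, n_train, seed=seed, n_test=n_test, n_boot=n_boot
        )
        for lead in leads
    }
    comparisons = {}
    for i, l1 in enumerate(leads):
        for l2 in leads[i + 1 :]:
            comparisons[(l1, l2)] = wilcoxon_compare(results[l1].errors, results[l2].errors)
    return results, comparisons


def wilcoxon_compare(
    errors1: Mapping[tuple[str, date], float],
    errors2: Mapping[tuple[str, date], float],
) -> dict:
    """Two-sided Wilcoxon signed-rank test on matched per-point absolute errors.

    The reported statistic is the signed rank sum R+ - R- (positive when the
    first arm has larger errors), so swapping the arms flips its sign while
    the p-value is unchanged.  All-zero differences yield p = 1 by convention.
    """
    keys = sorted(set(errors1) & set(errors2))
    if len(keys) < 1:
        raise ValueError("no matched error pairs to compare")
    d = np.array([errors1[k] - errors2[k] for k in keys])
    nz = d[d != 0]
    if len(nz) == 0:
        return {"statistic": 0.0, "p_value": 1.0, "n": len(keys)}
    ranks = stats.rankdata(np.abs(nz))
    signed = float(np.sum(ranks[nz > 0]) - np.sum(ranks[nz < 0]))
    p = float(stats.wilcoxon(nz, alternative="two-sided").pvalue)
    return {"statistic": signed, "p_value": p, "n": len(keys)}


def bootstrap_ci(
    errors: Sequence[float] | np.ndarray,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile 95% CI of the MAE under resampling errors with replacement."""
    errs = np.asarray(errors, dtype=float)
    if len(errs) < 2:
        raise ValueError("bootstrap requires at least 2 errors")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(errs), size=(n_boot, len(errs)))
    means = errs[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return float(lo), float(hi)
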
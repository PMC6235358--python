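"""Orchestration: cohort -> cleaned windows -> feature table -> evaluation/reports.

These functions back both the Python API and the ``vtwarn`` command line.
Every record that drops out of the analysis is reported once with a
machine-readable reason code (``below_1700_normal_beats``,
``window_too_short`` or ``feature_error``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import EvalConfig, EvalResult, mann_whitney_u, run_evaluation
from .features import SCALAR_FEATURES, extract_feature_row
from .records import (
    Cohort,
    DEFAULT_WINDOW_M,
    MIN_NORMAL_BEATS,
    PRE_SHOCK,
    REGULAR,
    RRValidationError,
    WindowTooShortError,
    check_inclusion,
    extract_pre_event_window,
    filter_ectopic_beats,
)

__all__ = ["Exclusion", "featurize_cohort", "evaluate_cohort", "group_statistics"]

log = logging.getLogger("vtwarn")


@dataclass
class Exclusion:
    record_id: str
    reason: str
    detail: str = ""


def featurize_cohort(
    cohort: Cohort, horizon: str, m: int | None = None
) -> tuple[pd.DataFrame, np.ndarray, list[Exclusion]]:
    """Clean, window and featurize every record of a cohort.

    Per record: ectopy filtering -> >=1700-normal-beat inclusion -> pre-event
    horizon trim and last-*m* window -> ten scalar features. Returns the
    feature table (one row per surviving record), the aligned (n, m) window
    array, and the exclusion list.
    """
    if m is None:
        m = DEFAULT_WINDOW_M[horizon]
    rows: list[dict] = []
    windows: list[np.ndarray] = []
    exclusions: list[Exclusion] = []
    for rec in cohort.records:
        clean = filter_ectopic_beats(rec)
        if clean.n_normal() < MIN_NORMAL_BEATS:
            exclusions.append(
                Exclusion(rec.record_id, "below_1700_normal_beats", f"{clean.n_normal()} normal beats")
            )
            continue
        try:
            window = extract_pre_event_window(clean, horizon, m)
        except WindowTooShortError as exc:
            exclusions.append(Exclusion(rec.record_id, "window_too_short", str(exc)))
            continue
        try:
            row = extract_feature_row(
                window,
                {"patient_id": rec.patient_id, "record_id": rec.record_id, "label": rec.rhythm_class},
            )
        except RRValidationError as exc:
            exclusions.append(Exclusion(rec.record_id, "feature_error", str(exc)))
            continue
        rows.append(row.as_dict())
        windows.append(window)
    for exc in exclusions:
        log.info("excluded record=%s reason=%s detail=%s", exc.record_id, exc.reason, exc.detail)
    if not rows:
        raise RRValidationError("featurize_cohort: no records survive cleaning and windowing")
    features = pd.DataFrame(rows)
    return features, np.vstack(windows), exclusions


def evaluate_cohort(
    cohort: Cohort, config: EvalConfig
) -> tuple[EvalResult, pd.DataFrame, list[Exclusion]]:
    """Featurize at the config's horizon and run the repeated balanced evaluation."""
    features, windows, exclusions = featurize_cohort(cohort, config.horizon, config.window_m)
    result = run_evaluation(features, windows, config)
    return result, features, exclusions


def group_statistics(features: pd.DataFrame) -> pd.DataFrame:
    """Median (IQR) per class and two-sided Mann-Whitney p for each scalar feature.

    Computed on the full (unbalanced) feature table, one row per feature,
    with the pre-shock group as group A and regular rhythms as group B.
    """
    labels = set(features["label"].unique())
    if not {REGULAR, PRE_SHOCK} <= labels:
        raise RRValidationError("group_statistics: both rhythm classes must be present")
    rows = []
    for feature in SCALAR_FEATURES:
        a = features.loc[features["label"] == PRE_SHOCK, feature]
        b = features.loc[features["label"] == REGULAR, feature]
        t = mann_whitney_u(a, b, feature=feature)
        rows.append(
            {
                "feature": feature,
                "regular_median": t.median_b,
                "regular_q25": t.iqr_b[0],
                "regular_q75": t.iqr_b[1],
                "preshock_median": t.median_a,
                "preshock_q25": t.iqr_a[0],
                "preshock_q75": t.iqr_a[1],
                "u_statistic": t.u_statistic,
                "p_value": t.p_value,
            }
        )
    return pd.DataFrame(rows)


def eval_result_to_json(result: EvalResult) -> str:
    """Metrics JSON: config echo, per-trial arrays, aggregates, importances."""
    cfg = result.config
    payload = {
        "config": {
            "horizon": cfg.horizon,
            "window_m": cfg.window_m,
            "n_trials": cfg.n_trials,
            "train_fraction": cfg.train_fraction,
            "seed": cfg.seed,
            "classifiers": list(cfg.classifiers),
            "n_trees": cfg.n_trees,
            "svm_c": cfg.svm_c,
            "group_by_patient": cfg.group_by_patient,
        },
        "per_trial": result.per_trial,
        "aggregate": result.aggregate,
        "importance": result.importance,
        "retained_ranks": result.retained_ranks,
        "n_aborted": result.n_aborted,
    }
    return json.dumps(payload, indent=2, sort_keys=True)
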
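"""Balanced repeated train/test evaluation of the arrhythmia warning classifiers.

The cohort is heavily imbalanced (many routine downloads per pre-shock
buffer), so each trial (i) undersamples the regular-rhythm class down to the
pre-shock count, (ii) makes a stratified 80/20 train/test split, (iii) fits
the tachogram PCA on the training windows only and augments every row with
its PC coefficients, (iv) trains a random forest and/or a linear SVM, and
(v) scores the held-out test rows. Sensitivity, specificity and AUC are
aggregated as mean (SD) over trials; predictor importance comes from the
random forest's out-of-bag permutation importance.

Positive class: ``pre_appropriate_shock``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils import check_random_state

from .features import PREDICTOR_SCALAR_ORDER
from .pca import fit_windows, project_record
from .records import PRE_SHOCK, REGULAR, RRValidationError

__all__ = [
    "EvalConfig",
    "EvalResult",
    "GroupTest",
    "balance_by_undersampling",
    "split_train_test",
    "train_random_forest",
    "train_linear_svm",
    "roc_auc",
    "sensitivity_specificity",
    "permutation_importance",
    "run_evaluation",
    "mann_whitney_u",
    "POSITIVE_CLASS",
]

POSITIVE_CLASS = PRE_SHOCK
NEGATIVE_CLASS = REGULAR

DEFAULT_N_TREES = 500
DEFAULT_SVM_C = 1.0


@dataclass
class EvalConfig:
    horizon: str = "five_minute"
    window_m: int | None = None  # defaults to 1000 / 1600 by horizon
    n_trials: int = 100
    train_fraction: float = 0.8
    seed: int = 0
    classifiers: tuple[str, ...] = ("random_forest", "linear_svm")
    n_trees: int = DEFAULT_N_TREES
    svm_c: float = DEFAULT_SVM_C
    group_by_patient: bool = False  # leakage-safe alternative split
    compute_importance: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise RRValidationError("train_fraction must be in (0, 1)")
        if self.n_trials < 1:
            raise RRValidationError("n_trials must be >= 1")
        unknown = set(self.classifiers) - {"random_forest", "linear_svm"}
        if unknown:
            raise RRValidationError(f"unknown classifiers {sorted(unknown)}")


@dataclass
class GroupTest:
    """Mann-Whitney comparison of one feature between the two rhythm groups."""

    feature: str
    median_a: float
    iqr_a: tuple[float, float]
    median_b: float
    iqr_b: tuple[float, float]
    u_statistic: float
    p_value: float


@dataclass
class EvalResult:
    config: EvalConfig
    per_trial: list[dict]  # one dict per (trial, classifier)
    aggregate: dict  # classifier -> metric -> {"mean": ..., "sd": ...}
    importance: dict  # predictor name -> mean RF importance
    n_aborted: int = 0
    retained_ranks: list[int] = field(default_factory=list)

    def table4_frame(self) -> pd.DataFrame:
        """Mean (SD) of sensitivity, specificity and AUC per classifier."""
        rows = {}
        for clf, metrics in self.aggregate.items():
            rows[clf] = {
                metric: f"{v['mean']:.2f} ({v['sd']:.3f})" for metric, v in metrics.items()
            }
        return pd.DataFrame(rows)


def balance_by_undersampling(rows: pd.DataFrame, rng_seed: int) -> pd.DataFrame:
    """Undersample the majority class (without replacement) to the minority size.

    The minority class is kept whole; already balanced input is returned
    unchanged. Deterministic given *rng_seed*.
    """
    counts = rows["label"].value_counts()
    if not {POSITIVE_CLASS, NEGATIVE_CLASS} <= set(counts.index):
        raise RRValidationError("balance_by_undersampling: both classes must be present")
    if counts[POSITIVE_CLASS] == counts[NEGATIVE_CLASS]:
        return rows
    minority = counts.idxmin()
    majority = counts.idxmax()
    rng = np.random.default_rng(rng_seed)
    maj_idx = rows.index[rows["label"] == majority].to_numpy()
    keep = rng.choice(maj_idx, size=int(counts.min()), replace=False)
    balanced = pd.concat([rows.loc[rows["label"] == minority], rows.loc[np.sort(keep)]])
    return balanced.sort_index()


def split_train_test(
    rows: pd.DataFrame,
    train_fraction: float,
    rng_seed: int,
    group_by_patient: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/test split: round(train_fraction * class size) per class.

    With ``group_by_patient`` the split is made over patients within each
    class instead of records, so no patient contributes to both sets (the
    leakage-safe alternative; the record-level split matches the study
    protocol).
    """
    rng = np.random.default_rng(rng_seed)
    for label, grp in rows.groupby("label", sort=True):
        if len(grp) < 5:
            raise RRValidationError(f"split_train_test: class {label!r} has < 5 rows")
    if group_by_patient:
        # patients are assigned globally (one may contribute to both classes),
        # filling the training set until it holds ~train_fraction of the rows
        patients = rng.permutation(np.sort(rows["patient_id"].unique()))
        target = train_fraction * len(rows)
        train_pat: set = set()
        n_assigned = 0
        counts = rows["patient_id"].value_counts()
        for pat in patients:
            if n_assigned >= target:
                break
            train_pat.add(pat)
            n_assigned += int(counts[pat])
        train = rows[rows["patient_id"].isin(train_pat)]
        test = rows[~rows["patient_id"].isin(train_pat)]
        for part, name in ((train, "training"), (test, "test")):
            if part["label"].nunique() < 2:
                raise RRValidationError(
                    f"split_train_test: patient-grouped {name} set lost a class"
                )
        return train, test
    train_parts, test_parts = [], []
    for label, grp in rows.groupby("label", sort=True):
        perm = rng.permutation(grp.index.to_numpy())
        n_train = int(round(train_fraction * len(grp)))
        train_parts.append(grp.loc[np.sort(perm[:n_train])])
        test_parts.append(grp.loc[np.sort(perm[n_train:])])
    return pd.concat(train_parts), pd.concat(test_parts)


@dataclass
class FittedClassifier:
    """A trained model exposing a continuous score (higher = more pre-shock-like)."""

    name: str
    score: Callable[[np.ndarray], np.ndarray]
    predict: Callable[[np.ndarray], np.ndarray]  # boolean: True = positive class
    estimator: object = None
    scaler: object = None


def train_random_forest(
    X: np.ndarray, y: np.ndarray, rng_seed: int, n_trees: int = DEFAULT_N_TREES
) -> FittedClassifier:
    """Bootstrap-aggregated forest with sqrt(p) features per split.

    The score of a row is the fraction of trees voting for the positive class;
    the class decision thresholds that vote fraction at 0.5.
    """
    y = np.asarray(y, dtype=bool)
    if X.shape[0] == 0 or len(np.unique(y)) < 2:
        raise RRValidationError("train_random_forest: need both classes in training data")
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        bootstrap=True,
        random_state=rng_seed,
        n_jobs=1,
    )
    clf.fit(X, y)
    pos_col = int(np.flatnonzero(clf.classes_)[0])
    return FittedClassifier(
        name="random_forest",
        score=lambda Z: clf.predict_proba(Z)[:, pos_col],
        predict=lambda Z: clf.predict_proba(Z)[:, pos_col] > 0.5,
        estimator=clf,
    )


def train_linear_svm(
    X: np.ndarray, y: np.ndarray, rng_seed: int, c: float = DEFAULT_SVM_C
) -> FittedClassifier:
    """Linear-kernel maximum-margin classifier on standardized features.

    Features are z-scored with training mean/SD only; the score is the signed
    decision margin and the class decision thresholds it at 0.
    """
    y = np.asarray(y, dtype=bool)
    if X.shape[0] == 0 or len(np.unique(y)) < 2:
        raise RRValidationError("train_linear_svm: need both classes in training data")
    scaler = StandardScaler().fit(X)
    clf = SVC(kernel="linear", C=c, random_state=rng_seed)
    clf.fit(scaler.transform(X), y)
    # decision_function is positive for classes_[1]; with boolean labels that
    # is the positive (pre-shock) class.
    return FittedClassifier(
        name="linear_svm",
        score=lambda Z: clf.decision_function(scaler.transform(Z)),
        predict=lambda Z: clf.decision_function(scaler.transform(Z)) > 0.0,
        estimator=clf,
        scaler=scaler,
    )


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """AUC via the rank (Mann-Whitney) identity with midranks for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise RRValidationError("roc_auc: both classes must be present")
    ranks = stats.rankdata(scores)
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def sensitivity_specificity(
    predictions: Sequence[bool], labels: Sequence[bool]
) -> tuple[float, float]:
    """(TP/(TP+FN), TN/(TN+FP)) with the pre-shock group as positive."""
    predictions = np.asarray(predictions, dtype=bool)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise RRValidationError("sensitivity_specificity: both classes must be present")
    tp = int(np.count_nonzero(predictions & labels))
    tn = int(np.count_nonzero(~predictions & ~labels))
    return tp / n_pos, tn / n_neg


def _bootstrap_oob_masks(forest: RandomForestClassifier, n_samples: int) -> list[np.ndarray]:
    """Out-of-bag mask per tree, reproducing sklearn's bootstrap index draw."""
    masks = []
    for tree in forest.estimators_:
        rnd = check_random_state(tree.random_state)
        sampled = rnd.randint(0, n_samples, n_samples)
        mask = np.ones(n_samples, dtype=bool)
        mask[sampled] = False
        masks.append(mask)
    return masks


def permutation_importance(
    forest: FittedClassifier | RandomForestClassifier,
    X: np.ndarray,
    y: np.ndarray,
    rng_seed: int = 0,
) -> np.ndarray:
    """Out-of-bag permutation importance of each predictor.

    For every tree, the misclassification rate on its out-of-bag rows is
    compared with the rate after permuting one predictor across those rows;
    the importance of the predictor is the increase in error averaged over
    trees. Deterministic given *rng_seed*.
    """
    clf = forest.estimator if isinstance(forest, FittedClassifier) else forest
    if not isinstance(clf, RandomForestClassifier):
        raise RRValidationError("permutation_importance: expected a fitted random forest")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise RRValidationError("permutation_importance: X rows must align with y")
    n, p = X.shape
    rng = np.random.default_rng(rng_seed)
    deltas = np.zeros(p)
    n_used = 0
    for tree, oob in zip(clf.estimators_, _bootstrap_oob_masks(clf, n)):
        n_oob = int(oob.sum())
        if n_oob == 0:
            continue
        Xo, yo = X[oob], y[oob]
        base_err = np.mean(tree.predict(Xo).astype(bool) != yo)
        # one stacked predict call per tree: block j has predictor j permuted
        stacked = np.tile(Xo, (p, 1))
        for j in range(p):
            stacked[j * n_oob : (j + 1) * n_oob, j] = rng.permutation(Xo[:, j])
        pred = tree.predict(stacked).astype(bool).reshape(p, n_oob)
        deltas += (pred != yo).mean(axis=1) - base_err
        n_used += 1
    if n_used == 0:
        raise RRValidationError("permutation_importance: no out-of-bag samples")
    return deltas / n_used


def mann_whitney_u(
    group_a: Sequence[float], group_b: Sequence[float], feature: str = ""
) -> GroupTest:
    """Two-sided Mann-Whitney U-test plus medians and interquartile ranges.

    Exact enumeration is used for min(n) <= 8 (when there are no cross-group
    ties); otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise RRValidationError("mann_whitney_u: both groups must be non-empty")
    method = "exact" if min(a.size, b.size) <= 8 else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupTest(
        feature=feature,
        median_a=float(np.median(a)),
        iqr_a=(float(np.percentile(a, 25)), float(np.percentile(a, 75))),
        median_b=float(np.median(b)),
        iqr_b=(float(np.percentile(b, 25)), float(np.percentile(b, 75))),
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )


_TRAINERS = {
    "random_forest": lambda X, y, seed, cfg: train_random_forest(X, y, seed, cfg.n_trees),
    "linear_svm": lambda X, y, seed, cfg: train_linear_svm(X, y, seed, cfg.svm_c),
}


def _predictor_matrix(
    rows: pd.DataFrame, pcs: dict[str, np.ndarray], k: int
) -> tuple[np.ndarray, list[str]]:
    """Assemble [PC1..PCk, alpha1, alpha2, mean_nn, bp1..bp5, complexity, mobility]."""
    pc_block = np.vstack([pcs[rid] for rid in rows["record_id"]])
    scalars = rows[PREDICTOR_SCALAR_ORDER].to_numpy(dtype=float)
    names = [f"pc{i}" for i in range(1, k + 1)] + list(PREDICTOR_SCALAR_ORDER)
    return np.hstack([pc_block, scalars]), names


def run_evaluation(
    features: pd.DataFrame, windows: np.ndarray, config: EvalConfig
) -> EvalResult:
    """Repeated balanced train/test evaluation (balance -> split -> PCA -> classify).

    *features* holds one row per record (columns ``record_id``, ``patient_id``,
    ``label`` and the ten scalar features); *windows* is the aligned
    (n_records, m) array of analysis windows. The PCA is refit on the training
    windows of every trial, so test records never influence the components or
    the retained rank. Trial i draws its randomness from ``config.seed + i``.
    Trials that fail are skipped; more than 10% failures aborts the run.
    """
    features = features.reset_index(drop=True)
    windows = np.asarray(windows, dtype=float)
    if windows.shape[0] != len(features):
        raise RRValidationError("run_evaluation: windows must align with feature rows")
    per_trial: list[dict] = []
    importance_sums: dict[str, float] = {}
    importance_counts: dict[str, int] = {}
    ranks: list[int] = []
    n_aborted = 0
    errors: list[str] = []
    for trial in range(config.n_trials):
        trial_seed = config.seed + trial
        sub = np.random.SeedSequence(trial_seed).spawn(5)
        seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in sub]
        try:
            balanced = balance_by_undersampling(features, seeds[0])
            train, test = split_train_test(
                balanced, config.train_fraction, seeds[1], config.group_by_patient
            )
            decomp = fit_windows(windows[train.index.to_numpy()])
            # vectorized project_record over every balanced row
            Xb = windows[balanced.index.to_numpy()] - decomp.mean_profile
            scales = Xb.std(axis=1)
            if np.any(scales <= 0):
                raise RRValidationError("degenerate window (zero variance) in trial")
            coeffs = (Xb / scales[:, None]) @ decomp.components
            pcs = dict(zip(balanced["record_id"], coeffs))
            Xtr, names = _predictor_matrix(train, pcs, decomp.k)
            Xte, _ = _predictor_matrix(test, pcs, decomp.k)
            ytr = (train["label"] == POSITIVE_CLASS).to_numpy()
            yte = (test["label"] == POSITIVE_CLASS).to_numpy()
            for clf_name in config.classifiers:
                model = _TRAINERS[clf_name](Xtr, ytr, seeds[2], config)
                sens, spec = sensitivity_specificity(model.predict(Xte), yte)
                auc = roc_auc(model.score(Xte), yte)
                per_trial.append(
                    {
                        "trial": trial,
                        "classifier": clf_name,
                        "sensitivity": sens,
                        "specificity": spec,
                        "auc": auc,
                    }
                )
                if clf_name == "random_forest" and config.compute_importance:
                    imp = permutation_importance(model, Xtr, ytr, seeds[3])
                    for name, val in zip(names, imp):
                        importance_sums[name] = importance_sums.get(name, 0.0) + float(val)
                        importance_counts[name] = importance_counts.get(name, 0) + 1
            ranks.append(decomp.k)
        except RRValidationError as exc:  # trial-level failure: record and continue
            n_aborted += 1
            errors.append(f"trial {trial}: {exc}")
    if n_aborted > 0.1 * config.n_trials:
        raise RuntimeError(
            f"run_evaluation: {n_aborted}/{config.n_trials} trials aborted; first: {errors[0]}"
        )
    aggregate: dict = {}
    frame = pd.DataFrame(per_trial)
    for clf_name in config.classifiers:
        sel = frame[frame["classifier"] == clf_name]
        aggregate[clf_name] = {
            metric: {
                "mean": float(sel[metric].mean()),
                "sd": float(sel[metric].std(ddof=0)) if len(sel) else 0.0,
            }
            for metric in ("sensitivity", "specificity", "auc")
        }
    importance = {
        name: importance_sums[name] / importance_counts[name] for name in importance_sums
    }
    return EvalResult(
        config=config,
        per_trial=per_trial,
        aggregate=aggregate,
        importance=importance,
        n_aborted=n_aborted,
        retained_ranks=ranks,
    )
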
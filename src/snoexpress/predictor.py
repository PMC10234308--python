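"""Stratified multi-iteration classification of snoRNA expression status.

The protocol shuffles and splits the snoRNA cohort into tuning / training
/ test sets (10% / 80% / 10%) in a stratified way, ten times, such that
the ten test sets partition the cohort: every snoRNA receives exactly one
held-out prediction. Per iteration, each classifier family is grid-search
tuned (stratified 3-fold) on the tuning set, trained on the training set,
and evaluated on the test set; the final call is the majority vote of the
logistic-regression, support-vector-machine, and random-forest models.
k-nearest neighbors and gradient boosting are trained and evaluated as
well but excluded from the ensemble by default (they overfit on this kind
of cohort); config can re-include them.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as scipy_stats
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .feature_assembly import TOP4_FEATURES, FeatureTable, ScalingStats, apply_scaler, fit_scaler

logger = logging.getLogger(__name__)

FAMILIES = (
    "logistic_regression",
    "svm",
    "knn",
    "random_forest",
    "gradient_boosting",
)
ENSEMBLE_FAMILIES = ("logistic_regression", "svm", "random_forest")

#: Modest reproducible default search spaces (user-overridable); the
#: original spaces are not recoverable and no equivalence is claimed.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "logistic_regression": {"C": [0.01, 0.1, 1.0, 10.0, 100.0]},
    "svm": {"kernel": ["linear", "rbf"], "C": [0.1, 1.0, 10.0]},
    "knn": {"n_neighbors": [3, 5, 11]},
    "random_forest": {"n_estimators": [50, 100, 200], "max_depth": [None, 5, 10]},
    "gradient_boosting": {"n_estimators": [50, 100, 200], "max_depth": [2, 3, 4]},
}

POSITIVE = 1  # expressed is the positive class throughout


def _derive_seed(master: int, offset: int) -> int:
    return (int(master) + offset) % (2**31 - 1)


@dataclass(frozen=True)
class SplitSets:
    tuning: tuple[str, ...]
    training: tuple[str, ...]
    test: tuple[str, ...]


@dataclass
class SplitPlan:
    iterations: list[SplitSets]
    seed: int

    def validate(self, ids: Sequence[str]) -> None:
        all_ids = set(ids)
        seen_test: set[str] = set()
        for s in self.iterations:
            t, r, e = set(s.tuning), set(s.training), set(s.test)
            assert t.isdisjoint(r) and t.isdisjoint(e) and r.isdisjoint(e)
            assert t | r | e == all_ids
            assert e.isdisjoint(seen_test)
            seen_test |= e
        assert seen_test == all_ids


def make_split_plan(
    ids: Sequence[str],
    labels: Mapping[str, int] | pd.Series,
    n_iter: int = 10,
    fractions: tuple[float, float, float] = (0.1, 0.8, 0.1),
    seed: int = 0,
) -> SplitPlan:
    """Stratified tuning/training/test splits whose test sets partition
    all ids across iterations (deterministic for a fixed seed)."""
    tune_frac, train_frac, test_frac = fractions
    if abs(n_iter * test_frac - 1.0) > 1e-9:
        raise ValueError("n_iter x test fraction must equal 1 for a test partition")
    ids = sorted(ids)
    y = np.asarray([int(labels[i]) for i in ids])
    counts = np.bincount(y, minlength=2)
    if counts.min() < n_iter:
        raise ValueError(
            f"each class needs >= {n_iter} members for stratified partitioning "
            f"(got {counts.tolist()})"
        )
    id_arr = np.asarray(ids)
    skf = StratifiedKFold(n_splits=n_iter, shuffle=True, random_state=seed)
    iterations = []
    for k, (rest_idx, test_idx) in enumerate(skf.split(id_arr, y)):
        rest_ids, rest_y = id_arr[rest_idx], y[rest_idx]
        tune_ids, train_ids = train_test_split(
            rest_ids,
            train_size=tune_frac / (tune_frac + train_frac),
            stratify=rest_y,
            random_state=_derive_seed(seed, 1000 + k),
        )
        iterations.append(
            SplitSets(tuple(tune_ids), tuple(train_ids), tuple(id_arr[test_idx]))
        )
    plan = SplitPlan(iterations, seed)
    plan.validate(ids)
    return plan


def build_estimator(family: str, params: Mapping[str, object], seed: int = 0):
    params = dict(params)
    if family == "logistic_regression":
        return LogisticRegression(max_iter=5000, random_state=seed, **params)
    if family == "svm":
        import warnings

        with warnings.catch_warnings():
            # Platt-scaled SVC kept for probability scores on the common
            # ensemble scale; the deprecation replacement changes the
            # hyperparameter surface.
            warnings.simplefilter("ignore", FutureWarning)
            return SVC(probability=True, random_state=seed, **params)
    if family == "knn":
        return KNeighborsClassifier(**params)
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, **params)
    if family == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed, **params)
    raise ValueError(f"unknown model family {family!r}")


def _grid_points(grid: Mapping[str, list]) -> list[dict]:
    keys = list(grid)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


def tune(
    family: str,
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    grid: Mapping[str, list] | None = None,
    seed: int = 0,
) -> dict:
    """Exhaustive grid search by mean stratified 3-fold accuracy; ties go
    to the first point in declared grid order."""
    grid = grid if grid is not None else DEFAULT_GRIDS[family]
    y = np.asarray(y)
    if np.bincount(y, minlength=2).min() < 3:
        # one re-seeded refold cannot fix a class with < n_folds members
        raise ValueError("tuning set needs >= 3 members of each class for 3-fold CV")
    cv = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
    best_score, best_params = -np.inf, None
    for params in _grid_points(grid):
        est = build_estimator(family, params, seed)
        score = cross_val_score(est, X, y, cv=cv, scoring="accuracy").mean()
        if score > best_score:
            best_score, best_params = score, params
    return best_params


def train(
    family: str,
    params: Mapping[str, object],
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    seed: int = 0,
):
    """Fit one classifier on (scaled) training rows."""
    if np.abs(np.asarray(X, dtype=float).mean(axis=0)).max() > 5:
        logger.warning("training features look unscaled (|column mean| > 5)")
    model = build_estimator(family, params, seed)
    model.fit(X, np.asarray(y))
    return model


def predict_status(model, X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Predicted statuses and positive-class probability scores."""
    statuses = model.predict(X).astype(int)
    proba = model.predict_proba(X)
    pos_col = list(model.classes_).index(POSITIVE)
    return statuses, proba[:, pos_col]


def ensemble_vote(votes: Sequence[int]) -> int:
    """Majority vote over exactly three binary model calls."""
    if len(votes) != 3:
        raise ValueError(f"ensemble vote requires exactly 3 votes, got {len(votes)}")
    return int(sum(votes) >= 2)


def _confusion_category(predicted: int, truth: int) -> str:
    if predicted == POSITIVE:
        return "TP" if truth == POSITIVE else "FP"
    return "FN" if truth == POSITIVE else "TN"


@dataclass
class ProtocolResult:
    predictions: pd.DataFrame
    models: dict[tuple[str, int], object]
    scalers: dict[int, ScalingStats]
    plan: SplitPlan
    best_params: dict[tuple[str, int], dict]
    families: tuple[str, ...]
    ensemble_families: tuple[str, ...]

    def test_rows(self, family: str, iteration: int) -> tuple[object, pd.Index]:
        model = self.models[(family, iteration)]
        mask = self.predictions["iteration"] == iteration
        return model, self.predictions.index[mask]


def run_protocol(
    table: FeatureTable,
    seed: int = 0,
    n_iter: int = 10,
    families: Sequence[str] = FAMILIES,
    ensemble_families: Sequence[str] = ENSEMBLE_FAMILIES,
    grids: Mapping[str, dict] | None = None,
    feature_subset: Sequence[str] | None = None,
) -> ProtocolResult:
    """Run the full tuning/training/testing protocol on an encoded table.

    `feature_subset` restricts the matrix (e.g. to the top-4 features) for
    the simplified models. Scaling statistics are fit on each iteration's
    training rows only.
    """
    features = list(feature_subset or table.feature_cols)
    X_all = table.X[features]
    y_all = table.y
    plan = make_split_plan(list(X_all.index), y_all, n_iter=n_iter, seed=seed)

    grids = grids or {}
    models: dict[tuple[str, int], object] = {}
    scalers: dict[int, ScalingStats] = {}
    best_params: dict[tuple[str, int], dict] = {}
    rows = []
    for k, split in enumerate(plan.iterations):
        iter_seed = _derive_seed(seed, 7919 * (k + 1))
        stats = fit_scaler(X_all.loc[list(split.training)], training_id=f"iter{k}")
        scalers[k] = stats
        X_tune = apply_scaler(stats, X_all.loc[list(split.tuning)])
        X_train = apply_scaler(stats, X_all.loc[list(split.training)])
        X_test = apply_scaler(stats, X_all.loc[list(split.test)])
        y_tune, y_train = y_all.loc[list(split.tuning)], y_all.loc[list(split.training)]

        per_family: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        tunable = np.bincount(np.asarray(y_tune), minlength=2).min() >= 3
        if not tunable and k == 0:
            logger.warning(
                "tuning set too small for stratified 3-fold grid search; "
                "using the first declared grid point per family"
            )
        for family in families:
            grid = grids.get(family, DEFAULT_GRIDS[family])
            if tunable:
                params = tune(family, X_tune, y_tune, grid, iter_seed)
            else:
                params = _grid_points(grid)[0]
            model = train(family, params, X_train, y_train, iter_seed)
            models[(family, k)] = model
            best_params[(family, k)] = params
            per_family[family] = predict_status(model, X_test)

        for pos, sno_id in enumerate(split.test):
            row: dict[str, object] = {
                "sno_id": sno_id,
                "iteration": k,
                "truth": int(y_all.loc[sno_id]),
            }
            for family in families:
                statuses, scores = per_family[family]
                row[f"{family}_status"] = int(statuses[pos])
                row[f"{family}_score"] = float(scores[pos])
            votes = [row[f"{f}_status"] for f in ensemble_families]
            row["ensemble_status"] = ensemble_vote(votes)
            row["ensemble_score"] = float(
                np.mean([row[f"{f}_score"] for f in ensemble_families])
            )
            row["confusion"] = _confusion_category(row["ensemble_status"], row["truth"])
            rows.append(row)

    predictions = pd.DataFrame(rows).set_index("sno_id").sort_index()
    return ProtocolResult(
        predictions,
        models,
        scalers,
        plan,
        best_params,
        tuple(families),
        tuple(ensemble_families),
    )


def confusion_and_metrics(
    predictions: pd.DataFrame,
    status_col: str = "ensemble_status",
    score_col: str = "ensemble_score",
) -> dict:
    """Accuracy, sensitivity, specificity, ROC points, and AUC.

    The ensemble score is the unweighted mean of the three selected
    models' positive-class probabilities; a single-class truth leaves the
    AUC undefined (None).
    """
    truth = predictions["truth"].to_numpy()
    called = predictions[status_col].to_numpy()
    tp = int(((called == 1) & (truth == 1)).sum())
    tn = int(((called == 0) & (truth == 0)).sum())
    fp = int(((called == 1) & (truth == 0)).sum())
    fn = int(((called == 0) & (truth == 1)).sum())
    n = len(predictions)
    metrics = {
        "n": n,
        "TP": tp,
        "TN": tn,
        "FP": fp,
        "FN": fn,
        "accuracy": (tp + tn) / n if n else float("nan"),
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
    }
    if len(np.unique(truth)) < 2:
        metrics["auc"] = None
        metrics["roc"] = None
    else:
        fpr, tpr, thresholds = roc_curve(truth, predictions[score_col])
        metrics["auc"] = float(sk_auc(fpr, tpr))
        metrics["roc"] = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return metrics


def fit_cross_species_model(
    table: FeatureTable,
    features: Sequence[str] = tuple(TOP4_FEATURES),
    family: str = "logistic_regression",
    seed: int = 42,
    grid: Mapping[str, list] | None = None,
) -> tuple[object, ScalingStats, dict]:
    """Train the reduced-feature transfer model on the full human cohort.

    The tuning and training sets are 10% / 90% stratified splits of all
    snoRNAs; seed 42 is the documented default for the transfer model.
    Returns (model, human training ScalingStats, best params).
    """
    X = table.X[list(features)]
    y = table.y
    tune_ids, train_ids = train_test_split(
        np.asarray(sorted(X.index)),
        train_size=0.1,
        stratify=y.loc[sorted(X.index)],
        random_state=seed,
    )
    stats = fit_scaler(X.loc[list(train_ids)], training_id=f"human-seed{seed}")
    params = tune(family, apply_scaler(stats, X.loc[list(tune_ids)]), y.loc[list(tune_ids)], grid, seed)
    model = train(family, params, apply_scaler(stats, X.loc[list(train_ids)]), y.loc[list(train_ids)], seed)
    return model, stats, params


def cross_species_predict(
    model, human_stats: ScalingStats, species_table: pd.DataFrame
) -> tuple[pd.DataFrame, float]:
    """Predict a species cohort with a human-trained reduced model.

    Species rows are scaled with the HUMAN training statistics. Returns
    per-snoRNA calls and the proportion predicted expressed.
    """
    expected = list(human_stats.mean.index)
    if list(species_table.columns) != expected:
        raise ValueError(
            f"species table columns {list(species_table.columns)} != expected {expected}"
        )
    X = apply_scaler(human_stats, species_table)
    statuses, scores = predict_status(model, X)
    out = pd.DataFrame(
        {"status": statuses, "score": scores}, index=species_table.index
    )
    return out, float(statuses.mean())


def expressed_proportion_count_correlation(
    proportions: Sequence[float], counts: Sequence[int]
) -> tuple[float, float]:
    """Pearson correlation between per-species predicted expressed
    proportion and total annotated snoRNA count."""
    r, p = scipy_stats.pearsonr(np.asarray(proportions, float), np.asarray(counts, float))
    return float(r), float(p)
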
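"""Cross-validated training and evaluation for both detection tasks.

General models hold entire persons out (leave-3-people-out over triples of
persons) to test generalization to unseen individuals; personalized models
run a stratified 5-fold within each person.  Each fold fits everything —
column dropping, standardization, feature selection, oversampling, the
classifier and its hyperparameter search — on training rows only.
"""

from __future__ import annotations

import hashlib
import logging
import pickle
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import f_classif
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from xgboost import XGBClassifier

from .oversample import oversample as _oversample
from .labeling import LabeledDataset, delta_features, prune_rare_classes
from .metrics import METRIC_NAMES, compute_metrics
from .preprocess import CATEGORIES, impute_and_standardize

logger = logging.getLogger(__name__)

__all__ = [
    "CVPlan",
    "EvalResult",
    "FoldResult",
    "make_cv_plan",
    "select_features",
    "train_eval",
    "importance_tally",
    "MODEL_FAMILIES",
]

K_GRID = (50, 70, 90, 110)
MISSING_DROP_FRACTION = 0.30
RARE_CLASS_THRESHOLD = 6


# ----------------------------------------------------------------------
# Cross-validation plans
# ----------------------------------------------------------------------

@dataclass
class CVPlan:
    """Fold assignments for one evaluation mode.

    general
        ``person_folds`` partitions persons into groups of 3; each group is
        one test fold and the rest train.
    personalized
        ``row_folds[person]`` is a list of (train_idx, test_idx) pairs of
        positional indices into that person's rows, stratified by class.
    """

    mode: str
    seed: int
    person_folds: list[list[str]] = field(default_factory=list)
    row_folds: dict[str, list[tuple[np.ndarray, np.ndarray]]] = field(default_factory=dict)


def make_cv_plan(
    persons,
    mode: str,
    seed: int = 0,
    y: pd.Series | None = None,
    group_size: int = 3,
    n_splits: int = 5,
) -> CVPlan:
    """Build a deterministic cross-validation plan.

    For general mode ``persons`` is the set of person ids, whose count must
    be divisible by ``group_size`` (18 persons -> six folds of 3).  For
    personalized mode ``persons`` is the per-row person id sequence over the
    FULL row table and ``y`` the aligned per-row class sequence (NaN rows
    are unlabeled and excluded); each person gets a stratified
    ``n_splits``-fold assignment of full-table row positions.
    """
    if mode == "general":
        unique = sorted(set(persons))
        if len(unique) % group_size:
            lower = (len(unique) // group_size) * group_size
            raise ValueError(
                f"{len(unique)} persons cannot be split into groups of "
                f"{group_size}; nearest valid counts are {lower} and "
                f"{lower + group_size}"
            )
        rng = np.random.default_rng(seed)
        order = rng.permutation(unique)
        folds = [sorted(order[i:i + group_size]) for i in range(0, len(order), group_size)]
        return CVPlan(mode="general", seed=seed, person_folds=folds)

    if mode != "personalized":
        raise ValueError(f"unknown mode {mode!r}")
    if y is None:
        raise ValueError("personalized mode requires per-row labels y")
    persons = pd.Index(persons, name="person")
    y = pd.Series(np.asarray(y, dtype=object))
    labeled = y.notna().to_numpy()
    plan = CVPlan(mode="personalized", seed=seed)
    for person in sorted(set(persons)):
        rows = np.flatnonzero((persons == person) & labeled)
        yy = y.to_numpy()[rows]
        if len(np.unique(yy)) < 2:
            raise ValueError(f"person {person!r} has fewer than 2 classes")
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        strat = np.asarray([str(v) for v in yy])  # dtype-agnostic stratification
        plan.row_folds[person] = [
            (rows[tr], rows[te]) for tr, te in skf.split(np.zeros(len(rows)), strat)
        ]
    return plan


# ----------------------------------------------------------------------
# Feature selection
# ----------------------------------------------------------------------

def select_features(
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    k: int,
) -> list[str]:
    """Pick the k columns with the strongest univariate class association.

    Columns are scored by the ANOVA F statistic between class means and
    ranked descending; ties (and NaN scores from degenerate columns) break
    deterministically by column position.  ``k`` larger than the number of
    columns is clamped with a log message.
    """
    if k > X_train.shape[1]:
        logger.info("k=%d clamped to %d available columns", k, X_train.shape[1])
        k = X_train.shape[1]
    scores, _ = f_classif(X_train.to_numpy(), y_train)
    scores = np.nan_to_num(scores, nan=-np.inf)
    order = np.argsort(-scores, kind="stable")  # stable: ties keep column order
    return [X_train.columns[i] for i in sorted(order[:k])]


# ----------------------------------------------------------------------
# Model families
# ----------------------------------------------------------------------

def _make_lr(seed):
    return LogisticRegression(max_iter=2000, random_state=seed)


def _make_rf(seed):
    return RandomForestClassifier(n_estimators=200, random_state=seed, n_jobs=1)


def _make_gbt(seed):
    return XGBClassifier(
        n_estimators=150, learning_rate=0.1, max_depth=3,
        random_state=seed, n_jobs=1, eval_metric="logloss", verbosity=0,
    )


def _make_mlp(seed):
    return MLPClassifier(hidden_layer_sizes=(64,), max_iter=400, random_state=seed)


#: name -> (estimator factory, hyperparameter grid for the inner search)
MODEL_FAMILIES = {
    "lr": (_make_lr, {"C": [0.1, 1.0, 10.0]}),
    "rf": (_make_rf, {"max_depth": [None, 10]}),
    "gbt": (_make_gbt, {"max_depth": [3, 6]}),
    "mlp": (_make_mlp, {"alpha": [1e-4, 1e-2]}),
}


# ----------------------------------------------------------------------
# Fold fitting
# ----------------------------------------------------------------------

@dataclass
class FoldResult:
    """Everything one outer fold produced.

    ``artifacts`` digests every training-side object (dropped and selected
    columns, scaler parameters, oversampled arrays, fitted model state) so
    leakage checks can assert byte-identity when test labels change.
    """

    metrics: dict[str, float]
    selected: list[str]
    categories: dict[str, str]
    model: object
    classes: list
    artifacts: dict[str, bytes]
    person: str | None = None


def _digest(obj) -> bytes:
    return hashlib.sha256(pickle.dumps(obj)).digest()


def _label_encode(y, classes):
    lut = {c: i for i, c in enumerate(classes)}
    return np.array([lut[v] for v in y])


def _fit_fold(
    data: LabeledDataset,
    task: str,
    train_idx: np.ndarray,
    model: str,
    k: int,
    oversample_method: str,
    tune: bool,
    seed: int,
    general: bool,
    sentinel_before_scaling: bool,
):
    """Fit all training-side steps of one fold; returns the fitted state.

    Nothing here sees test rows or test labels.
    """
    w = data.windowed
    y_all = data.y_state if task == "state" else data.y_transition
    labeled = y_all.notna().to_numpy()
    labeled_pos = np.flatnonzero(labeled)

    # 1. drop columns with too much missingness, measured on training rows
    miss_frac = w.mask.iloc[train_idx].mean(axis=0)
    keep = [c for c in w.X.columns if miss_frac[c] <= MISSING_DROP_FRACTION]
    dropped_missing = [c for c in w.X.columns if c not in keep]
    # 2. general models drop location columns entirely
    if general:
        keep = [c for c in keep if w.categories[c] != "location"]

    # 3. standardize on training rows, sentinel-fill the rest
    std = impute_and_standardize(
        w, train_idx, sentinel_before_scaling=sentinel_before_scaling
    )
    feats = std.X[keep]

    # 4. transition task runs on within-person first differences of the
    #    labeled-row sequence (the change since the reference window)
    if task == "transition":
        lab_feats = feats.iloc[labeled_pos]
        deltas = delta_features(lab_feats)
        feats = deltas
        usable = deltas.index
    else:
        feats = feats.iloc[labeled_pos]
        usable = feats.index

    y_rows = y_all.loc[usable]
    ok = y_rows.notna().to_numpy()
    feats = feats[ok]
    y_rows = y_rows[ok]

    # recover positional alignment of task rows through the index
    full_index = w.X.index
    row_lookup = pd.Series(np.arange(len(full_index)), index=full_index)
    task_rows = row_lookup.loc[feats.index].to_numpy()
    in_train = np.isin(task_rows, train_idx)

    X_tr = feats[in_train]
    y_tr = y_rows[in_train].to_numpy()
    if task == "transition":
        y_tr = y_tr.astype(int)

    # 5. univariate selection on training rows only
    selected = select_features(X_tr, y_tr, k)
    X_tr_sel = X_tr[selected].to_numpy()

    # 6. training-only oversampling
    X_bal, y_bal = _oversample(
        X_tr_sel, y_tr, method=oversample_method, random_state=seed
    )

    classes = sorted(np.unique(y_bal).tolist())
    y_enc = _label_encode(y_bal, classes)

    factory, grid = MODEL_FAMILIES[model]
    est = factory(seed)
    if tune and len(np.unique(y_enc)) > 1:
        inner = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
        search = GridSearchCV(est, grid, scoring="f1_macro", cv=inner, n_jobs=1)
        search.fit(X_bal, y_enc)
        fitted = search.best_estimator_
        best_params = search.best_params_
    else:
        est.fit(X_bal, y_enc)
        fitted = est
        best_params = est.get_params()

    artifacts = {
        "dropped_missing": _digest(dropped_missing),
        "kept_columns": _digest(keep),
        "scaler": _digest((std.scaler_mean.to_numpy().tobytes(),
                           std.scaler_scale.to_numpy().tobytes())),
        "selected": _digest(selected),
        "oversampled": _digest((X_bal.tobytes(), list(y_bal))),
        "model_params": _digest(best_params),
        "model_state": _digest(_model_state(fitted)),
    }
    state = {
        "feats": feats,
        "task_rows": task_rows,
        "y_rows": y_rows,
        "selected": selected,
        "classes": classes,
        "model": fitted,
        "artifacts": artifacts,
        "categories": {c: w.categories[c] for c in selected},
    }
    return state


def _model_state(model) -> bytes:
    if isinstance(model, XGBClassifier):
        return model.get_booster().save_raw("json")
    return pickle.dumps(model)


def _eval_fold(state, test_idx: np.ndarray, task: str) -> dict[str, float] | None:
    feats = state["feats"]
    task_rows = state["task_rows"]
    y_rows = state["y_rows"]
    in_test = np.isin(task_rows, test_idx)
    if not in_test.any():
        return None
    X_te = feats[in_test][state["selected"]].to_numpy()
    y_te = y_rows[in_test].to_numpy()
    if task == "transition":
        y_te = y_te.astype(int)
    model = state["model"]
    classes = state["classes"]
    proba = model.predict_proba(X_te)
    y_pred = np.array(classes)[np.argmax(proba, axis=1)]
    if task == "transition":
        y_pred = y_pred.astype(int)
    return compute_metrics(y_te, y_pred, proba, classes)


# ----------------------------------------------------------------------
# Top-level harness
# ----------------------------------------------------------------------

@dataclass
class EvalResult:
    """Mean (SD) of the seven metrics plus the per-fold/per-person detail."""

    task: str
    mode: str
    model: str
    summary: pd.DataFrame          # index metric, columns mean/sd
    per_fold: pd.DataFrame         # one row per outer fold (or person-fold)
    folds: list[FoldResult]

    def tally(self) -> pd.DataFrame:
        return importance_tally(self.folds)


def train_eval(
    data: LabeledDataset,
    task: str,
    plan: CVPlan,
    model: str = "rf",
    k: int = 50,
    oversample_method: str = "none",
    tune: bool = True,
    seed: int = 0,
    sentinel_before_scaling: bool = False,
    prune_threshold: int = RARE_CLASS_THRESHOLD,
) -> EvalResult:
    """Run the full cross-validated evaluation for one configuration.

    ``task`` is "state" (six-class) or "transition" (binary).  In
    personalized state mode, per-person classes with at most
    ``prune_threshold`` samples are removed before folding.  Metrics are
    reported as mean (SD) across folds (general) or across persons
    (personalized, averaging each person's folds first).
    """
    if task not in {"state", "transition"}:
        raise ValueError(f"unknown task {task!r}")
    data, excluded_persons = _maybe_prune(data, task, plan.mode, prune_threshold)
    fold_results: list[FoldResult] = []
    rows = []

    if plan.mode == "general":
        person_index = data.person
        for fold_no, test_persons in enumerate(plan.person_folds):
            te = np.flatnonzero(person_index.isin(test_persons))
            tr = np.flatnonzero(~person_index.isin(test_persons))
            state = _fit_fold(data, task, tr, model, k, oversample_method,
                              tune, seed, general=True,
                              sentinel_before_scaling=sentinel_before_scaling)
            m = _eval_fold(state, te, task)
            if m is None:
                logger.warning("fold %d has no labeled test rows; skipped", fold_no)
                continue
            fold_results.append(FoldResult(
                metrics=m, selected=state["selected"],
                categories=state["categories"], model=state["model"],
                classes=state["classes"], artifacts=state["artifacts"],
            ))
            rows.append({"fold": fold_no, **m})
        per_fold = pd.DataFrame(rows)
        agg = per_fold[list(METRIC_NAMES)]
    else:
        for person, folds in plan.row_folds.items():
            if person in excluded_persons:
                logger.warning("person %s skipped (excluded by pruning)", person)
                continue
            person_rows = []
            for fold_no, (tr, te) in enumerate(folds):
                state = _fit_fold(data, task, tr, model, k, oversample_method,
                                  tune, seed, general=False,
                                  sentinel_before_scaling=sentinel_before_scaling)
                m = _eval_fold(state, te, task)
                if m is None:
                    continue
                fold_results.append(FoldResult(
                    metrics=m, selected=state["selected"],
                    categories=state["categories"], model=state["model"],
                    classes=state["classes"], artifacts=state["artifacts"],
                    person=person,
                ))
                person_rows.append({"person": person, "fold": fold_no, **m})
            rows.extend(person_rows)
        per_fold = pd.DataFrame(rows)
        # average folds within person, then summarize across persons
        agg = per_fold.groupby("person")[list(METRIC_NAMES)].mean()

    summary = pd.DataFrame({
        "mean": agg.mean(axis=0),
        "sd": agg.std(axis=0, ddof=1) if len(agg) > 1 else 0.0,
    })
    return EvalResult(task=task, mode=plan.mode, model=model,
                      summary=summary, per_fold=per_fold, folds=fold_results)


def _maybe_prune(
    data: LabeledDataset, task: str, mode: str, threshold: int,
) -> tuple[LabeledDataset, list[str]]:
    """NaN out rare per-person classes; row positions never shift, so
    externally built CV plans stay aligned."""
    if task != "state" or mode != "personalized" or threshold is None:
        return data, []
    y_pruned, excluded = prune_rare_classes(data.y_state, threshold=threshold)
    return LabeledDataset(data.windowed, y_pruned, data.y_transition), excluded


# ----------------------------------------------------------------------
# Feature-importance category tally
# ----------------------------------------------------------------------

def importance_tally(
    folds: list[FoldResult],
    X_val: pd.DataFrame | None = None,
    y_val: np.ndarray | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Count which feature categories occupy the top-3 importance ranks.

    For every fitted fold (and person, in personalized mode) the three
    most important selected features are found and the 7x3 counter matrix
    (category x rank) is incremented at their categories.  The attribution
    is whatever total ordering the model exposes: tree-gain style
    ``feature_importances_``, the mean absolute coefficient for linear
    models, or permutation importance as a fallback (requires ``X_val``,
    ``y_val``).  Ties break toward the lower column index.
    """
    tally = pd.DataFrame(0, index=list(CATEGORIES), columns=[1, 2, 3])
    for fold in folds:
        scores = _attribution(fold.model, len(fold.selected), X_val, y_val, seed)
        order = np.argsort(-scores, kind="stable")  # stable: ties -> lower index
        for rank, col in enumerate(order[:3], start=1):
            cat = fold.categories[fold.selected[col]]
            tally.loc[cat, rank] += 1
    return tally


def _attribution(model, n_features: int, X_val, y_val, seed) -> np.ndarray:
    if hasattr(model, "feature_importances_"):
        return np.asarray(model.feature_importances_, dtype=float)
    if hasattr(model, "coef_"):
        coef = np.atleast_2d(model.coef_)
        return np.abs(coef).mean(axis=0)
    if X_val is None or y_val is None:
        raise ValueError(
            "model exposes no importances or coefficients; pass X_val/y_val "
            "for permutation importance"
        )
    res = permutation_importance(model, X_val, y_val, n_repeats=5, random_state=seed)
    return res.importances_mean
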
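"""CV plans, feature selection, metrics oracle, tally, leakage guards."""

import numpy as np
import pandas as pd
import pytest

import emostate as es
from emostate.metrics import METRIC_NAMES, compute_metrics
from emostate.modeling import (
    FoldResult,
    importance_tally,
    make_cv_plan,
    select_features,
    train_eval,
)
from emostate.preprocess import WindowedDataset
from emostate.labeling import LabeledDataset
from emostate.synth import GeneratorConfig, PersonProfile, generate


# ----------------------------------------------------------------------
# CV plans
# ----------------------------------------------------------------------

def test_general_plan_partitions_18_persons_into_6_triples():
    persons = [f"P{i:02d}" for i in range(1, 19)]
    plan = make_cv_plan(persons, "general", seed=4)
    assert len(plan.person_folds) == 6
    assert all(len(f) == 3 for f in plan.person_folds)
    assert sorted(p for f in plan.person_folds for p in f) == persons
    plan2 = make_cv_plan(persons, "general", seed=4)
    assert plan.person_folds == plan2.person_folds  # deterministic


def test_general_plan_rejects_indivisible_person_count():
    with pytest.raises(ValueError, match="15 and 18"):
        make_cv_plan([f"P{i}" for i in range(17)], "general")


def test_personalized_plan_stratifies_balanced_classes():
    persons = ["A"] * 100
    y = pd.Series(["x"] * 50 + ["y"] * 50)
    plan = make_cv_plan(persons, "personalized", seed=0, y=y)
    for tr, te in plan.row_folds["A"]:
        assert len(te) == 20
        assert (y.iloc[te] == "x").sum() == 10
    with pytest.raises(ValueError, match="fewer than 2 classes"):
        make_cv_plan(["A"] * 10, "personalized", seed=0, y=pd.Series(["x"] * 10))


# ----------------------------------------------------------------------
# feature selection
# ----------------------------------------------------------------------

def test_perfectly_associated_column_selected_first():
    rng = np.random.default_rng(0)
    y = rng.integers(0, 2, 200)
    X = pd.DataFrame(rng.normal(size=(200, 10)),
                     columns=[f"n{i}" for i in range(10)])
    X["signal"] = y.astype(float)
    assert select_features(X, y, k=1) == ["signal"]


def test_selection_is_deterministic_and_clamps(caplog):
    rng = np.random.default_rng(1)
    y = rng.integers(0, 2, 50)
    X = pd.DataFrame(np.tile(rng.normal(size=(50, 1)), 4),
                     columns=list("abcd"))  # identical columns: pure tie
    assert select_features(X, y, k=2) == ["a", "b"]  # ties keep column order
    with caplog.at_level("INFO", logger="emostate.modeling"):
        got = select_features(X, y, k=99)
    assert got == list("abcd")
    assert "clamped" in caplog.text


# ----------------------------------------------------------------------
# metrics against a brute-force confusion-matrix oracle
# ----------------------------------------------------------------------

def _oracle_metrics(y_true, y_pred, scores, labels):
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    acc = np.mean(y_true == y_pred)
    prec, rec, spec, f1s, aucs, recalls_present = [], [], [], [], [], []
    for j, c in enumerate(labels):
        tp = np.sum((y_true == c) & (y_pred == c))
        fp = np.sum((y_true != c) & (y_pred == c))
        fn = np.sum((y_true == c) & (y_pred != c))
        tn = np.sum((y_true != c) & (y_pred != c))
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        prec.append(p)
        rec.append(r)
        f1s.append(2 * p * r / (p + r) if p + r else 0.0)
        if tn + fp:
            spec.append(tn / (tn + fp))
        if (y_true == c).any():
            recalls_present.append(r)
        # AUC by explicit pair counting (Mann-Whitney)
        pos = scores[y_true == c, j]
        neg = scores[y_true != c, j]
        if len(pos) and len(neg):
            wins = sum((pos[:, None] > neg[None, :]).sum() for _ in [0])
            ties = (pos[:, None] == neg[None, :]).sum()
            aucs.append((wins + 0.5 * ties) / (len(pos) * len(neg)))
    return {
        "accuracy": acc,
        "balanced_accuracy": np.mean(recalls_present),
        "precision_macro": np.mean(prec),
        "recall_macro": np.mean(rec),
        "specificity_macro": np.mean(spec),
        "auroc_macro": np.mean(aucs),
        "f1_macro": np.mean(f1s),
    }


def test_all_seven_metrics_match_bruteforce_oracle():
    rng = np.random.default_rng(8)
    labels = list(range(6))
    for _ in range(5):
        n = 1000
        y_true = rng.integers(0, 6, n)
        y_pred = rng.integers(0, 6, n)
        scores = rng.random((n, 6))
        scores /= scores.sum(axis=1, keepdims=True)
        got = compute_metrics(y_true, y_pred, scores, labels)
        want = _oracle_metrics(y_true, y_pred, scores, labels)
        for m in METRIC_NAMES:
            assert got[m] == pytest.approx(want[m], abs=1e-10), m


def test_perfect_predictions_score_one():
    y = np.array([0, 1, 0, 1, 1, 0])
    scores = np.column_stack([1.0 - y, y.astype(float)])
    m = compute_metrics(y, y, scores, [0, 1])
    assert m["accuracy"] == m["balanced_accuracy"] == m["f1_macro"] == 1.0
    assert m["auroc_macro"] == 1.0


# ----------------------------------------------------------------------
# importance tally
# ----------------------------------------------------------------------

class _StubModel:
    def __init__(self, importances):
        self.feature_importances_ = np.asarray(importances, dtype=float)


def _stub_fold(importances, features, categories):
    return FoldResult(
        metrics={}, selected=list(features),
        categories=dict(zip(features, categories)),
        model=_StubModel(importances), classes=[0, 1], artifacts={},
    )


def test_tally_worked_example():
    """Top-3 = contextual, phone_state, contextual increments the matching
    (category, rank) counters."""
    fold = _stub_fold(
        importances=[0.5, 0.3, 0.2, 0.1],
        features=["label_sitting", "battery_level", "label_source", "acc_mean"],
        categories=["contextual", "phone_state", "contextual", "motion"],
    )
    t = importance_tally([fold])
    assert t.loc["contextual", 1] == 1
    assert t.loc["phone_state", 2] == 1
    assert t.loc["contextual", 3] == 1
    assert t.to_numpy().sum() == 3


def test_tally_zero_folds_is_zero_matrix():
    t = importance_tally([])
    assert t.shape == (7, 3)
    assert (t.to_numpy() == 0).all()


def test_tally_tie_breaks_toward_lower_column_index():
    fold = _stub_fold([0.4, 0.4, 0.4, 0.4],
                      ["a", "b", "c", "d"],
                      ["motion", "audio", "temporal", "contextual"])
    t = importance_tally([fold])
    assert t.loc["motion", 1] == 1 and t.loc["audio", 2] == 1 and t.loc["temporal", 3] == 1


def test_tally_column_sums_equal_fold_count():
    folds = [_stub_fold(np.arange(4)[::-1], list("abcd"),
                        ["motion", "audio", "temporal", "contextual"])
             for _ in range(5)]
    t = importance_tally(folds)
    assert (t.sum(axis=0) == 5).all()


# ----------------------------------------------------------------------
# planted-signal recovery
# ----------------------------------------------------------------------

def _handmade_dataset(seed=0, n=400):
    """Noise in every category except one contextual column driving y."""
    rng = np.random.default_rng(seed)
    idx = pd.MultiIndex.from_product(
        [["A"], pd.date_range("2016-03-07", periods=n, freq="5min")],
        names=["person", "window_start"],
    )
    cats = {}
    cols = {}
    for cat, names in {
        "motion": ["m0", "m1"], "audio": ["a0"], "location": ["l0"],
        "phone_state": ["p0"], "environmental": ["e0"],
        "temporal": ["t0"], "contextual": ["ctx_signal", "ctx_noise"],
    }.items():
        for c in names:
            cols[c] = rng.normal(size=n)
            cats[c] = cat
    y_bits = rng.integers(0, 2, n)
    cols["ctx_signal"] = y_bits + rng.normal(0, 0.05, n)
    X = pd.DataFrame(cols, index=idx)
    mask = pd.DataFrame(False, index=idx, columns=X.columns)
    w = WindowedDataset(X, mask, cats, {c: "continuous" for c in X.columns},
                        pd.Series(1, index=idx))
    y_state = pd.Series(np.where(y_bits, "pleased", "dissuaded"), index=idx)
    from emostate.labeling import transition_targets
    return LabeledDataset(w, y_state, transition_targets(y_state))


def test_contextual_signal_dominates_rank_one_tally():
    data = _handmade_dataset()
    y = data.y_state
    plan = make_cv_plan(data.person, "personalized", seed=0, y=y)
    res = train_eval(data, "state", plan, model="gbt", k=5, tune=False, seed=0)
    assert res.summary.loc["auroc_macro", "mean"] > 0.95
    t = res.tally()
    assert t.loc["contextual", 1] == t[1].sum()  # plurality (here: all) of rank 1


# ----------------------------------------------------------------------
# leakage guard
# ----------------------------------------------------------------------

@pytest.fixture(scope="module")
def trio_dataset(rating_table=None):
    from emostate.mapping import load_example_ratings
    profiles = [PersonProfile(p, n_days=2, rho=1.0, missing_rate=0.2,
                              report_gap_minutes=(10, 20))
                for p in ["A", "B", "C", "D", "E", "F"]]
    cfg = GeneratorConfig(profiles=profiles, seed=17)
    table = generate(cfg)
    w = es.resample_5min(table)
    w = es.temporal_features(w)
    w = es.location_features(w)
    return es.build_labeled_dataset(w, table.events, cfg.rating_table)


def _permute_test_rows(data, test_persons, seed=0):
    rng = np.random.default_rng(seed)
    y = data.y_state.copy()
    X = data.windowed.X.astype(float)
    in_test = y.index.get_level_values("person").isin(test_persons)
    lab = in_test & y.notna()
    vals = y[lab].to_numpy()
    y.loc[lab] = rng.permutation(vals)
    # scramble test-row features as well: training artifacts must not care
    X.loc[in_test, :] = X.loc[in_test, :].to_numpy() * 3.7 + 11.0
    w2 = data.windowed.copy()
    w2.X = X
    from emostate.labeling import transition_targets
    return LabeledDataset(w2, y, transition_targets(y))


def test_training_artifacts_ignore_test_rows(trio_dataset):
    """Permuting test-fold labels and rescaling test-fold features leaves
    every training-side artifact byte-identical."""
    plan = make_cv_plan(sorted(set(trio_dataset.person)), "general", seed=0)
    res_a = train_eval(trio_dataset, "state", plan, model="rf", k=20,
                       oversample_method="smote", tune=False, seed=0)
    mutated = _permute_test_rows(trio_dataset, plan.person_folds[0])
    res_b = train_eval(mutated, "state", plan, model="rf", k=20,
                       oversample_method="smote", tune=False, seed=0)
    art_a = res_a.folds[0].artifacts
    art_b = res_b.folds[0].artifacts
    assert set(art_a) == set(art_b)
    for key in art_a:
        assert art_a[key] == art_b[key], key


def test_general_mode_excludes_location_columns(trio_dataset):
    plan = make_cv_plan(sorted(set(trio_dataset.person)), "general", seed=0)
    res = train_eval(trio_dataset, "state", plan, model="rf", k=200,
                     tune=False, seed=0)
    for fold in res.folds:
        assert all(fold.categories[c] != "location" for c in fold.selected)


def test_personalized_mode_keeps_location_columns(trio_dataset):
    y = trio_dataset.y_state
    plan = make_cv_plan(trio_dataset.person, "personalized", seed=0, y=y)
    res = train_eval(trio_dataset, "state", plan, model="rf", k=200,
                     tune=False, seed=0)
    cats = {fold.categories[c] for fold in res.folds for c in fold.selected}
    assert "location" in cats


def test_grid_search_runs_and_reports(trio_dataset):
    y = trio_dataset.y_state
    plan = make_cv_plan(trio_dataset.person, "personalized", seed=0, y=y)
    plan.row_folds = {"A": plan.row_folds["A"][:2]}  # 2 folds for speed
    res = train_eval(trio_dataset, "state", plan, model="lr", k=20,
                     tune=True, seed=0)
    assert set(res.summary.index) == set(METRIC_NAMES)
    assert ((res.summary["mean"] >= 0) & (res.summary["mean"] <= 1)).all()
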
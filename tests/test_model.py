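"""Boosted classifier: training, prediction, metrics, SHAP, elimination."""

import numpy as np
import pandas as pd
import pytest

from pocketdrug.descriptors import DESCRIPTOR_NAMES
from pocketdrug.fixtures import make_labeled_table
from pocketdrug.model import (
    DRUGGABLE,
    LESS_DRUGGABLE,
    ConfusionCounts,
    LabeledTable,
    confusion_counts,
    eliminate_descriptors,
    evaluate,
    loo_cv,
    predict,
    predict_table,
    shap_rank,
    train_model,
)


def _separable_table(n=200, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    rows = pd.DataFrame({
        "psa_r": np.where(y == 1, 0.1, 0.9) + rng.normal(0, 0.01, n),
        "hsa": np.where(y == 1, 500.0, 100.0) + rng.normal(0, 5, n),
    }, index=[f"p{i}" for i in range(n)])
    rows["psa_r"] = rows["psa_r"].clip(0, 1)
    labels = pd.Series(np.where(y == 1, DRUGGABLE, LESS_DRUGGABLE),
                       index=rows.index)
    return LabeledTable(rows, labels)


def test_separable_table_reaches_perfect_training_accuracy():
    table = _separable_table(seed=1)
    valid = _separable_table(seed=2)
    model = train_model(table, valid, seed=3)
    counts = confusion_counts(model, table)
    assert evaluate(counts)["accuracy"] == 1.0


def test_label_permutation_gives_chance_accuracy():
    """With permuted labels the validation accuracy hovers around 0.5."""
    accs = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        table = make_labeled_table(n=120, effect=1.0, seed=seed)
        permuted = LabeledTable(
            table.rows,
            pd.Series(rng.permutation(table.labels.to_numpy()),
                      index=table.rows.index))
        valid = make_labeled_table(n=120, effect=0.0, seed=seed + 100)
        model = train_model(permuted, valid, seed=seed)
        accs.append(evaluate(confusion_counts(model, valid))["accuracy"])
    assert abs(np.mean(accs) - 0.5) < 0.1


def test_training_deterministic():
    table = make_labeled_table(n=100, seed=5)
    valid = make_labeled_table(n=60, seed=6)
    m1 = train_model(table, valid, seed=9)
    m2 = train_model(table, valid, seed=9)
    np.testing.assert_array_equal(m1.score(valid.rows), m2.score(valid.rows))


def test_single_class_table_rejected():
    table = make_labeled_table(n=40, seed=1)
    one_class = LabeledTable(table.rows,
                             pd.Series(DRUGGABLE, index=table.rows.index))
    with pytest.raises(ValueError):
        train_model(one_class, table, seed=0)


class _StubModel:
    """Minimal stand-in exposing the scoring interface, to pin down the
    decision-threshold behaviour exactly."""

    def __init__(self, scores):
        self._scores = np.asarray(scores, float)
        self.descriptor_subset = ["psa_r"]

    def score(self, rows):
        return self._scores[: len(rows)]


@pytest.mark.parametrize("score,expected", [
    (0.5, DRUGGABLE),       # boundary inclusive
    (0.49, LESS_DRUGGABLE),
    (0.51, DRUGGABLE),
    (0.0, LESS_DRUGGABLE),
    (1.0, DRUGGABLE),
])
def test_score_threshold_boundary(score, expected):
    rows = pd.DataFrame({"psa_r": [0.5]}, index=["x"])
    out = predict_table(_StubModel([score]), rows)
    assert out.loc["x", "label"] == expected


def test_predict_missing_descriptor_named():
    table = make_labeled_table(n=40, seed=2)
    valid = make_labeled_table(n=40, seed=3)
    model = train_model(table, valid, seed=1)
    with pytest.raises(ValueError, match="psa_r"):
        predict(model, {d: 0.5 for d in DESCRIPTOR_NAMES if d != "psa_r"})


def test_scores_in_unit_interval():
    table = make_labeled_table(n=100, seed=7)
    valid = make_labeled_table(n=50, seed=8)
    model = train_model(table, valid, seed=2)
    scores = model.score(valid.rows)
    assert np.all((scores >= 0) & (scores <= 1))


# --- evaluate ----------------------------------------------------------------

def test_evaluate_perfect():
    m = evaluate(ConfusionCounts(tp=10, tn=10, fp=0, fn=0))
    assert m["accuracy"] == 1.0
    assert m["precision"][DRUGGABLE] == 1.0
    assert m["recall"][LESS_DRUGGABLE] == 1.0


def test_evaluate_worked_example():
    """tp=19, fp=1, tn=13, fn=2: accuracy 32/35, druggable precision 19/20,
    druggable recall 19/21."""
    m = evaluate(ConfusionCounts(tp=19, fp=1, tn=13, fn=2))
    assert m["accuracy"] == pytest.approx(32 / 35)
    assert m["precision"][DRUGGABLE] == pytest.approx(19 / 20)
    assert m["recall"][DRUGGABLE] == pytest.approx(19 / 21)
    assert m["precision"][LESS_DRUGGABLE] == pytest.approx(13 / 15)
    assert m["recall"][LESS_DRUGGABLE] == pytest.approx(13 / 14)


def test_evaluate_all_wrong():
    m = evaluate(ConfusionCounts(tp=0, tn=0, fp=5, fn=5))
    assert m["accuracy"] == 0.0


def test_evaluate_undefined_is_none():
    m = evaluate(ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
    assert m["precision"][DRUGGABLE] is None


def test_evaluate_matches_bruteforce_on_random_matrices():
    rng = np.random.default_rng(11)
    for _ in range(300):
        tp, tn, fp, fn = (int(x) for x in rng.integers(0, 30, 4))
        if tp + tn + fp + fn == 0:
            continue
        m = evaluate(ConfusionCounts(tp, tn, fp, fn))
        # brute force from raw label pairs
        truth = [1] * (tp + fn) + [0] * (tn + fp)
        pred = [1] * tp + [0] * fn + [0] * tn + [1] * fp
        correct = sum(t == p for t, p in zip(truth, pred))
        assert m["accuracy"] == pytest.approx(correct / len(truth))


# --- SHAP --------------------------------------------------------------------

def test_shap_additivity():
    """Per-row SHAP contributions plus the base value reproduce the model's
    margin output."""
    table = make_labeled_table(n=100, seed=4)
    valid = make_labeled_table(n=60, seed=5)
    model = train_model(table, valid, seed=1)
    contribs, base = model.shap_values(valid.rows)
    margins = model.booster.predict(model.dmatrix(valid.rows),
                                    output_margin=True,
                                    iteration_range=(0, model.best_iteration + 1))
    np.testing.assert_allclose(contribs.sum(axis=1) + base, margins, atol=1e-4)


def test_shap_rank_finds_generative_descriptors():
    table = make_labeled_table(n=200, effect=2.0, noise_sd=0.05, seed=6)
    valid = make_labeled_table(n=100, effect=2.0, noise_sd=0.05, seed=7)
    model = train_model(table, valid, seed=1)
    ranking = shap_rank(model, table)
    top3 = {name for name, _ in ranking[:3]}
    assert {"psa_r", "fr_buried_sl_atoms"} <= top3


def test_shap_single_descriptor_model():
    table = make_labeled_table(n=100, seed=8).subset(["psa_r"])
    valid = make_labeled_table(n=60, seed=9).subset(["psa_r"])
    model = train_model(table, valid, seed=1)
    ranking = shap_rank(model, table)
    assert ranking[0][0] == "psa_r"


# --- elimination and cross-validation ----------------------------------------

def test_elimination_removes_noise_before_signal():
    hits = 0
    runs = 8
    for seed in range(runs):
        table = make_labeled_table(n=200, effect=1.5, noise_sd=0.08, seed=seed)
        valid = make_labeled_table(n=100, effect=1.5, noise_sd=0.08,
                                   seed=seed + 50)
        model, trace = eliminate_descriptors(table, valid, seed=seed)
        kept = set(model.descriptor_subset)
        if {"psa_r", "fr_buried_sl_atoms", "hsa"} <= kept or \
           all(d in {"psa_r", "fr_buried_sl_atoms", "hsa"} for d in kept):
            hits += 1
        assert len(trace) <= 12 + 1
    assert hits >= int(0.75 * runs)


def test_elimination_single_descriptor_returns_immediately():
    table = make_labeled_table(n=60, seed=1).subset(["psa_r"])
    valid = make_labeled_table(n=40, seed=2).subset(["psa_r"])
    model, trace = eliminate_descriptors(table, valid, seed=0)
    assert model.descriptor_subset == ["psa_r"]
    assert len(trace) == 1


def test_loo_cv_counts_and_separable():
    table = _separable_table(n=24, seed=3)
    train_err, test_err = loo_cv(table, seed=0)
    assert train_err == 0.0
    assert test_err <= 0.1


def test_loo_cv_minimum_rows():
    table = _separable_table(n=24, seed=3)
    tiny = LabeledTable(table.rows.iloc[:2], table.labels.iloc[:2])
    with pytest.raises(ValueError):
        loo_cv(tiny, seed=0)
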
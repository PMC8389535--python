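"""Gradient-boosted druggability classifier with SHAP-driven pruning.

The classifier is an XGBoost tree ensemble with a binary-logistic objective
(probability output): pockets scoring ≥ 0.5 are labelled druggable.  Three
hyperparameters diverge from the library defaults — ``max_depth=3``,
``scale_pos_weight=0.63`` (training-set class skew) and early stopping with
patience 20 on a validation set — everything else is left at its default,
with the round cap at 1000.

Descriptor importance uses TreeSHAP as computed natively by XGBoost
(``pred_contribs=True``): the mean absolute SHAP value of a descriptor over
the data set ranks it, and :func:`eliminate_descriptors` iteratively drops
the weakest descriptor until validation accuracy degrades.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import xgboost as xgb

from .descriptors import DESCRIPTOR_NAMES, DescriptorVector

DRUGGABLE = "druggable"
LESS_DRUGGABLE = "less_druggable"
SCORE_THRESHOLD = 0.5

DEFAULT_PARAMS = {
    "max_depth": 3,
    "scale_pos_weight": 0.63,
    "objective": "binary:logistic",
    "eval_metric": "logloss",
    "nthread": 1,
}
EARLY_STOPPING_ROUNDS = 20
MAX_ROUNDS = 1000


@dataclass
class LabeledTable:
    """Descriptor rows plus druggable / less-druggable labels."""

    rows: pd.DataFrame                 # index: pocket_id, columns: descriptors
    labels: pd.Series                  # index: pocket_id, values in {druggable, less_druggable}

    def __post_init__(self) -> None:
        if not self.rows.index.equals(self.labels.index):
            self.labels = self.labels.reindex(self.rows.index)
        if self.labels.isna().any():
            raise ValueError("labels do not cover all rows")
        if self.rows.isna().any().any():
            raise ValueError("missing descriptor values")
        bad = set(self.labels.unique()) - {DRUGGABLE, LESS_DRUGGABLE}
        if bad:
            raise ValueError(f"unknown labels: {bad}")

    @property
    def y(self) -> np.ndarray:
        return (self.labels == DRUGGABLE).to_numpy(dtype=int)

    def subset(self, descriptors: Sequence[str]) -> "LabeledTable":
        return LabeledTable(self.rows[list(descriptors)], self.labels)

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class DruggabilityModel:
    booster: xgb.Booster
    descriptor_subset: list[str]
    seed: int
    best_iteration: int | None = None

    def dmatrix(self, rows: pd.DataFrame) -> xgb.DMatrix:
        return xgb.DMatrix(rows[self.descriptor_subset],
                           feature_names=self.descriptor_subset)

    def score(self, rows: pd.DataFrame) -> np.ndarray:
        it = (0, self.best_iteration + 1) if self.best_iteration is not None else None
        return self.booster.predict(self.dmatrix(rows), iteration_range=it)

    def shap_values(self, rows: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Per-row signed SHAP contributions (n, k) and the base values (n,),
        on the margin (log-odds) scale."""
        it = (0, self.best_iteration + 1) if self.best_iteration is not None else None
        contribs = self.booster.predict(self.dmatrix(rows), pred_contribs=True,
                                        iteration_range=it)
        return contribs[:, :-1], contribs[:, -1]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        self.booster.save_model(str(path))
        meta = {"descriptor_subset": self.descriptor_subset, "seed": self.seed,
                "threshold": SCORE_THRESHOLD, "best_iteration": self.best_iteration}
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "DruggabilityModel":
        path = Path(path)
        booster = xgb.Booster()
        booster.load_model(str(path))
        meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
        return cls(booster=booster, descriptor_subset=meta["descriptor_subset"],
                   seed=meta["seed"], best_iteration=meta.get("best_iteration"))


@dataclass
class Prediction:
    pocket_id: str
    score: float
    label: str
    shap_values: dict[str, float] = field(default_factory=dict)


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


def train_model(
    table: LabeledTable,
    validation: LabeledTable,
    seed: int = 0,
    params: dict | None = None,
    early_stopping_rounds: int = EARLY_STOPPING_ROUNDS,
    num_rounds: int = MAX_ROUNDS,
) -> DruggabilityModel:
    """Train the boosted classifier with early stopping on the validation
    set.  Deterministic for a fixed seed (single-threaded training)."""
    y = table.y
    if len(np.unique(y)) < 2:
        raise ValueError("training table must contain both classes")
    names = list(table.rows.columns)
    p = dict(DEFAULT_PARAMS)
    if params:
        p.update(params)
    p["seed"] = int(seed)
    dtrain = xgb.DMatrix(table.rows, label=y, feature_names=names)
    dvalid = xgb.DMatrix(validation.rows[names], label=validation.y, feature_names=names)
    booster = xgb.train(
        p, dtrain, num_boost_round=num_rounds,
        evals=[(dvalid, "validation")],
        early_stopping_rounds=early_stopping_rounds,
        verbose_eval=False,
    )
    best_it = getattr(booster, "best_iteration", None)
    return DruggabilityModel(booster=booster, descriptor_subset=names,
                             seed=int(seed), best_iteration=best_it)


def predict(model: DruggabilityModel, vector: DescriptorVector | dict | pd.Series,
            pocket_id: str = "") -> Prediction:
    """Score one pocket; score ≥ 0.5 (boundary inclusive) → druggable."""
    if isinstance(vector, DescriptorVector):
        data = vector.to_dict()
    elif isinstance(vector, pd.Series):
        data = vector.to_dict()
    else:
        data = dict(vector)
    missing = [d for d in model.descriptor_subset if d not in data]
    if missing:
        raise ValueError(f"missing descriptor(s): {', '.join(missing)}")
    row = pd.DataFrame([data])[model.descriptor_subset]
    score = float(model.score(row)[0])
    contribs, _ = model.shap_values(row)
    shap = dict(zip(model.descriptor_subset, contribs[0].tolist()))
    label = DRUGGABLE if score >= SCORE_THRESHOLD else LESS_DRUGGABLE
    return Prediction(pocket_id=pocket_id, score=score, label=label, shap_values=shap)


def predict_table(model: DruggabilityModel, rows: pd.DataFrame) -> pd.DataFrame:
    """Score a descriptor table; returns a DataFrame with score and label."""
    scores = model.score(rows)
    labels = np.where(scores >= SCORE_THRESHOLD, DRUGGABLE, LESS_DRUGGABLE)
    return pd.DataFrame({"score": scores, "label": labels}, index=rows.index)


def confusion_counts(model: DruggabilityModel, table: LabeledTable) -> ConfusionCounts:
    pred = predict_table(model, table.rows)["label"].to_numpy()
    truth = table.labels.to_numpy()
    tp = int(np.sum((pred == DRUGGABLE) & (truth == DRUGGABLE)))
    tn = int(np.sum((pred == LESS_DRUGGABLE) & (truth == LESS_DRUGGABLE)))
    fp = int(np.sum((pred == DRUGGABLE) & (truth == LESS_DRUGGABLE)))
    fn = int(np.sum((pred == LESS_DRUGGABLE) & (truth == DRUGGABLE)))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def evaluate(counts: ConfusionCounts) -> dict:
    """Accuracy plus per-class precision and recall (druggable treated as
    the positive class; the less-druggable class gets the symmetric
    definitions).  Zero denominators yield ``None`` (undefined), not 0."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    total = tp + tn + fp + fn
    if total < 1:
        raise ValueError("empty confusion matrix")

    def _ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return {
        "accuracy": (tp + tn) / total,
        "precision": {
            DRUGGABLE: _ratio(tp, tp + fp),
            LESS_DRUGGABLE: _ratio(tn, tn + fn),
        },
        "recall": {
            DRUGGABLE: _ratio(tp, tp + fn),
            LESS_DRUGGABLE: _ratio(tn, tn + fp),
        },
    }


def shap_rank(model: DruggabilityModel, table: LabeledTable) -> list[tuple[str, float]]:
    """Descriptors sorted by descending mean absolute SHAP value over the
    table; the per-pocket signed values are available via
    :meth:`DruggabilityModel.shap_values`."""
    contribs, _ = model.shap_values(table.rows)
    mean_abs = np.abs(contribs).mean(axis=0)
    order = np.argsort(-mean_abs, kind="stable")
    return [(model.descriptor_subset[i], float(mean_abs[i])) for i in order]


def _accuracy(model: DruggabilityModel, table: LabeledTable) -> float:
    c = confusion_counts(model, table)
    return (c.tp + c.tn) / len(table)


def eliminate_descriptors(
    train: LabeledTable,
    validation: LabeledTable,
    seed: int = 0,
) -> tuple[DruggabilityModel, list[dict]]:
    """Iterative SHAP-guided descriptor elimination.

    Train, rank descriptors by mean |SHAP|, drop the weakest, retrain;
    stop as soon as validation accuracy falls below the best seen so far,
    and return the model fitted just before the degrading step together
    with the full trace (one entry per fitted model)."""
    if train.rows.shape[1] < 1:
        raise ValueError("need at least one descriptor")
    current = list(train.rows.columns)
    trace: list[dict] = []
    best_acc = -np.inf
    best_model: DruggabilityModel | None = None
    while True:
        model = train_model(train.subset(current), validation.subset(current), seed=seed)
        acc = _accuracy(model, validation.subset(current))
        ranking = shap_rank(model, train.subset(current))
        trace.append({"descriptors": list(current), "validation_accuracy": acc,
                      "ranking": ranking})
        if acc < best_acc:
            break
        best_acc = acc
        best_model = model
        if len(current) == 1:
            break
        weakest = ranking[-1][0]
        current = [d for d in current if d != weakest]
    assert best_model is not None
    return best_model, trace


def loo_cv(table: LabeledTable, seed: int = 0) -> tuple[float, float]:
    """Leave-one-out cross-validation: one model per row, early stopping
    monitored on the training fold itself.  Returns the mean training and
    testing misclassification rates."""
    n = len(table)
    if n < 3:
        raise ValueError("need at least 3 rows for leave-one-out")
    train_errs = []
    test_errs = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        tr = LabeledTable(table.rows.iloc[mask], table.labels.iloc[mask])
        model = train_model(tr, tr, seed=seed)
        train_errs.append(1.0 - _accuracy(model, tr))
        held = table.rows.iloc[[i]]
        pred = predict_table(model, held)["label"].iloc[0]
        test_errs.append(float(pred != table.labels.iloc[i]))
    return float(np.mean(train_errs)), float(np.mean(test_errs))


# --- table I/O ---------------------------------------------------------------

def read_labeled_table(path: str | Path) -> LabeledTable:
    """Read a labelled descriptor CSV (index column ``pocket_id``, a
    ``label`` column, descriptor columns)."""
    df = pd.read_csv(path, index_col=0)
    if "label" not in df.columns:
        raise ValueError(f"{path}: no 'label' column")
    labels = df["label"]
    rows = df.drop(columns=["label"])
    return LabeledTable(rows, labels)


def write_labeled_table(table: LabeledTable, path: str | Path) -> None:
    df = table.rows.copy()
    df["label"] = table.labels
    df.to_csv(path, index_label="pocket_id")
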
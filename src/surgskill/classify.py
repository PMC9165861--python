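"""Three-class surgical-skill classification and evaluation.

Three classifiers — a 100-tree random forest, an RBF-kernel support
vector machine, and Gaussian naive Bayes — are trained on 70% of the
data and evaluated on the held-out 30%, per muscle and per muscle
combination.  Metrics come from the 3x3 confusion matrix via the
one-vs-rest decomposition; ROC curves and AUCs are one-vs-rest per
class.

Note on the precision formula: the source protocol prints precision
with a TP+FN denominator, which duplicates recall; the standard
TP/(TP+FP) is implemented and the deviation recorded in every report
footer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features_table import feature_columns, pivot_muscle_features
from .types import MUSCLES, SKILLS, InvalidArgumentError

logger = logging.getLogger(__name__)

MODEL_NAMES = ("random_forest", "svm", "naive_bayes")

PRECISION_NOTE = (
    "precision computed as TP/(TP+FP); the protocol's printed formula "
    "(TP/(TP+FN)) duplicates recall and is treated as a typographical error"
)


@dataclass(frozen=True)
class SplitSpec:
    """70/30 train/test split specification.

    ``grouping='subject'`` keeps every subject's rows on one side of the
    split (no leakage across a subject's trials); ``'row'`` treats trials
    as independent samples.
    """

    train_fraction: float = 0.7
    stratified: bool = True
    seed: int = 0
    grouping: str = "subject"

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise InvalidArgumentError("train_fraction must lie in (0, 1)")
        if self.grouping not in ("subject", "row"):
            raise InvalidArgumentError("grouping must be 'subject' or 'row'")


def split_train_test(
    table: pd.DataFrame, spec: SplitSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified, seeded train/test split of a labeled table."""
    rng = np.random.default_rng(spec.seed)
    for cls in SKILLS:
        if (table["skill"] == cls).sum() < 2:
            raise InvalidArgumentError(f"class {cls!r} has fewer than 2 rows")
    if spec.grouping == "subject":
        train_idx, test_idx = [], []
        for cls in SKILLS:
            cls_rows = table[table["skill"] == cls]
            subjects = sorted(cls_rows["subject_id"].unique())
            if len(subjects) < 2:
                raise InvalidArgumentError(
                    f"class {cls!r} needs >= 2 subjects for a subject-level split"
                )
            order = list(rng.permutation(subjects))
            n_train = int(round(spec.train_fraction * len(subjects)))
            n_train = min(max(n_train, 1), len(subjects) - 1)
            train_subj = set(order[:n_train])
            train_idx.extend(cls_rows.index[cls_rows["subject_id"].isin(train_subj)])
            test_idx.extend(cls_rows.index[~cls_rows["subject_id"].isin(train_subj)])
        return table.loc[sorted(train_idx)], table.loc[sorted(test_idx)]
    # row-level stratified split
    train_idx, test_idx = [], []
    for cls in SKILLS:
        idx = np.array(sorted(table.index[table["skill"] == cls]))
        order = rng.permutation(idx)
        n_train = int(round(spec.train_fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        train_idx.extend(order[:n_train])
        test_idx.extend(order[n_train:])
    return table.loc[sorted(train_idx)], table.loc[sorted(test_idx)]


def make_models(seed: int = 0) -> dict[str, Pipeline]:
    """The three classifiers with train-fit imputation/standardization.

    The random forest consumes raw (median-imputed) features; the SVM and
    naive Bayes additionally get zero-mean unit-variance standardization
    fit on the training data only.
    """
    impute = lambda: SimpleImputer(strategy="median")  # noqa: E731
    return {
        "random_forest": Pipeline(
            [("impute", impute()),
             ("model", RandomForestClassifier(n_estimators=100, random_state=seed))]
        ),
        "svm": Pipeline(
            [("impute", impute()), ("scale", StandardScaler()),
             ("model", SVC(kernel="rbf", random_state=seed))]
        ),
        "naive_bayes": Pipeline(
            [("impute", impute()), ("scale", StandardScaler()), ("model", GaussianNB())]
        ),
    }


def train_models(
    train_table: pd.DataFrame,
    model_names: Sequence[str] = MODEL_NAMES,
    seed: int = 0,
) -> dict[str, Pipeline]:
    """Fit the requested classifiers on a labeled feature table."""
    if train_table.empty:
        raise InvalidArgumentError("empty training table")
    y = train_table["skill"].to_numpy()
    if len(set(y)) < 2:
        raise InvalidArgumentError("training data contains a single class")
    X = train_table[feature_columns(train_table)].to_numpy(dtype=float)
    models = make_models(seed)
    fitted = {}
    for name in model_names:
        if name not in models:
            raise InvalidArgumentError(f"unknown model {name!r}")
        fitted[name] = models[name].fit(X, y)
    return fitted


@dataclass
class ConfusionCounts:
    """3x3 confusion matrix plus its one-vs-rest decompositions."""

    matrix: np.ndarray  # rows = true class, cols = predicted
    classes: tuple[str, ...]
    per_class: dict[str, dict[str, int]]  # class -> {TP, TN, FP, FN}


@dataclass
class MetricSet:
    counts: ConfusionCounts
    accuracy: float  # overall fraction correct (trace / n)
    per_class: pd.DataFrame  # rows = classes; accuracy/precision/recall/specificity/f1
    macro: dict[str, float]


def confusion_metrics(
    y_true: Sequence[str], y_pred: Sequence[str], classes: Sequence[str] = SKILLS
) -> MetricSet:
    """Confusion matrix and the five one-vs-rest metrics.

    Per class: accuracy (TP+TN)/n, recall TP/(TP+FN), specificity
    TN/(TN+FP), precision TP/(TP+FP), F1 the harmonic mean of precision
    and recall.  A zero denominator flags that metric NaN for the class
    and excludes it from the macro average (logged).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size != y_pred.size:
        raise InvalidArgumentError("y_true and y_pred must have equal lengths")
    classes = tuple(classes)
    index = {c: i for i, c in enumerate(classes)}
    for v in np.concatenate([y_true, y_pred]):
        if v not in index:
            raise InvalidArgumentError(f"label {v!r} outside the class set {classes}")
    n = y_true.size
    mat = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        mat[index[t], index[p]] += 1
    per_class_counts = {}
    rows = []
    for c in classes:
        i = index[c]
        tp = int(mat[i, i])
        fn = int(mat[i, :].sum() - tp)
        fp = int(mat[:, i].sum() - tp)
        tn = n - tp - fn - fp
        per_class_counts[c] = {"TP": tp, "TN": tn, "FP": fp, "FN": fn}

        def ratio(num: int, den: int, name: str) -> float:
            if den == 0:
                logger.warning("%s undefined for class %s (zero denominator)", name, c)
                return float("nan")
            return num / den

        recall = ratio(tp, tp + fn, "recall")
        precision = ratio(tp, tp + fp, "precision")
        specificity = ratio(tn, tn + fp, "specificity")
        if np.isnan(recall) or np.isnan(precision) or (recall + precision) == 0:
            f1 = float("nan") if (np.isnan(recall) or np.isnan(precision)) else 0.0
        else:
            f1 = 2 * recall * precision / (recall + precision)
        rows.append(
            {
                "class": c,
                "accuracy": (tp + tn) / n,
                "precision": precision,
                "recall": recall,
                "specificity": specificity,
                "f1": f1,
            }
        )
    per_class = pd.DataFrame(rows).set_index("class")
    macro = {
        k: float(np.nanmean(per_class[k].to_numpy()))
        for k in ("precision", "recall", "specificity", "f1")
    }
    counts = ConfusionCounts(matrix=mat, classes=classes, per_class=per_class_counts)
    return MetricSet(
        counts=counts,
        accuracy=float(np.trace(mat)) / n,
        per_class=per_class,
        macro=macro,
    )


def roc_one_vs_rest(
    scores: np.ndarray,
    y_true: Sequence[str],
    classes: Sequence[str] = SKILLS,
) -> dict[str, dict]:
    """Per-class one-vs-rest ROC curves and trapezoidal AUCs.

    ``scores`` is an (n, n_classes) array of class scores (probabilities
    or decision values) in ``classes`` order.  A class absent from
    ``y_true`` yields a ``None`` entry (flagged, logged).
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    out: dict[str, dict] = {}
    for i, c in enumerate(classes):
        pos = (y_true == c).astype(int)
        if pos.sum() == 0 or pos.sum() == pos.size:
            logger.warning("ROC undefined for class %s (absent or exhaustive)", c)
            out[c] = None
            continue
        fpr, tpr, _ = roc_curve(pos, scores[:, i])
        out[c] = {"fpr": fpr, "tpr": tpr, "auc": float(sk_auc(fpr, tpr))}
    return out


@dataclass
class SkillModelReport:
    """Evaluation results per (muscle set, model)."""

    table: pd.DataFrame  # muscle_set, model, accuracy, precision, recall, f1, specificity
    confusions: dict[tuple[str, str], MetricSet]
    rocs: dict[tuple[str, str], dict[str, dict]]
    config: dict
    footer: str = PRECISION_NOTE


def evaluate_table(
    table: pd.DataFrame,
    spec: SplitSpec,
    model_names: Sequence[str] = MODEL_NAMES,
    seed: int = 0,
) -> tuple[dict[str, MetricSet], dict[str, dict], dict[str, "Pipeline"]]:
    """Split, train all models, and evaluate on the held-out rows."""
    train, test = split_train_test(table, spec)
    fitted = train_models(train, model_names, seed=seed)
    feats = feature_columns(table)
    X_test = test[feats].to_numpy(dtype=float)
    y_test = test["skill"].to_numpy()
    metrics, rocs = {}, {}
    for name, model in fitted.items():
        y_pred = model.predict(X_test)
        metrics[name] = confusion_metrics(y_test, y_pred)
        classes = list(model.classes_)
        if hasattr(model, "predict_proba"):
            scores = model.predict_proba(X_test)
        else:  # SVM: one-vs-rest decision values
            scores = np.atleast_2d(model.decision_function(X_test))
            if scores.shape[1] != len(classes):  # binary case returns 1-D
                scores = np.column_stack([-scores.ravel(), scores.ravel()])
        aligned = np.column_stack(
            [scores[:, classes.index(c)] if c in classes else np.zeros(len(y_test))
             for c in SKILLS]
        )
        rocs[name] = roc_one_vs_rest(aligned, y_test)
    return metrics, rocs, fitted


def evaluate_muscle_sets(
    trial_table: pd.DataFrame,
    muscle_sets: Sequence[Sequence[str]],
    spec: SplitSpec,
    model_names: Sequence[str] = MODEL_NAMES,
    seed: int = 0,
) -> SkillModelReport:
    """Train/evaluate every model on every muscle set's feature subset.

    Each muscle set restricts the trial table to its sensors, widens
    per-(muscle, side) features into columns, then runs the 70/30
    protocol for the three models.
    """
    for ms in muscle_sets:
        for m in ms:
            if m not in MUSCLES:
                raise InvalidArgumentError(f"unknown muscle {m!r}")
    rows = []
    confusions: dict[tuple[str, str], MetricSet] = {}
    rocs: dict[tuple[str, str], dict] = {}
    for ms in muscle_sets:
        set_name = "+".join(ms)
        wide = pivot_muscle_features(trial_table, ms)
        metrics, roc_bundle, _ = evaluate_table(wide, spec, model_names, seed=seed)
        for name in model_names:
            mset = metrics[name]
            rows.append(
                {
                    "muscle_set": set_name,
                    "model": name,
                    "accuracy": mset.accuracy,
                    "precision": mset.macro["precision"],
                    "recall": mset.macro["recall"],
                    "f1": mset.macro["f1"],
                    "specificity": mset.macro["specificity"],
                }
            )
            confusions[(set_name, name)] = mset
            rocs[(set_name, name)] = roc_bundle[name]
    report_table = pd.DataFrame(rows)
    config = {
        "train_fraction": spec.train_fraction,
        "grouping": spec.grouping,
        "seed": seed,
        "models": list(model_names),
        "muscle_sets": ["+".join(ms) for ms in muscle_sets],
    }
    return SkillModelReport(table=report_table, confusions=confusions, rocs=rocs, config=config)
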
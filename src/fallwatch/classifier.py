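"""Four-class posture classification (bend / lie / sit / stand) and evaluation.

The classifier is a C-SVM with RBF kernel (libsvm via scikit-learn), trained
on the projection-histogram feature vectors.  Multiclass handling is the
usual one-vs-one construction.  No feature standardization is applied: the
histogram block already lives in [0, 1] and the appended angles are bounded
by pi, so the tuned kernel width (gamma = 0.01) and cost (C = 100) act on a
naturally bounded space.

Evaluation follows the one-vs-rest convention per class: accuracy
(TP+TN)/(TP+FP+TN+FN), precision TP/(TP+FP), recall TP/(TP+FN) and the
F-score 2PR/(P+R), plus a micro-averaged overall accuracy (trace of the
confusion matrix over the total).  Metrics with a zero denominator are
reported as 0 and flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "POSTURE_NAMES",
    "POSTURE_CODES",
    "ABNORMAL_POSTURES",
    "ClassifierParams",
    "EvalReport",
    "train_posture_model",
    "predict_posture",
    "evaluate",
    "kfold_cv",
    "save_model",
    "load_model",
]

#: Label space: 1=bend, 2=lie, 3=sit, 4=stand.
POSTURE_NAMES = {1: "bend", 2: "lie", 3: "sit", 4: "stand"}
POSTURE_CODES = {v: k for k, v in POSTURE_NAMES.items()}
#: Fall-related postures (rule 1 of the fall engine).
ABNORMAL_POSTURES = frozenset({POSTURE_CODES["lie"], POSTURE_CODES["bend"]})
LABELS = (1, 2, 3, 4)


@dataclass(frozen=True)
class ClassifierParams:
    cost: float = 100.0
    gamma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cost <= 0 or self.gamma <= 0:
            raise ValueError("cost and gamma must be positive")


@dataclass
class ClassMetrics:
    accuracy: float
    precision: float
    recall: float
    f_score: float
    flags: list[str] = field(default_factory=list)


@dataclass
class EvalReport:
    confusion: np.ndarray  # 4x4 counts, rows = truth, cols = prediction
    accuracy: float  # micro-average: trace / total
    per_class: dict[int, ClassMetrics]

    @property
    def min_recall(self) -> float:
        return min(m.recall for m in self.per_class.values())


def train_posture_model(
    features: np.ndarray, labels, params: ClassifierParams | None = None
) -> SVC:
    """Fit the RBF C-SVM on a feature table (rows) with posture labels."""
    params = params or ClassifierParams()
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D table")
    if len(y) != X.shape[0]:
        raise ValueError(f"length mismatch: {X.shape[0]} rows vs {len(y)} labels")
    if np.unique(y).size < 2:
        raise ValueError("need >= 2 classes to train")
    if not np.isfinite(X).all():
        raise ValueError("features contain missing or non-finite values")
    model = SVC(
        kernel="rbf",
        C=params.cost,
        gamma=params.gamma,
        random_state=params.seed,
    )
    model.fit(X, y)
    return model


def predict_posture(model: SVC, fs: np.ndarray) -> np.ndarray | int:
    """Predict posture code(s); accepts one vector or a table of rows."""
    fs = np.asarray(fs, dtype=np.float64)
    single = fs.ndim == 1
    X = fs[None, :] if single else fs
    if X.shape[1] != model.n_features_in_:
        raise ValueError(
            f"dimension mismatch: got {X.shape[1]} features, "
            f"model expects {model.n_features_in_}"
        )
    pred = model.predict(X)
    return int(pred[0]) if single else pred.astype(int)


def evaluate(predictions, truth, labels=None) -> EvalReport:
    """Confusion matrix plus one-vs-rest metrics for each posture class.

    ``labels`` defaults to the four posture codes; if the data carries other
    codes the label set is inferred from the data instead.
    """
    pred = np.asarray(predictions, dtype=int)
    true = np.asarray(truth, dtype=int)
    if pred.size == 0:
        raise ValueError("empty input")
    if pred.shape != true.shape:
        raise ValueError("length mismatch between predictions and truth")
    if labels is None:
        seen = set(pred) | set(true)
        labels = LABELS if seen <= set(LABELS) else tuple(sorted(seen))
    k = len(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    confusion = np.zeros((k, k), dtype=np.int64)
    for t, p in zip(true, pred):
        confusion[index[t], index[p]] += 1
    total = confusion.sum()
    per_class: dict[int, ClassMetrics] = {}
    for lab in labels:
        i = index[lab]
        tp = confusion[i, i]
        fp = confusion[:, i].sum() - tp
        fn = confusion[i, :].sum() - tp
        tn = total - tp - fp - fn
        flags = []
        acc = (tp + tn) / total
        if tp + fp > 0:
            prec = tp / (tp + fp)
        else:
            prec, flags = 0.0, flags + ["no_predicted_positives"]
        if tp + fn > 0:
            rec = tp / (tp + fn)
        else:
            rec, flags = 0.0, flags + ["class_absent_from_truth"]
        if prec + rec > 0:
            f = 2 * prec * rec / (prec + rec)
        else:
            f, flags = 0.0, flags + ["zero_f_denominator"]
        per_class[lab] = ClassMetrics(
            accuracy=float(acc),
            precision=float(prec),
            recall=float(rec),
            f_score=float(f),
            flags=flags,
        )
    return EvalReport(
        confusion=confusion,
        accuracy=float(np.trace(confusion) / total),
        per_class=per_class,
    )


def kfold_cv(
    features,
    labels,
    k: int = 10,
    params: ClassifierParams | None = None,
    seed: int = 0,
) -> EvalReport:
    """Stratified k-fold cross-validation; pooled held-out confusion matrix.

    Falls back to plain (unstratified) folding with a warning when a class
    has fewer members than there are folds.
    """
    params = params or ClassifierParams(seed=seed)
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = np.bincount(y)
    if counts[counts > 0].min() < k:
        warnings.warn(
            "a class has fewer members than folds; using unstratified folds",
            stacklevel=2,
        )
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pooled_pred = np.empty_like(y)
    for train_idx, test_idx in splitter.split(X, y):
        model = train_posture_model(X[train_idx], y[train_idx], params)
        pooled_pred[test_idx] = predict_posture(model, X[test_idx])
    return evaluate(pooled_pred, y)


def save_model(model: SVC, params: ClassifierParams, path) -> None:
    """Persist the trained model with its parameter header to one file."""
    joblib.dump({"format": "fallwatch-svm-v1", "params": params, "model": model}, path)


def load_model(path) -> tuple[SVC, ClassifierParams]:
    payload = joblib.load(path)
    if not isinstance(payload, dict) or payload.get("format") != "fallwatch-svm-v1":
        raise ValueError("not a fallwatch model file")
    return payload["model"], payload["params"]
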
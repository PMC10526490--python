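"""Cross-validation schemes, metric definitions and the training loop.

K-fold plans are stratified by class within subject (fold sizes differ by at
most one); the leave-one-subject-out scheme makes one fold per subject.
Metrics are computed from one-vs-rest confusion counts and reported as
percentages; for more than two classes precision/recall/F are macro-averaged.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, EmotionClassifier, ModelConfig, Tensor
from .nn.functional import softmax_cross_entropy

__all__ = [
    "binarize_ratings",
    "FoldPlan",
    "make_folds",
    "ConfusionCounts",
    "MetricReport",
    "confusion_counts",
    "compute_metrics",
    "TrainSettings",
    "train_model",
    "train_and_evaluate",
]


def binarize_ratings(ratings: np.ndarray, threshold: float = 5.0) -> np.ndarray:
    """Continuous 1-9 scores -> {0, 1}: score > threshold is class 1 (high).

    Scores exactly at the threshold go to the low class (deterministic tie
    rule).
    """
    ratings = np.asarray(ratings, dtype=np.float64)
    if np.any(ratings < 1.0) or np.any(ratings > 9.0):
        bad = ratings[(ratings < 1.0) | (ratings > 9.0)][0]
        raise ValueError(f"rating {bad} outside the 1-9 scale")
    return (ratings > threshold).astype(np.int64)


# --------------------------------------------------------------------------
# fold planning
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldPlan:
    scheme: str  # "kfold" or "loso"
    n_folds: int
    assignments: np.ndarray  # sample index -> fold id
    seed: int

    def __post_init__(self):
        a = np.asarray(self.assignments)
        if a.min() < 0 or a.max() >= self.n_folds:
            raise ValueError("fold assignments out of range")
        if self.scheme == "kfold":
            sizes = np.bincount(a, minlength=self.n_folds)
            if sizes.max() - sizes.min() > 1:
                raise ValueError(f"kfold sizes differ by more than 1: {sizes.tolist()}")

    def folds(self):
        for f in range(self.n_folds):
            test = np.flatnonzero(self.assignments == f)
            train = np.flatnonzero(self.assignments != f)
            yield f, train, test


def make_folds(
    labels: np.ndarray,
    subjects: np.ndarray,
    scheme: str = "kfold",
    k: int = 5,
    seed: int = 0,
) -> FoldPlan:
    """Build a cross-validation plan.

    ``kfold``: samples are dealt to k folds within each (subject, class)
    group, with a rolling pointer so overall fold sizes differ by at most
    one. ``loso``: one fold per subject.
    """
    labels = np.asarray(labels)
    subjects = np.asarray(subjects)
    if labels.shape != subjects.shape:
        raise ValueError("labels and subjects must align")
    n = labels.shape[0]
    if scheme == "loso":
        uniq = np.unique(subjects)
        sub_to_fold = {s: i for i, s in enumerate(uniq)}
        assignments = np.array([sub_to_fold[s] for s in subjects])
        return FoldPlan(scheme="loso", n_folds=len(uniq), assignments=assignments, seed=seed)
    if scheme != "kfold":
        raise ValueError(f"unknown scheme {scheme!r}")
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples ({n})")
    rng = np.random.default_rng(seed)
    assignments = np.empty(n, dtype=np.int64)
    pointer = rng.integers(k)
    for subject in np.unique(subjects):
        for cls in np.unique(labels):
            idx = np.flatnonzero((subjects == subject) & (labels == cls))
            rng.shuffle(idx)
            for i in idx:
                assignments[i] = pointer % k
                pointer += 1
    return FoldPlan(scheme="kfold", n_folds=k, assignments=assignments, seed=seed)


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion counts for a single positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricReport:
    """Percent-scale metrics; ratios with a zero denominator are ``None``."""

    accuracy: float
    precision: float | None
    recall: float | None
    f_score: float | None


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray, positive: int) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos_t = y_true == positive
    pos_p = y_pred == positive
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def compute_metrics(counts: ConfusionCounts) -> MetricReport:
    """Accuracy, precision, recall and F-score (percent) from confusion counts."""
    if counts.total == 0:
        raise ValueError("no evaluated samples")
    accuracy = 100.0 * (counts.tp + counts.tn) / counts.total
    precision = recall = f_score = None
    if counts.tp + counts.fp > 0:
        precision = 100.0 * counts.tp / (counts.tp + counts.fp)
    else:
        warnings.warn("precision undefined: no positive predictions", stacklevel=2)
    if counts.tp + counts.fn > 0:
        recall = 100.0 * counts.tp / (counts.tp + counts.fn)
    else:
        warnings.warn("recall undefined: no positive ground-truth samples", stacklevel=2)
    if precision is not None and recall is not None:
        if precision + recall > 0:
            f_score = 2.0 * precision * recall / (precision + recall)
        else:
            f_score = 0.0
    return MetricReport(accuracy=accuracy, precision=precision, recall=recall, f_score=f_score)


def _evaluate_predictions(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> MetricReport:
    """Binary: class 1 is positive. Multiclass: macro one-vs-rest averages,
    skipping classes whose ratio is undefined."""
    accuracy = 100.0 * float(np.mean(y_true == y_pred))
    if n_classes == 2:
        rep = compute_metrics(confusion_counts(y_true, y_pred, positive=1))
        return MetricReport(accuracy, rep.precision, rep.recall, rep.f_score)
    precisions, recalls, fs = [], [], []
    for cls in range(n_classes):
        rep = compute_metrics(confusion_counts(y_true, y_pred, positive=cls))
        if rep.precision is not None:
            precisions.append(rep.precision)
        if rep.recall is not None:
            recalls.append(rep.recall)
        if rep.f_score is not None:
            fs.append(rep.f_score)
    return MetricReport(
        accuracy=accuracy,
        precision=float(np.mean(precisions)) if precisions else None,
        recall=float(np.mean(recalls)) if recalls else None,
        f_score=float(np.mean(fs)) if fs else None,
    )


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

@dataclass
class TrainSettings:
    epochs: int = 100
    batch_size: int = 128
    learning_rate: float = 1e-3
    normalize: bool = True  # standardize occupied cells using training-data stats

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("invalid training settings")


def train_model(
    x: np.ndarray,
    y: np.ndarray,
    cfg: ModelConfig,
    settings: TrainSettings = TrainSettings(),
    rng: np.random.Generator | None = None,
) -> tuple[EmotionClassifier, list[float]]:
    """Train a classifier with Adam + cross-entropy; returns (model, per-epoch losses)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if x.shape[0] != y.shape[0]:
        raise ValueError("features and labels must align")
    if len(np.unique(y)) < 2:
        warnings.warn("training data contains a single class", stacklevel=2)
    rng = rng or np.random.default_rng(cfg.seed)
    model = EmotionClassifier(cfg)
    if settings.normalize:
        occupied = x[x != 0]
        if occupied.size and occupied.std() > 0:
            model.set_normalizer(occupied.mean(), occupied.std())
        x = model.normalize(x)
    optimizer = Adam(model.parameters(), lr=settings.learning_rate)
    n = x.shape[0]
    epoch_losses: list[float] = []
    for _ in range(settings.epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, settings.batch_size):
            idx = order[start : start + settings.batch_size]
            logits = model.forward_logits(Tensor(x[idx]))
            loss = softmax_cross_entropy(logits, y[idx])
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            total += float(loss.data) * len(idx)
        epoch_losses.append(total / n)
    return model, epoch_losses


@dataclass
class FoldResult:
    fold: int
    report: MetricReport
    n_train: int
    n_test: int
    losses: list[float]


def train_and_evaluate(
    features: np.ndarray,
    labels: np.ndarray,
    cfg: ModelConfig,
    plan: FoldPlan,
    settings: TrainSettings = TrainSettings(),
) -> dict:
    """Train one model per fold (seeded from master seed + fold id) and report
    per-fold and aggregate metrics."""
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if features.shape[0] != labels.shape[0]:
        raise ValueError("features and labels must align")
    if plan.assignments.shape[0] != labels.shape[0]:
        raise ValueError("fold plan does not cover all samples")
    for fold_id, train_idx, test_idx in plan.folds():
        if test_idx.size == 0:
            raise ValueError(f"fold {fold_id} has an empty test set")
        if train_idx.size == 0:
            raise ValueError(f"fold {fold_id} has an empty training set")
    results: list[FoldResult] = []
    for fold_id, train_idx, test_idx in plan.folds():
        if len(np.unique(labels[train_idx])) < 2:
            warnings.warn(f"fold {fold_id}: training data contains a single class", stacklevel=2)
        fold_cfg = ModelConfig.from_dict({**cfg.to_dict(), "seed": cfg.seed + fold_id})
        t0 = time.perf_counter()
        model, losses = train_model(
            features[train_idx], labels[train_idx], fold_cfg, settings,
            rng=np.random.default_rng(fold_cfg.seed),
        )
        y_pred = model.predict(features[test_idx])
        report = _evaluate_predictions(labels[test_idx], y_pred, fold_cfg.n_classes)
        results.append(
            FoldResult(
                fold=fold_id,
                report=report,
                n_train=int(train_idx.size),
                n_test=int(test_idx.size),
                losses=losses,
            )
        )
    accs = np.array([r.report.accuracy for r in results])
    summary = {
        "scheme": plan.scheme,
        "n_folds": plan.n_folds,
        "seed": plan.seed,
        "mean_accuracy": float(accs.mean()),
        "sd_accuracy": float(accs.std(ddof=1)) if len(accs) > 1 else 0.0,
        "folds": [
            {
                "fold": r.fold,
                "accuracy": r.report.accuracy,
                "precision": r.report.precision,
                "recall": r.report.recall,
                "f_score": r.report.f_score,
                "n_train": r.n_train,
                "n_test": r.n_test,
                "final_loss": r.losses[-1],
            }
            for r in results
        ],
        "epoch_losses": [r.losses for r in results],
    }
    return summary
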
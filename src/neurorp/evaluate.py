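"""Evaluation: confusion matrices, the four report metrics, k-fold CV.

Metrics follow the usual multiclass conventions: accuracy is the fraction
of correct predictions (trace over total); precision and recall are
computed one-vs-rest per class and macro-averaged over the fixed class
order (0-back, 2-back, 3-back, rest); F1 is the harmonic mean of the macro
precision and macro recall.  All four are reported in percent.

Cross-validation is stratified over classifier samples (whole RP
sequences, never individual overlapping windows, so adjacent windows
cannot straddle a fold boundary), with per-fold training from scratch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, KFold

from .core_io import CLASS_LABELS
from .model import (
    ArchitectureSpec,
    TrainConfig,
    build_model,
    predict_proba,
    train,
)
from .recurrence import RPSample

__all__ = [
    "confusion_matrix",
    "metrics",
    "FoldResult",
    "EvalReport",
    "kfold_cv",
    "report",
]


def confusion_matrix(
    y_true, y_pred, classes: tuple[str, ...] = CLASS_LABELS
) -> np.ndarray:
    """Count matrix with rows = true class, columns = predicted class."""
    from sklearn.metrics import confusion_matrix as sk_cm

    return sk_cm(y_true, y_pred, labels=list(classes))


def metrics(cm: np.ndarray) -> dict[str, float]:
    """Accuracy, macro precision, macro recall and F1 (all in %) from a
    confusion matrix.

    Classes with no predicted (or no actual) positives contribute 0 to the
    macro average, with a warning.
    """
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(cm).astype(float)
    pred_pos = cm.sum(axis=0).astype(float)
    actual_pos = cm.sum(axis=1).astype(float)
    if (pred_pos == 0).any() or (actual_pos == 0).any():
        warnings.warn(
            "class(es) with zero predicted or actual positives contribute 0 "
            "to the macro average",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.where(pred_pos > 0, tp / pred_pos, 0.0)
        rec = np.where(actual_pos > 0, tp / actual_pos, 0.0)
    macro_p = prec.mean()
    macro_r = rec.mean()
    f1 = 2 * macro_p * macro_r / (macro_p + macro_r) if macro_p + macro_r > 0 else 0.0
    return {
        "accuracy": 100.0 * tp.sum() / total,
        "precision": 100.0 * macro_p,
        "recall": 100.0 * macro_r,
        "f1": 100.0 * f1,
    }


@dataclass
class FoldResult:
    cm: np.ndarray
    metrics: dict[str, float]
    test_indices: np.ndarray


@dataclass
class EvalReport:
    """Per-fold confusion matrices and metrics plus their arithmetic mean."""

    folds: list[FoldResult]
    mean: dict[str, float]
    modality: str = ""
    seed: int = 0

    @property
    def accuracy(self) -> float:
        return self.mean["accuracy"]

    def as_frame(self) -> pd.DataFrame:
        rows = [f.metrics for f in self.folds] + [self.mean]
        idx = [f"fold{i + 1}" for i in range(len(self.folds))] + ["mean"]
        return pd.DataFrame(rows, index=idx)


def kfold_cv(
    samples: list[RPSample],
    k: int = 10,
    seed: int = 0,
    stratified: bool = True,
    spec: ArchitectureSpec | None = None,
    cfg: TrainConfig | None = None,
    classes: tuple[str, ...] = CLASS_LABELS,
    modality: str = "",
) -> EvalReport:
    """Stratified k-fold cross-validation with per-fold training from scratch.

    Fold assignment is deterministic given ``seed``; model initialization
    and shuffling derive from the same seed.  Every class must supply at
    least ``k`` samples.
    """
    spec = spec or ArchitectureSpec()
    cfg = cfg or TrainConfig()
    y = np.array([s.label for s in samples])
    present = [c for c in classes if (y == c).sum() > 0]
    counts = {c: int((y == c).sum()) for c in present}
    if stratified:
        short = {c: n for c, n in counts.items() if n < k}
        if short:
            raise ValueError(
                f"class(es) with fewer than k={k} samples: {short}; use a smaller k"
            )
    splitter = (
        StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        if stratified
        else KFold(n_splits=k, shuffle=True, random_state=seed)
    )
    folds = []
    all_test: list[np.ndarray] = []
    for fold_i, (tr, te) in enumerate(splitter.split(np.zeros(len(samples)), y)):
        assert not set(tr) & set(te), "train/test leakage within a fold"
        net = build_model(
            spec, _shapes_of(samples[0]), seed=seed * 1000 + fold_i
        )
        clf = train(net, [samples[i] for i in tr], cfg, classes=classes)
        proba = predict_proba(clf, [samples[i] for i in te])
        pred = [classes[j] for j in proba.argmax(axis=1)]
        cm = confusion_matrix(y[te], pred, classes)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            folds.append(FoldResult(cm=cm, metrics=metrics(cm), test_indices=te))
        all_test.append(te)
    covered = np.concatenate(all_test)
    assert covered.size == len(samples) and np.unique(covered).size == len(samples)
    mean = {
        key: float(np.mean([f.metrics[key] for f in folds]))
        for key in ("accuracy", "precision", "recall", "f1")
    }
    return EvalReport(folds=folds, mean=mean, modality=modality, seed=seed)


def _shapes_of(sample: RPSample):
    if isinstance(sample.x, tuple):
        return [sample.x[0].shape, sample.x[1].shape]
    return sample.x.shape


def report(reports: list[EvalReport]) -> pd.DataFrame:
    """Aggregate per-subject reports into per-modality mean/max tables."""
    if not reports:
        raise ValueError("need at least one EvalReport")
    rows = []
    for r in reports:
        rows.append({"modality": r.modality or "unknown", **r.mean})
    df = pd.DataFrame(rows)
    agg = df.groupby("modality").agg(["mean", "max"])
    empty = [m for m in df["modality"].unique() if df[df.modality == m].empty]
    for m in empty:  # pragma: no cover - defensive
        warnings.warn(f"modality {m} has no reports; omitted")
    return agg
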
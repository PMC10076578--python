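"""Evaluation protocol: repeated stratified 10-fold cross-validation.

Subjects (never single utterances) are split into k class-proportional
folds, so all nine utterances of a subject stay on one side of each split.
Metrics are computed from the subject-level confusion matrix with the
depressed class positive:

    accuracy = (TP + TN) / (TP + FN + FP + TN)
    F1-D     = 2 TP / (2 TP + FP + FN)
    F1-H     = 2 TN / (2 TN + FP + FN)

Each repetition reshuffles the folds under a new seed; a repetition's score
is the unweighted mean of its k test folds and the final score the mean over
repetitions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold

from voxscreen.errors import ArgumentError

POSITIVE_LABEL = "depressed"


@dataclass
class FoldPlan:
    folds: list  # list of lists of subject ids
    seed: int

    def __post_init__(self) -> None:
        flat = [s for f in self.folds for s in f]
        if len(flat) != len(set(flat)):
            raise ArgumentError("folds overlap")


def stratified_folds(labels: dict[str, str], k: int = 10, seed: int = 0) -> FoldPlan:
    """Split subjects into k class-proportional folds (counts differ by <= 1).

    ``labels`` maps subject id -> class label. Each class must have at least
    k members.
    """
    subjects = sorted(labels)
    y = np.array([labels[s] for s in subjects])
    for cls in np.unique(y):
        if (y == cls).sum() < k:
            raise ArgumentError(f"class {cls!r} has fewer than k={k} subjects")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [[subjects[i] for i in te] for _, te in skf.split(np.zeros(len(y)), y)]
    return FoldPlan(folds=folds, seed=seed)


@dataclass
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ArgumentError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionMatrix":
        yt = np.asarray(y_true).astype(int)
        yp = np.asarray(y_pred).astype(int)
        return cls(
            tp=int(((yt == 1) & (yp == 1)).sum()),
            fn=int(((yt == 1) & (yp == 0)).sum()),
            fp=int(((yt == 0) & (yp == 1)).sum()),
            tn=int(((yt == 0) & (yp == 0)).sum()),
        )


def metrics(cm: ConfusionMatrix) -> dict:
    """accuracy, F1-D, F1-H from a confusion matrix; 0/0 reported as 0 + flag."""
    if cm.total <= 0:
        raise ArgumentError("empty confusion matrix")
    flags = []

    def safe(num: float, den: float, name: str) -> float:
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    acc = (cm.tp + cm.tn) / cm.total
    f1_d = safe(2.0 * cm.tp, 2.0 * cm.tp + cm.fp + cm.fn, "F1-D")
    f1_h = safe(2.0 * cm.tn, 2.0 * cm.tn + cm.fp + cm.fn, "F1-H")
    return {"accuracy": float(acc), "f1_d": float(f1_d), "f1_h": float(f1_h), "undefined": flags}


@dataclass
class EvalReport:
    """Per-repetition, per-fold results and their aggregates."""

    repetitions: list = field(default_factory=list)  # [{fold_metrics: [...], mean: {...}}]
    aggregate: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=float))


def _mean_over(dicts: list[dict]) -> dict:
    keys = ("accuracy", "f1_d", "f1_h")
    return {k: float(np.mean([d[k] for d in dicts])) for k in keys}


def repeated_cv(
    pipeline_factory,
    table,
    repetitions: int = 100,
    k: int = 10,
    base_seed: int = 0,
    config_note: dict | None = None,
) -> EvalReport:
    """Repeated stratified k-fold CV of a subject-level pipeline.

    ``pipeline_factory(seed)`` must return an object with
    ``fit(table, train_subjects)`` and ``predict(table, test_subjects)``
    (predictions carry a ``label`` column). Repetition r uses seed
    ``base_seed + r``; the full two-stage ensemble is refit from scratch in
    every fold.
    """
    report = EvalReport(config={"repetitions": repetitions, "k": k, "base_seed": base_seed})
    if config_note:
        report.config.update(config_note)
    for r in range(repetitions):
        seed = base_seed + r
        plan = stratified_folds(table.labels, k=k, seed=seed)
        fold_metrics = []
        for i, test_subjects in enumerate(plan.folds):
            train_subjects = [s for f in plan.folds for s in f if f is not plan.folds[i]]
            pipe = pipeline_factory(seed)
            pipe.fit(table, train_subjects)
            preds = pipe.predict(table, test_subjects)
            y_true = table.label_array(test_subjects)
            y_pred = (preds["label"].to_numpy() == POSITIVE_LABEL).astype(int)
            m = metrics(ConfusionMatrix.from_predictions(y_true, y_pred))
            m["fold"] = i
            fold_metrics.append(m)
        rep = {"seed": seed, "fold_metrics": fold_metrics, "mean": _mean_over(fold_metrics)}
        report.repetitions.append(rep)
    report.aggregate = _mean_over([rep["mean"] for rep in report.repetitions])
    return report
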
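"""Multi-task stacked ensemble over speaker embeddings.

Per (speech task, embedding type) an SVM with a Gaussian kernel is fitted on
subject embeddings; its positive-class (depressed) probability p_i(j) for
subject i on task j becomes one meta-feature. The nine per-task
probabilities — concatenated across embedding types when several are fused —
form the subject's meta-feature vector, classified by an MLP meta-learner.

Meta-features for training subjects are produced out-of-fold by default (an
inner 5-fold split, so no subject is scored by a task model trained on
itself); an ``in_sample`` protocol is available as a fidelity switch. Two
literature comparison baselines are included: cosine-similarity nearest
centroid with majority voting over the nine tasks, and paired-t-test task
selection followed by SVM stacking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from voxscreen.errors import ArgumentError, DataCompletenessError, NotFittedError
from voxscreen.types import VALID_TAGS, SpeakerEmbedding

POSITIVE_LABEL = "depressed"
NEGATIVE_LABEL = "healthy"

SVM_GRID = {"C": [0.1, 1, 10, 100], "gamma": ["scale", 1e-3, 1e-2, 1e-1]}
RF_GRID = {"n_estimators": [100, 300, 500]}
MLP_GRID = {"hidden_layer_sizes": [(16,), (32,), (64,), (32, 16)], "alpha": [1e-4, 1e-3]}


class EmbeddingTable:
    """(subject, task, tag) -> embedding vector, plus subject labels."""

    def __init__(self) -> None:
        self._vectors: dict[tuple[str, int, str], np.ndarray] = {}
        self.labels: dict[str, str] = {}
        self._tag_order: list[str] = []

    def add(self, emb: SpeakerEmbedding, label: str | None = None) -> None:
        if emb.tag not in VALID_TAGS:
            raise ArgumentError(f"unknown embedding tag {emb.tag!r}")
        key = (emb.subject_id, int(emb.task_id), emb.tag)
        self._vectors[key] = emb.vector
        if emb.tag not in self._tag_order:
            self._tag_order.append(emb.tag)
        if label is not None:
            self.labels[emb.subject_id] = label

    def get(self, subject: str, task: int, tag: str) -> np.ndarray:
        try:
            return self._vectors[(subject, task, tag)]
        except KeyError:
            raise DataCompletenessError(f"missing embedding for ({subject}, task {task}, {tag})")

    @property
    def subjects(self) -> list[str]:
        return sorted({k[0] for k in self._vectors})

    @property
    def tasks(self) -> list[int]:
        return sorted({k[1] for k in self._vectors})

    @property
    def tags(self) -> list[str]:
        return list(self._tag_order)

    def matrix(self, task: int, tag: str, subjects: list[str]) -> np.ndarray:
        return np.stack([self.get(s, task, tag) for s in subjects])

    def label_array(self, subjects: list[str]) -> np.ndarray:
        missing = [s for s in subjects if s not in self.labels]
        if missing:
            raise DataCompletenessError(f"subjects without labels: {missing[:3]}")
        return np.array([1 if self.labels[s] == POSITIVE_LABEL else 0 for s in subjects])

    def validate_complete(self) -> None:
        for s in self.subjects:
            for t in self.tasks:
                for g in self.tags:
                    self.get(s, t, g)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for (subj, task, tag), vec in sorted(self._vectors.items()):
            row = {"subject": subj, "task": task, "tag": tag, "label": self.labels.get(subj, "NA")}
            row.update({f"v{i}": v for i, v in enumerate(vec)})
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "EmbeddingTable":
        table = cls()
        vcols = sorted([c for c in df.columns if c.startswith("v")], key=lambda c: int(c[1:]))
        for _, row in df.iterrows():
            emb = SpeakerEmbedding(
                vector=row[vcols].to_numpy(dtype=np.float64),
                subject_id=str(row["subject"]),
                task_id=int(row["task"]),
                tag=str(row["tag"]),
            )
            label = str(row.get("label", "NA"))
            table.add(emb, label if label in (POSITIVE_LABEL, NEGATIVE_LABEL) else None)
        return table


def _check_two_classes(y: np.ndarray, minimum: int = 2) -> None:
    counts = np.bincount(y, minlength=2)
    if counts.min() < minimum:
        raise ArgumentError(f"need >= {minimum} subjects per class, got counts {counts.tolist()}")


def _fit_one(X: np.ndarray, y: np.ndarray, kind: str, grid: dict, seed: int):
    """Inner grid search on training rows only; returns (fitted probabilistic model, best params)."""
    n_min = int(np.bincount(y, minlength=2).min())
    cv = StratifiedKFold(n_splits=min(3, n_min), shuffle=True, random_state=seed)
    if kind == "svm":
        gs = GridSearchCV(SVC(kernel="rbf"), grid, cv=cv, refit=False)
        gs.fit(X, y)
        best = gs.best_params_
        model = SVC(kernel="rbf", probability=True, random_state=seed, **best)
    elif kind == "rf":
        gs = GridSearchCV(RandomForestClassifier(random_state=seed), grid, cv=cv, refit=False)
        gs.fit(X, y)
        best = gs.best_params_
        model = RandomForestClassifier(random_state=seed, **best)
    else:
        raise ArgumentError(f"unknown classifier kind {kind!r}; expected 'svm' or 'rf'")
    model.fit(X, y)
    return model, best


@dataclass
class TaskClassifierSet:
    """Per-(task, tag) classifiers plus what is needed to re-fit them out-of-fold."""

    models: dict = field(default_factory=dict)  # (tag, task) -> fitted model
    best_params: dict = field(default_factory=dict)
    train_subjects: list = field(default_factory=list)
    train_labels: np.ndarray | None = None
    tags: list = field(default_factory=list)
    tasks: list = field(default_factory=list)
    kind: str = "svm"
    seed: int = 0


def train_task_classifiers(
    table: EmbeddingTable,
    train_subjects: list[str] | None = None,
    kind: str = "svm",
    grid: dict | None = None,
    seed: int = 0,
    tags: list[str] | None = None,
) -> TaskClassifierSet:
    """One probabilistic classifier per (task, embedding tag)."""
    subjects = list(train_subjects) if train_subjects is not None else table.subjects
    tags = list(tags) if tags is not None else table.tags
    y = table.label_array(subjects)
    _check_two_classes(y)
    grid = grid if grid is not None else (SVM_GRID if kind == "svm" else RF_GRID)
    out = TaskClassifierSet(
        train_subjects=subjects, train_labels=y, tags=tags, tasks=table.tasks, kind=kind, seed=seed
    )
    for tag in tags:
        for task in table.tasks:
            X = table.matrix(task, tag, subjects)
            model, best = _fit_one(X, y, kind, grid, seed)
            out.models[(tag, task)] = model
            out.best_params[(tag, task)] = best
    return out


def _refit_with_params(kind: str, best: dict, seed: int):
    if kind == "svm":
        return SVC(kernel="rbf", probability=True, random_state=seed, **best)
    return RandomForestClassifier(random_state=seed, **best)


def build_meta_features(
    models: TaskClassifierSet,
    table: EmbeddingTable,
    subjects: list[str],
    protocol: str = "out_of_fold",
    seed: int | None = None,
) -> pd.DataFrame:
    """n_subjects x (n_tasks * n_tags) matrix of positive-class probabilities.

    Column order is tag-major, task-minor. Under ``out_of_fold``, rows for
    subjects that were in the models' training partition come from an inner
    5-fold split (task models re-fitted with the selected hyperparameters);
    all other subjects are scored by the full-partition models.
    """
    if protocol not in ("out_of_fold", "in_sample"):
        raise ArgumentError(f"unknown protocol {protocol!r}")
    seed = models.seed if seed is None else seed
    cols = [f"{tag}_task{task}" for tag in models.tags for task in models.tasks]
    meta = pd.DataFrame(np.nan, index=list(subjects), columns=cols)

    train_set = [s for s in subjects if s in set(models.train_subjects)]
    test_set = [s for s in subjects if s not in set(models.train_subjects)]

    for tag in models.tags:
        for task in models.tasks:
            col = f"{tag}_task{task}"
            model = models.models[(tag, task)]
            if test_set:
                X = table.matrix(task, tag, test_set)
                meta.loc[test_set, col] = model.predict_proba(X)[:, 1]
            if train_set and protocol == "in_sample":
                X = table.matrix(task, tag, train_set)
                meta.loc[train_set, col] = model.predict_proba(X)[:, 1]

    if train_set and protocol == "out_of_fold":
        order = list(models.train_subjects)
        y_all = models.train_labels
        n_min = int(np.bincount(y_all, minlength=2).min())
        skf = StratifiedKFold(n_splits=min(5, n_min), shuffle=True, random_state=seed)
        wanted = set(train_set)
        for tr_idx, te_idx in skf.split(np.zeros(len(order)), y_all):
            fold_tr = [order[i] for i in tr_idx]
            fold_te = [order[i] for i in te_idx if order[i] in wanted]
            if not fold_te:
                continue
            y_tr = y_all[tr_idx]
            for tag in models.tags:
                for task in models.tasks:
                    m = _refit_with_params(models.kind, models.best_params[(tag, task)], seed)
                    m.fit(table.matrix(task, tag, fold_tr), y_tr)
                    probs = m.predict_proba(table.matrix(task, tag, fold_te))[:, 1]
                    meta.loc[fold_te, f"{tag}_task{task}"] = probs

    if meta.isna().any().any():
        raise DataCompletenessError("meta-feature matrix has unscored entries")
    return meta.clip(0.0, 1.0)


def train_meta_learner(
    meta: pd.DataFrame,
    labels: np.ndarray,
    grid: dict | None = None,
    seed: int = 0,
    max_iter: int = 500,
) -> GridSearchCV:
    """MLP meta-learner selected by grid search with inner CV on training rows."""
    y = np.asarray(labels)
    _check_two_classes(y)
    grid = grid if grid is not None else MLP_GRID
    n_min = int(np.bincount(y, minlength=2).min())
    cv = StratifiedKFold(n_splits=min(3, n_min), shuffle=True, random_state=seed)
    gs = GridSearchCV(
        MLPClassifier(max_iter=max_iter, random_state=seed), grid, cv=cv, refit=True
    )
    gs.fit(meta.to_numpy(), y)
    return gs


@dataclass
class EnsembleModel:
    """Fitted two-stage ensemble: task classifiers + MLP meta-learner."""

    task_set: TaskClassifierSet
    meta_learner: GridSearchCV
    protocol: str = "out_of_fold"


def predict(ensemble: EnsembleModel, table: EmbeddingTable, subjects: list[str]) -> pd.DataFrame:
    """Per-subject probability and hard label at threshold 0.5."""
    if ensemble.meta_learner is None or ensemble.task_set is None:
        raise NotFittedError("ensemble is not fitted")
    meta = build_meta_features(ensemble.task_set, table, subjects, protocol="in_sample")
    # non-training subjects are always scored by full-partition models; the
    # in_sample path is only reached if a training subject is re-queried.
    probs = ensemble.meta_learner.predict_proba(meta.to_numpy())[:, 1]
    return pd.DataFrame(
        {
            "subject": subjects,
            "probability": probs,
            "label": np.where(probs >= 0.5, POSITIVE_LABEL, NEGATIVE_LABEL),
        }
    )


class EnsemblePipeline:
    """fit/predict wrapper used by the cross-validation driver."""

    def __init__(
        self,
        tags: list[str] | None = None,
        kind: str = "svm",
        task_grid: dict | None = None,
        meta_grid: dict | None = None,
        protocol: str = "out_of_fold",
        seed: int = 0,
        mlp_max_iter: int = 500,
    ):
        self.tags = tags
        self.kind = kind
        self.task_grid = task_grid
        self.meta_grid = meta_grid
        self.protocol = protocol
        self.seed = seed
        self.mlp_max_iter = mlp_max_iter
        self.model: EnsembleModel | None = None

    def fit(self, table: EmbeddingTable, train_subjects: list[str]) -> "EnsemblePipeline":
        task_set = train_task_classifiers(
            table, train_subjects, kind=self.kind, grid=self.task_grid, seed=self.seed, tags=self.tags
        )
        meta = build_meta_features(task_set, table, train_subjects, protocol=self.protocol, seed=self.seed)
        y = table.label_array(train_subjects)
        learner = train_meta_learner(
            meta, y, grid=self.meta_grid, seed=self.seed, max_iter=self.mlp_max_iter
        )
        self.model = EnsembleModel(task_set=task_set, meta_learner=learner, protocol=self.protocol)
        return self

    def predict(self, table: EmbeddingTable, subjects: list[str]) -> pd.DataFrame:
        if self.model is None:
            raise NotFittedError("call fit before predict")
        return predict(self.model, table, subjects)


def baseline_vote(
    table: EmbeddingTable,
    train_subjects: list[str],
    test_subjects: list[str],
    tag: str | None = None,
) -> pd.DataFrame:
    """Cosine nearest-centroid per task, then majority vote over the 9 tasks."""
    tag = tag if tag is not None else table.tags[0]
    y_tr = table.label_array(train_subjects)
    if y_tr.min() == y_tr.max():
        raise ArgumentError("training partition contains a single class")
    votes = np.zeros((len(test_subjects), len(table.tasks)), dtype=int)
    for j, task in enumerate(table.tasks):
        Xtr = table.matrix(task, tag, train_subjects)
        cen = {c: Xtr[y_tr == c].mean(axis=0) for c in (0, 1)}
        Xte = table.matrix(task, tag, test_subjects)

        def cos(a, b):
            return a @ b / (np.linalg.norm(a, axis=-1) * np.linalg.norm(b) + 1e-12)

        votes[:, j] = (cos(Xte, cen[1]) > cos(Xte, cen[0])).astype(int)
    majority = votes.sum(axis=1) * 2 > len(table.tasks)
    return pd.DataFrame(
        {
            "subject": test_subjects,
            "label": np.where(majority, POSITIVE_LABEL, NEGATIVE_LABEL),
            "votes_depressed": votes.sum(axis=1),
        }
    )


def baseline_ttest_stack(
    table: EmbeddingTable,
    train_subjects: list[str],
    test_subjects: list[str],
    alpha: float = 0.05,
    n_folds: int = 5,
    seed: int = 0,
    tag: str | None = None,
) -> tuple[pd.DataFrame, list[int]]:
    """Paired-t-test task selection, then SVM stacking of retained tasks.

    Per-task CV accuracies on the training partition are compared with the
    best task's by a one-sided paired t-test; tasks significantly worse
    (p < alpha) are dropped. Returns (predictions, retained task ids).
    """
    if n_folds < 2:
        raise ArgumentError("need at least 2 folds for the paired t-test")
    tag = tag if tag is not None else table.tags[0]
    y = table.label_array(train_subjects)
    _check_two_classes(y, minimum=n_folds)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    tasks = table.tasks
    acc = np.zeros((len(tasks), n_folds))
    oof = {t: np.zeros(len(train_subjects)) for t in tasks}
    for f, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        sub_tr = [train_subjects[i] for i in tr]
        sub_te = [train_subjects[i] for i in te]
        for j, task in enumerate(tasks):
            m = SVC(kernel="rbf", probability=True, random_state=seed)
            m.fit(table.matrix(task, tag, sub_tr), y[tr])
            p = m.predict_proba(table.matrix(task, tag, sub_te))[:, 1]
            oof[task][te] = p
            acc[j, f] = float(np.mean((p >= 0.5).astype(int) == y[te]))

    best = int(np.argmax(acc.mean(axis=1)))
    retained = []
    for j, task in enumerate(tasks):
        if j == best:
            retained.append(task)
            continue
        t_stat, p_val = sps.ttest_rel(acc[best], acc[j], alternative="greater")
        if not np.isfinite(p_val) or p_val >= alpha:
            retained.append(task)
    retained.sort()

    Xtr = np.column_stack([oof[t] for t in retained])
    stacker = SVC(kernel="rbf", probability=True, random_state=seed)
    stacker.fit(Xtr, y)

    full = {t: SVC(kernel="rbf", probability=True, random_state=seed) for t in retained}
    for t in retained:
        full[t].fit(table.matrix(t, tag, train_subjects), y)
    Xte = np.column_stack(
        [full[t].predict_proba(table.matrix(t, tag, test_subjects))[:, 1] for t in retained]
    )
    probs = stacker.predict_proba(Xte)[:, 1]
    preds = pd.DataFrame(
        {
            "subject": test_subjects,
            "probability": probs,
            "label": np.where(probs >= 0.5, POSITIVE_LABEL, NEGATIVE_LABEL),
        }
    )
    return preds, retained
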
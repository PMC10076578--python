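"""Multi-task stacked ensemble: meta-features, meta-learner, baselines."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from voxscreen.ensemble import (
    EmbeddingTable,
    EnsemblePipeline,
    baseline_ttest_stack,
    baseline_vote,
    build_meta_features,
    train_meta_learner,
    train_task_classifiers,
)
from voxscreen.errors import ArgumentError, DataCompletenessError, NotFittedError
from voxscreen.types import SpeakerEmbedding


def make_table(
    n_pos=10,
    n_neg=10,
    n_tasks=9,
    tags=("T_m",),
    dim=8,
    separation=4.0,
    seed=0,
    identical=False,
):
    """Synthetic embedding table: class means separated by ``separation``."""
    rng = np.random.default_rng(seed)
    table = EmbeddingTable()
    directions = {
        (tag, task): rng.normal(size=dim) / np.sqrt(dim) for tag in tags for task in range(1, n_tasks + 1)
    }
    for i in range(n_pos + n_neg):
        label = "depressed" if i < n_pos else "healthy"
        sign = 1.0 if label == "depressed" else -1.0
        for tag in tags:
            for task in range(1, n_tasks + 1):
                if identical:
                    vec = np.ones(dim)
                else:
                    vec = rng.normal(size=dim) + sign * separation / 2 * directions[(tag, task)]
                table.add(
                    SpeakerEmbedding(vector=vec, subject_id=f"s{i:03d}", task_id=task, tag=tag),
                    label=label,
                )
    return table


class TestEmbeddingTable:
    def test_missing_entry_raises_completeness_error(self):
        table = make_table(n_pos=2, n_neg=2, n_tasks=3)
        with pytest.raises(DataCompletenessError):
            table.get("s000", 7, "T_m")

    def test_roundtrip_through_dataframe(self):
        table = make_table(n_pos=3, n_neg=3, n_tasks=2)
        df = table.to_dataframe()
        back = EmbeddingTable.from_dataframe(df)
        assert back.subjects == table.subjects
        np.testing.assert_allclose(back.get("s001", 2, "T_m"), table.get("s001", 2, "T_m"))
        assert back.labels == table.labels


class TestTaskClassifiers:
    def test_separable_embeddings_perfect_in_sample(self):
        table = make_table(separation=20.0, n_tasks=4)
        models = train_task_classifiers(table, seed=0)
        subjects = table.subjects
        y = table.label_array(subjects)
        for task in table.tasks:
            X = table.matrix(task, "T_m", subjects)
            acc = (models.models[("T_m", task)].predict(X) == y).mean()
            assert acc == 1.0

    def test_identical_embeddings_emit_prior_probability(self):
        table = make_table(n_pos=14, n_neg=6, n_tasks=2, identical=True)
        models = train_task_classifiers(table, seed=0)
        X = table.matrix(1, "T_m", table.subjects)
        p = models.models[("T_m", 1)].predict_proba(X)[:, 1]
        assert np.all(np.abs(p - 0.7) <= 0.05)

    def test_rf_selected_trees_member_of_grid(self):
        table = make_table(n_pos=8, n_neg=8, n_tasks=2, separation=3.0)
        grid = {"n_estimators": [10, 30]}
        models = train_task_classifiers(table, kind="rf", grid=grid, seed=0)
        for best in models.best_params.values():
            assert best["n_estimators"] in grid["n_estimators"]

    def test_single_class_rejected(self):
        table = make_table(n_pos=6, n_neg=0, n_tasks=2)
        with pytest.raises(ArgumentError):
            train_task_classifiers(table, seed=0)


class TestMetaFeatures:
    def test_shape_single_tag(self):
        table = make_table(n_pos=5, n_neg=5, n_tasks=9)
        models = train_task_classifiers(table, seed=0)
        meta = build_meta_features(models, table, table.subjects, protocol="in_sample")
        assert meta.shape == (10, 9)
        assert ((meta >= 0) & (meta <= 1)).all().all()

    def test_three_tags_fused_block_order(self):
        tags = ("R_m", "R_p", "R_f")
        table = make_table(n_pos=5, n_neg=5, n_tasks=9, tags=tags)
        models = train_task_classifiers(table, seed=0, tags=list(tags))
        meta = build_meta_features(models, table, table.subjects, protocol="in_sample")
        assert meta.shape == (10, 27)
        assert list(meta.columns[:9]) == [f"R_m_task{j}" for j in range(1, 10)]
        assert list(meta.columns[9:18]) == [f"R_p_task{j}" for j in range(1, 10)]
        assert list(meta.columns[18:]) == [f"R_f_task{j}" for j in range(1, 10)]

    def test_separable_in_sample_probabilities_confident(self):
        table = make_table(separation=20.0, n_tasks=3)
        models = train_task_classifiers(table, seed=0)
        meta = build_meta_features(models, table, table.subjects, protocol="in_sample")
        dep = [s for s in table.subjects if table.labels[s] == "depressed"]
        assert meta.loc[dep].to_numpy().mean() > 0.9

    def test_out_of_fold_scores_every_training_subject(self):
        table = make_table(n_pos=10, n_neg=10, n_tasks=3)
        models = train_task_classifiers(table, seed=0)
        meta = build_meta_features(models, table, table.subjects, protocol="out_of_fold")
        assert not meta.isna().any().any()

    def test_unknown_protocol_rejected(self):
        table = make_table(n_pos=3, n_neg=3, n_tasks=2)
        models = train_task_classifiers(table, seed=0)
        with pytest.raises(ArgumentError):
            build_meta_features(models, table, table.subjects, protocol="loo")


class TestMetaLearner:
    def test_label_leak_column_learned_perfectly(self):
        rng = np.random.default_rng(0)
        y = np.array([1] * 20 + [0] * 20)
        meta = pd.DataFrame(rng.uniform(size=(40, 9)), columns=[f"T_m_task{j}" for j in range(1, 10)])
        meta.iloc[:, 0] = y
        gs = train_meta_learner(meta.iloc[:30], y[:30], seed=0)
        held = gs.predict(meta.iloc[30:].to_numpy())
        assert (held == y[30:]).mean() == 1.0

    def test_random_meta_features_near_chance(self):
        rng = np.random.default_rng(1)
        y = rng.permutation(np.array([1] * 50 + [0] * 50))
        meta = pd.DataFrame(rng.uniform(size=(100, 9)))
        gs = train_meta_learner(meta.iloc[:70], y[:70], seed=0)
        acc = (gs.predict(meta.iloc[70:].to_numpy()) == y[70:]).mean()
        assert 0.35 <= acc <= 0.65

    def test_deterministic_given_seed(self):
        table = make_table(n_pos=8, n_neg=8, n_tasks=3, separation=2.0)
        runs = []
        for _ in range(2):
            models = train_task_classifiers(table, seed=4)
            meta = build_meta_features(models, table, table.subjects, protocol="out_of_fold")
            gs = train_meta_learner(meta, table.label_array(table.subjects), seed=4)
            runs.append((gs.best_params_, gs.predict(meta.to_numpy())))
        assert runs[0][0] == runs[1][0]
        np.testing.assert_array_equal(runs[0][1], runs[1][1])


class TestPipeline:
    def test_predict_before_fit_rejected(self):
        pipe = EnsemblePipeline(seed=0)
        with pytest.raises(NotFittedError):
            pipe.predict(make_table(n_pos=2, n_neg=2, n_tasks=2), ["s000"])

    def test_no_leakage_from_test_labels(self):
        """Training artifacts must be identical whatever the test labels are."""
        table = make_table(n_pos=12, n_neg=12, n_tasks=3, separation=3.0)
        subjects = table.subjects
        train, test = subjects[:16], subjects[16:]
        preds = []
        for flip in (False, True):
            t2 = make_table(n_pos=12, n_neg=12, n_tasks=3, separation=3.0)
            if flip:
                for s in test:
                    t2.labels[s] = (
                        "healthy" if t2.labels[s] == "depressed" else "depressed"
                    )
            pipe = EnsemblePipeline(seed=0).fit(t2, train)
            preds.append(pipe.predict(t2, test)["probability"].to_numpy())
        np.testing.assert_array_equal(preds[0], preds[1])

    def test_fusing_noise_tag_is_robust(self):
        """Adding a pure-noise embedding type degrades accuracy by < 0.05."""
        rng = np.random.default_rng(5)
        accs = {}
        for tags in (["T_m"], ["T_m", "T_f"]):
            table = make_table(n_pos=20, n_neg=20, n_tasks=9, tags=("T_m",), separation=5.0, seed=7)
            if "T_f" in tags:
                for s in list(table.subjects):
                    for task in range(1, 10):
                        table.add(
                            SpeakerEmbedding(
                                vector=rng.normal(size=8), subject_id=s, task_id=task, tag="T_f"
                            )
                        )
            subjects = table.subjects
            train, test = subjects[::2], subjects[1::2]
            pipe = EnsemblePipeline(
                tags=tags,
                seed=0,
                task_grid={"C": [1, 10], "gamma": ["scale"]},
                meta_grid={"hidden_layer_sizes": [(16,)], "alpha": [1e-3]},
            ).fit(table, train)
            preds = pipe.predict(table, test)
            y = table.label_array(test)
            accs[tuple(tags)] = ((preds["label"].to_numpy() == "depressed").astype(int) == y).mean()
        assert accs[("T_m",)] - accs[("T_m", "T_f")] < 0.05


class TestBaselineVote:
    def test_unanimous_and_majority_counting(self):
        table = make_table(n_pos=6, n_neg=6, n_tasks=9, separation=50.0)
        subjects = table.subjects
        train, test = subjects[:8], subjects[8:]
        preds = baseline_vote(table, train, test)
        y = {s: table.labels[s] for s in test}
        for _, row in preds.iterrows():
            assert row["label"] == y[row["subject"]]
            assert row["votes_depressed"] in (0, 9)

    def test_agrees_with_naive_reimplementation(self):
        table = make_table(n_pos=10, n_neg=10, n_tasks=9, separation=2.0, seed=3)
        subjects = table.subjects
        train, test = subjects[:14], subjects[14:]
        preds = baseline_vote(table, train, test)
        y_tr = table.label_array(train)
        for _, row in preds.iterrows():
            votes = 0
            for task in table.tasks:
                Xtr = table.matrix(task, "T_m", train)
                c1 = Xtr[y_tr == 1].mean(axis=0)
                c0 = Xtr[y_tr == 0].mean(axis=0)
                v = table.get(row["subject"], task, "T_m")

                def cos(a, b):
                    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b) + 1e-12))

                votes += int(cos(v, c1) > cos(v, c0))
            assert votes == row["votes_depressed"]
            assert (votes > 4.5) == (row["label"] == "depressed")

    def test_empty_training_class_rejected(self):
        table = make_table(n_pos=6, n_neg=6, n_tasks=2)
        healthy_only = [s for s in table.subjects if table.labels[s] == "healthy"]
        with pytest.raises(ArgumentError):
            baseline_vote(table, healthy_only, table.subjects[:2])


class TestBaselineTtest:
    def test_indistinguishable_tasks_all_retained(self):
        """Tasks carrying the same embeddings tie exactly; nothing is dropped."""
        rng = np.random.default_rng(11)
        table = EmbeddingTable()
        for i in range(30):
            label = "depressed" if i < 15 else "healthy"
            sign = 1.0 if i < 15 else -1.0
            vec = rng.normal(size=6) + sign * np.array([1.5, 0, 0, 0, 0, 0])
            for task in range(1, 10):
                table.add(
                    SpeakerEmbedding(vector=vec, subject_id=f"s{i:03d}", task_id=task, tag="T_m"),
                    label=label,
                )
        subjects = table.subjects
        _, retained = baseline_ttest_stack(table, subjects[:24], subjects[24:], alpha=0.05, seed=0)
        assert retained == list(range(1, 10))

    def test_alpha_zero_never_rejects(self):
        table = make_table(n_pos=15, n_neg=15, n_tasks=5, separation=1.0, seed=12)
        subjects = table.subjects
        _, retained = baseline_ttest_stack(table, subjects[:24], subjects[24:], alpha=0.0, seed=0)
        assert retained == list(range(1, 6))

    def test_perfect_task_retained_among_noise(self):
        rng = np.random.default_rng(13)
        table = EmbeddingTable()
        for i in range(30):
            label = "depressed" if i < 15 else "healthy"
            sign = 1.0 if i < 15 else -1.0
            for task in range(1, 6):
                vec = rng.normal(size=6)
                if task == 3:  # only task 3 carries signal
                    vec = vec + sign * np.array([6.0, 0, 0, 0, 0, 0])
                table.add(
                    SpeakerEmbedding(vector=vec, subject_id=f"s{i:03d}", task_id=task, tag="T_m"),
                    label=label,
                )
        subjects = table.subjects
        _, retained = baseline_ttest_stack(table, subjects[:24], subjects[24:], alpha=0.05, seed=0)
        assert 3 in retained
        assert len(retained) < 5  # chance-level tasks significantly worse

    def test_too_few_folds_rejected(self):
        table = make_table(n_pos=8, n_neg=8, n_tasks=2)
        with pytest.raises(ArgumentError):
            baseline_ttest_stack(table, table.subjects[:12], table.subjects[12:], n_folds=1)
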
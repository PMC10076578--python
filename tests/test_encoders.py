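"""Neural encoders: pooling, gradients, architecture conformance, training."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from voxscreen.encoders import EncoderSpec, build_encoder
from voxscreen.errors import ArgumentError
from voxscreen.nnet import AdamW, StatsPool, stats_pool, softmax_cross_entropy
from voxscreen.pretrain import TrainingConfig, extract_embedding, featurize_manifest, train_extractor
from voxscreen.synth import SpeakerProfile, render_utterance
from voxscreen.audio import write_wav
from voxscreen.features import FrameFeatures


class TestStatsPool:
    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            T, D = int(rng.integers(1, 60)), int(rng.integers(1, 20))
            x = rng.normal(size=(T, D))
            out = stats_pool(x)
            mean_ref = np.array([sum(x[t, d] for t in range(T)) / T for d in range(D)])
            std_ref = np.array(
                [
                    max(np.sqrt(sum((x[t, d] - mean_ref[d]) ** 2 for t in range(T)) / T), 1e-5)
                    for d in range(D)
                ]
            )
            np.testing.assert_allclose(out[:D], mean_ref, atol=1e-6)
            np.testing.assert_allclose(out[D:], std_ref, atol=1e-6)

    def test_permutation_invariant_over_time(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(37, 16))
        np.testing.assert_allclose(stats_pool(x), stats_pool(x[rng.permutation(37)]), atol=1e-12)

    def test_constant_rows_hit_std_floor(self):
        x = np.full((10, 4), 2.5)
        out = stats_pool(x)
        np.testing.assert_allclose(out[:4], 2.5)
        np.testing.assert_allclose(out[4:], 1e-5)

    def test_single_frame(self):
        x = np.array([[1.0, -2.0, 3.0]])
        out = stats_pool(x)
        np.testing.assert_allclose(out, [1.0, -2.0, 3.0, 1e-5, 1e-5, 1e-5])

    def test_empty_input_rejected(self):
        with pytest.raises(ArgumentError):
            stats_pool(np.empty((0, 4)))


class TestArchitecture:
    def test_tdnn_receptive_field_is_15(self):
        assert EncoderSpec.tdnn().receptive_field == 15
        assert EncoderSpec.tiny_tdnn().receptive_field == 15

    def test_all_zero_contexts_receptive_field_1(self):
        spec = EncoderSpec(
            kind="tdnn", tdnn_contexts=([0], [0], [0], [0], [0]), tdnn_dims=(8, 8, 8, 8, 8)
        )
        assert spec.receptive_field == 1

    def test_resnet_shape_trace_matches_schedule(self):
        """F=60, T=200: stride-2 stages halve both axes (ceil), ending at 8 x 25."""
        trace = EncoderSpec.resnet34().resnet_shape_trace(200)
        assert trace[0] == ("conv1", 32, 60, 200)
        assert trace[1] == ("resblock1", 32, 60, 200)
        assert trace[2] == ("resblock2", 64, 30, 100)
        assert trace[3] == ("resblock3", 128, 15, 50)
        assert trace[4] == ("resblock4", 256, 8, 25)

    def test_resnet_default_block_layout(self):
        spec = EncoderSpec.resnet34()
        assert spec.resnet_blocks == (3, 4, 6, 3)
        assert spec.resnet_channels == (32, 64, 128, 256)
        assert spec.first_kernel == 7 and spec.kernel == 3

    def test_inconsistent_spec_rejected(self):
        with pytest.raises(ArgumentError):
            EncoderSpec(kind="resnet34", resnet_blocks=(1, 1), resnet_channels=(4, 8, 16))
        with pytest.raises(ArgumentError):
            EncoderSpec(kind="tdnn", tdnn_contexts=([0],), tdnn_dims=(8, 8))

    def test_forward_shapes_actually_match_trace(self):
        spec = EncoderSpec.tiny_resnet()
        enc = build_encoder(spec, seed=0)
        x = np.random.default_rng(0).normal(size=(1, 40, 60))
        enc._trunk(x)
        _, C, Fr, T = enc._trunk_shape
        name, c_exp, f_exp, t_exp = spec.resnet_shape_trace(40)[-1]
        assert (C, Fr, T) == (c_exp, f_exp, t_exp)


def _numeric_grad_check(enc, x, y, picks):
    _, d = softmax_cross_entropy(enc.forward_train(x), y)
    for p in enc.params():
        p.grad[...] = 0.0
    enc.backward(d)
    errs = []
    for p in picks:
        flat, g = p.value.ravel(), p.grad.ravel()
        for idx in (0, len(flat) // 2):
            orig = flat[idx]
            eps = 1e-6
            flat[idx] = orig + eps
            lp, _ = softmax_cross_entropy(enc.forward_train(x), y)
            flat[idx] = orig - eps
            lm, _ = softmax_cross_entropy(enc.forward_train(x), y)
            flat[idx] = orig
            errs.append(abs((lp - lm) / (2 * eps) - g[idx]))
    return max(errs)


class TestGradients:
    def test_tdnn_backprop_matches_numeric(self):
        spec = EncoderSpec(
            kind="tdnn",
            tdnn_contexts=([-2, -1, 0, 1, 2], [-2, 0, 2], [-3, 0, 3], [0], [0]),
            tdnn_dims=(5, 5, 5, 5, 7),
            embedding_dim=4,
            feat_dim=6,
        )
        enc = build_encoder(spec, seed=0)
        enc.set_head(3)
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=(2, 30, 6)), np.array([0, 2])
        ps = enc.params()
        assert _numeric_grad_check(enc, x, y, [ps[0], ps[4], ps[-2]]) < 1e-7

    def test_resnet_backprop_matches_numeric(self):
        spec = EncoderSpec(
            kind="resnet34",
            embedding_dim=4,
            feat_dim=12,
            resnet_blocks=(1, 1, 1, 1),
            resnet_channels=(2, 3, 4, 5),
            resnet_strides=(1, 2, 2, 2),
        )
        enc = build_encoder(spec, seed=0)
        enc.set_head(3)
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=(2, 16, 12)), np.array([1, 0])
        ps = enc.params()
        assert _numeric_grad_check(enc, x, y, [ps[0], ps[2], ps[-2]]) < 1e-7


class TestVariableLength:
    @pytest.mark.parametrize("spec", [EncoderSpec.tiny_tdnn(), EncoderSpec.tiny_resnet()])
    def test_fixed_embedding_length_across_durations(self, spec):
        """120- and 480-frame utterances must map to identical-length vectors."""
        enc = build_encoder(spec, seed=0)
        rng = np.random.default_rng(0)
        v1 = enc.embed(rng.normal(size=(120, 60)))
        v2 = enc.embed(rng.normal(size=(480, 60)))
        assert v1.shape == v2.shape == (spec.embedding_dim,)

    def test_too_few_frames_rejected(self):
        enc = build_encoder(EncoderSpec.tiny_tdnn(), seed=0)
        with pytest.raises(ArgumentError):
            enc.embed(np.zeros((14, 60)))

    def test_inference_deterministic(self):
        enc = build_encoder(EncoderSpec.tiny_tdnn(), seed=0)
        x = np.random.default_rng(3).normal(size=(90, 60))
        np.testing.assert_array_equal(enc.embed(x), enc.embed(x))


def _two_speaker_manifest(tmp_path):
    rows = []
    rng = np.random.default_rng(0)
    for s, (f0, rate) in enumerate([(110.0, 3.5), (250.0, 4.5)]):
        for u in range(8):
            prof = SpeakerProfile(
                f"spk{s:04d}", f0 * rng.normal(1, 0.02), 20.0, np.ones(3), rate, 0.1
            )
            wav, _ = render_utterance(prof, 0, 3.0, 100 * s + u)
            p = tmp_path / f"spk{s:04d}_utt{u:03d}.wav"
            write_wav(p, wav)
            rows.append(
                {"id": p.stem, "label": "NA", "task": "NA", "path": str(p), "duration_s": 3.0}
            )
    return pd.DataFrame(rows)


class TestTraining:
    def test_disjoint_f0_speakers_learned_quickly(self, tmp_path):
        """Two acoustically disjoint speakers: >0.9 chunk accuracy in 3 epochs."""
        manifest = _two_speaker_manifest(tmp_path)
        feats = featurize_manifest(manifest, "mfcc")
        ext = train_extractor(
            manifest,
            "mfcc",
            EncoderSpec.tiny_tdnn(),
            TrainingConfig(epochs=3, batch_size=16, seed=0),
            features=feats,
        )
        assert ext.history["chunk_accuracy"][-1] > 0.9

    def test_single_speaker_rejected(self, tmp_path):
        manifest = _two_speaker_manifest(tmp_path)
        solo = manifest[manifest["id"].str.startswith("spk0000")]
        with pytest.raises(ArgumentError):
            train_extractor(
                solo, "mfcc", EncoderSpec.tiny_tdnn(), TrainingConfig(epochs=1, seed=0)
            )

    def test_zero_epochs_still_shape_valid(self, pretrain_corpus, mfcc_features):
        manifest, _ = pretrain_corpus
        ext = train_extractor(
            manifest,
            "mfcc",
            EncoderSpec.tiny_tdnn(),
            TrainingConfig(epochs=0, seed=0),
            features=mfcc_features,
        )
        ff = mfcc_features[manifest["id"][0]]
        emb = extract_embedding(ext, ff, subject_id="s")
        assert emb.dim == ext.spec.embedding_dim

    def test_seeded_training_reproducible(self, pretrain_corpus, mfcc_features):
        manifest, _ = pretrain_corpus
        outs = []
        for _ in range(2):
            ext = train_extractor(
                manifest,
                "mfcc",
                EncoderSpec.tiny_tdnn(),
                TrainingConfig(epochs=1, batch_size=16, seed=9),
                features=mfcc_features,
            )
            outs.append(np.concatenate([p.value.ravel() for p in ext.encoder.params()]))
        np.testing.assert_array_equal(outs[0], outs[1])


class TestExtraction:
    def test_feature_kind_mismatch_rejected(self, tiny_tdnn_extractor):
        ff = FrameFeatures(data=np.zeros((50, 60)), kind="plp")
        with pytest.raises(ArgumentError):
            extract_embedding(tiny_tdnn_extractor, ff)

    def test_embedding_tagged_and_deterministic(self, tiny_tdnn_extractor, mfcc_features, pretrain_corpus):
        manifest, _ = pretrain_corpus
        ff = mfcc_features[manifest["id"][0]]
        a = extract_embedding(tiny_tdnn_extractor, ff, subject_id="s", task_id=1)
        b = extract_embedding(tiny_tdnn_extractor, ff, subject_id="s", task_id=1)
        assert a.tag == "T_m"
        np.testing.assert_array_equal(a.vector, b.vector)

    def test_whole_vs_halves_cosine(self, tiny_tdnn_extractor, mfcc_features, pretrain_corpus):
        """Whole-utterance embedding stays close to the mean of half embeddings."""
        manifest, _ = pretrain_corpus
        enc = tiny_tdnn_extractor.encoder
        ff = mfcc_features[manifest["id"][0]]
        x = ff.data
        whole = enc.embed(x)
        halves = (enc.embed(x[: len(x) // 2]) + enc.embed(x[len(x) // 2 :])) / 2
        cos = whole @ halves / (np.linalg.norm(whole) * np.linalg.norm(halves))
        assert cos > 0.8
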
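"""Pre-training of neural embedding extractors on a many-speaker corpus.

Extractors are trained with a speaker-classification cross-entropy objective
on fixed-length chunks (default 200 frames) and then frozen: the
classification head is kept for diagnostics but never used at extraction
time. Extraction always forwards the full, unchunked utterance; only
training chunks are wrap-padded when an utterance is shorter than one chunk.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from voxscreen.audio import read_wav, resample_to_16k
from voxscreen.encoders import EncoderSpec, build_encoder
from voxscreen.errors import ArgumentError
from voxscreen.features import FeatureConfig, FrameFeatures, VadConfig, apply_cmvn, energy_vad, extract_features
from voxscreen.nnet import AdamW, softmax_cross_entropy
from voxscreen.synth import subject_of
from voxscreen.types import SpeakerEmbedding, embedding_tag


@dataclass
class TrainingConfig:
    chunk_frames: int = 200
    batch_size: int = 64
    lr: float = 0.001
    lr_decay: float = 0.7  # TDNN schedule; ResNet uses factor 1.0 (constant)
    decay_every_steps: int = 400
    epochs: int = 18
    weight_decay: float = 1e-4
    optimizer: str = "adamw"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chunk_frames < 1:
            raise ArgumentError("chunk_frames must be >= 1")
        if self.lr <= 0:
            raise ArgumentError("lr must be > 0")


@dataclass
class EmbeddingExtractor:
    """A trained encoder plus the metadata needed to use it safely."""

    encoder: object
    spec: EncoderSpec
    config: TrainingConfig
    feature_kind: str
    speakers: list = field(default_factory=list)
    history: dict = field(default_factory=dict)

    @property
    def tag(self) -> str:
        return embedding_tag(self.spec.kind, self.feature_kind)


def featurize_utterance(
    path: str | Path,
    kind: str,
    feature_config: FeatureConfig | None = None,
    vad_config: VadConfig | None = None,
    *,
    apply_vad: bool = True,
    cmvn: bool = True,
    utt_id: str = "",
) -> FrameFeatures:
    """WAV -> voiced, mean-normalized 60-d features (the standard front end)."""
    wav, rate = read_wav(path)
    wav = resample_to_16k(wav, rate)
    ff = extract_features(wav, kind, feature_config, utt_id=utt_id)
    if apply_vad:
        mask = energy_vad(wav, vad_config, feature_config)
        ff = FrameFeatures(
            data=ff.data[mask],
            kind=ff.kind,
            utt_id=ff.utt_id,
            frame_shift_s=ff.frame_shift_s,
            frame_length_s=ff.frame_length_s,
        )
    if cmvn and ff.n_frames >= 2:
        ff = apply_cmvn(ff)
    return ff


def featurize_manifest(
    manifest: pd.DataFrame,
    kind: str,
    feature_config: FeatureConfig | None = None,
    **kwargs,
) -> dict[str, FrameFeatures]:
    return {
        row["id"]: featurize_utterance(row["path"], kind, feature_config, utt_id=row["id"], **kwargs)
        for _, row in manifest.iterrows()
    }


def _chunk(data: np.ndarray, chunk_frames: int) -> list[np.ndarray]:
    """Non-overlapping chunks; short utterances are wrap-padded to one chunk."""
    T = data.shape[0]
    if T < chunk_frames:
        reps = -(-chunk_frames // T)
        return [np.tile(data, (reps, 1))[:chunk_frames]]
    return [data[i : i + chunk_frames] for i in range(0, T - chunk_frames + 1, chunk_frames)]


def train_extractor(
    corpus: pd.DataFrame,
    feature_kind: str,
    spec: EncoderSpec,
    cfg: TrainingConfig,
    features: dict[str, FrameFeatures] | None = None,
) -> EmbeddingExtractor:
    """Train a speaker-classification encoder on the pre-training corpus.

    ``features`` may carry precomputed per-utterance features keyed by
    manifest id; otherwise WAVs are featurized (VAD + CMVN) on the fly.
    Deterministic given ``cfg.seed`` on a single thread.
    """
    if features is None:
        features = featurize_manifest(corpus, feature_kind)
    speakers = sorted({subject_of(u) for u in corpus["id"]})
    if len(speakers) < 2:
        raise ArgumentError("pre-training needs at least 2 speakers")
    spk_index = {s: i for i, s in enumerate(speakers)}

    chunks: list[np.ndarray] = []
    labels: list[int] = []
    for utt_id in corpus["id"]:
        ff = features[utt_id]
        for ch in _chunk(ff.data, cfg.chunk_frames):
            chunks.append(ch)
            labels.append(spk_index[subject_of(utt_id)])
    X = np.stack(chunks)
    y = np.asarray(labels)

    encoder = build_encoder(spec, seed=cfg.seed)
    encoder.set_head(len(speakers))
    opt = AdamW(encoder.params(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed + 1)

    history = {"loss": [], "chunk_accuracy": []}
    step = 0
    for _epoch in range(cfg.epochs):
        order = rng.permutation(len(X))
        losses, correct, seen = [], 0, 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = X[idx], y[idx]
            opt.lr = cfg.lr * (cfg.lr_decay ** (step // cfg.decay_every_steps))
            logits = encoder.forward_train(xb)
            loss, dlogits = softmax_cross_entropy(logits, yb)
            opt.zero_grad()
            encoder.backward(dlogits)
            opt.step()
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == yb).sum())
            seen += len(yb)
            step += 1
        history["loss"].append(float(np.mean(losses)))
        history["chunk_accuracy"].append(correct / max(seen, 1))

    return EmbeddingExtractor(
        encoder=encoder,
        spec=spec,
        config=cfg,
        feature_kind=feature_kind.lower(),
        speakers=speakers,
        history=history,
    )


def extract_embedding(
    extractor: EmbeddingExtractor,
    features: FrameFeatures,
    subject_id: str = "",
    task_id: int | None = None,
) -> SpeakerEmbedding:
    """Forward the full utterance and tap the first segment-level affine."""
    if features.kind != extractor.feature_kind:
        raise ArgumentError(
            f"features are {features.kind!r} but extractor was trained on {extractor.feature_kind!r}"
        )
    vec = extractor.encoder.embed(features.data)
    return SpeakerEmbedding(vector=vec, subject_id=subject_id, task_id=task_id, tag=extractor.tag)


def save_extractor(path: str | Path, extractor: EmbeddingExtractor, fingerprint: str = "") -> None:
    arrays = {f"p{i}": p.value for i, p in enumerate(extractor.encoder.params())}
    meta = {
        "spec": asdict(extractor.spec),
        "config": asdict(extractor.config),
        "feature_kind": extractor.feature_kind,
        "speakers": extractor.speakers,
        "history": extractor.history,
        "fingerprint": fingerprint,
    }
    np.savez_compressed(path, _meta=np.array(json.dumps(meta)), **arrays)


def load_extractor(path: str | Path) -> EmbeddingExtractor:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["_meta"]))
        spec_d = dict(meta["spec"])
        spec_d["tdnn_contexts"] = tuple(tuple(c) for c in spec_d["tdnn_contexts"])
        for key in ("tdnn_dims", "resnet_blocks", "resnet_channels", "resnet_strides"):
            spec_d[key] = tuple(spec_d[key])
        spec = EncoderSpec(**spec_d)
        cfg = TrainingConfig(**meta["config"])
        encoder = build_encoder(spec, seed=cfg.seed)
        encoder.set_head(len(meta["speakers"]))
        for i, p in enumerate(encoder.params()):
            p.value[...] = z[f"p{i}"]
        return EmbeddingExtractor(
            encoder=encoder,
            spec=spec,
            config=cfg,
            feature_kind=meta["feature_kind"],
            speakers=meta["speakers"],
            history=meta["history"],
        )
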
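"""End-to-end experiment orchestration with content-fingerprint caching.

Stages: simulate (pretrain corpus + cohort) -> featurize -> pre-train
extractors -> extract embeddings -> repeated-CV ensemble evaluation. Each
stage writes its artifact plus a fingerprint of the config subtree and seed
that produced it; a rerun with an unchanged fingerprint is a cache hit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from voxscreen import ivector as iv
from voxscreen.encoders import EncoderSpec
from voxscreen.ensemble import EmbeddingTable, EnsemblePipeline
from voxscreen.errors import ArgumentError
from voxscreen.evaluation import EvalReport, repeated_cv
from voxscreen.pretrain import (
    EmbeddingExtractor,
    TrainingConfig,
    extract_embedding,
    featurize_manifest,
    load_extractor,
    save_extractor,
    train_extractor,
)
from voxscreen.synth import CohortConfig, generate_cohort, generate_pretrain_corpus, read_manifest, subject_of
from voxscreen.types import SpeakerEmbedding, embedding_tag

log = logging.getLogger("voxscreen")


def _fingerprint(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _cached(stage_dir: Path, fp: str) -> bool:
    f = stage_dir / "fingerprint.json"
    return f.is_file() and json.loads(f.read_text()).get("fingerprint") == fp


def _mark(stage_dir: Path, fp: str) -> None:
    stage_dir.mkdir(parents=True, exist_ok=True)
    (stage_dir / "fingerprint.json").write_text(json.dumps({"fingerprint": fp}))


class IVectorExtractor:
    """Adapter giving the i-vector model the same extraction surface as the DNNs."""

    def __init__(self, model: iv.TotalVariabilityModel, feature_kind: str):
        self.model = model
        self.feature_kind = feature_kind

    @property
    def tag(self) -> str:
        return embedding_tag("ivector", self.feature_kind)

    def extract(self, ff, subject_id: str, task_id: int | None) -> SpeakerEmbedding:
        stats = iv.accumulate_stats(self.model.ubm, ff)
        return iv.extract_ivector(
            self.model, stats, subject_id=subject_id, task_id=task_id, feature_kind=self.feature_kind
        )


def _extractor_sizes(ext_cfg: dict) -> dict:
    """Desk-scale ('tiny') vs. published-scale ('paper') model sizes."""
    if ext_cfg["size"] == "paper":
        return {
            "tdnn_spec": EncoderSpec.tdnn(),
            "resnet_spec": EncoderSpec.resnet34(),
            "ubm_components": 256,
            "ivector_rank": 256,
            "epochs_tdnn": 18,
            "epochs_resnet": 21,
        }
    return {
        "tdnn_spec": EncoderSpec.tiny_tdnn(),
        "resnet_spec": EncoderSpec.tiny_resnet(),
        "ubm_components": 8,
        "ivector_rank": 16,
        "epochs_tdnn": 40,  # thin layers + small corpus need more passes to fit
        "epochs_resnet": 6,
    }


def build_extractor(ext_cfg: dict, pretrain_manifest: pd.DataFrame, seed: int, cache_dir: Path):
    """Train (or cache-load) one embedding extractor on the pre-training corpus."""
    sizes = _extractor_sizes(ext_cfg)
    kind, feat = ext_cfg["kind"], ext_cfg["feature"]
    fp = _fingerprint({"ext": ext_cfg, "seed": seed, "n_rows": len(pretrain_manifest)})
    cache_dir.mkdir(parents=True, exist_ok=True)

    if kind == "ivector":
        path = cache_dir / f"ivector_{feat}.npz"
        if _cached(cache_dir, fp) and path.is_file():
            log.info("cache hit: %s", path)
            return IVectorExtractor(iv.load_ivector_model(path), feat)
        feats = featurize_manifest(pretrain_manifest, feat)
        ubm = iv.train_ubm(list(feats.values()), n_components=sizes["ubm_components"], seed=seed)
        stats = [iv.accumulate_stats(ubm, f) for f in feats.values()]
        model = iv.train_total_variability(stats, rank=sizes["ivector_rank"], seed=seed, ubm=ubm)
        iv.save_ivector_model(path, model, fingerprint=fp)
        _mark(cache_dir, fp)
        return IVectorExtractor(model, feat)

    spec = sizes["tdnn_spec"] if kind == "tdnn" else sizes["resnet_spec"]
    epochs = ext_cfg["epochs"]
    if epochs is None:
        epochs = sizes["epochs_tdnn"] if kind == "tdnn" else sizes["epochs_resnet"]
    cfg = TrainingConfig(
        epochs=epochs,
        seed=seed,
        lr_decay=0.7 if kind == "tdnn" else 1.0,  # ResNet: constant rate
    )
    path = cache_dir / f"{kind}_{feat}.npz"
    if _cached(cache_dir, fp) and path.is_file():
        log.info("cache hit: %s", path)
        return load_extractor(path)
    feats = featurize_manifest(pretrain_manifest, feat)
    extractor = train_extractor(pretrain_manifest, feat, spec, cfg, features=feats)
    save_extractor(path, extractor, fingerprint=fp)
    _mark(cache_dir, fp)
    return extractor


def extract_cohort_table(extractors: list, cohort_manifest: pd.DataFrame) -> EmbeddingTable:
    """Embed every cohort utterance with every extractor into one table."""
    table = EmbeddingTable()
    by_kind: dict[str, dict] = {}
    for ext in extractors:
        fk = ext.feature_kind
        if fk not in by_kind:
            by_kind[fk] = featurize_manifest(cohort_manifest, fk)
    for _, row in cohort_manifest.iterrows():
        subj = subject_of(row["id"])
        task = int(row["task"])
        for ext in extractors:
            ff = by_kind[ext.feature_kind][row["id"]]
            if isinstance(ext, EmbeddingExtractor):
                emb = extract_embedding(ext, ff, subject_id=subj, task_id=task)
            else:
                emb = ext.extract(ff, subject_id=subj, task_id=task)
            table.add(emb, label=row["label"])
    return table


def run_experiment(cfg: dict) -> EvalReport:
    """Execute simulate -> featurize -> pretrain -> extract -> ensemble -> evaluate."""
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")

    # stage: simulate pretrain corpus
    pre_dir = out / "pretrain_corpus"
    fp = _fingerprint({"pretrain": cfg["pretrain"], "seed": seed})
    if _cached(pre_dir, fp):
        pre_manifest = read_manifest(pre_dir / "manifest.csv")
        log.info("cache hit: pretrain corpus")
    else:
        pre_manifest = generate_pretrain_corpus(
            cfg["pretrain"]["n_speakers"],
            cfg["pretrain"]["utts_per_speaker"],
            seed=seed,
            out_dir=pre_dir,
            mean_duration_s=cfg["pretrain"]["duration_s"],
        )
        _mark(pre_dir, fp)

    # stage: simulate cohort
    coh_dir = out / "cohort"
    fp = _fingerprint({"cohort": cfg["cohort"], "seed": seed})
    if _cached(coh_dir, fp):
        coh_manifest = read_manifest(coh_dir / "manifest.csv")
        log.info("cache hit: cohort")
    else:
        coh_manifest = generate_cohort(
            CohortConfig(seed=seed + 1, **cfg["cohort"]), out_dir=coh_dir
        )
        _mark(coh_dir, fp)

    # stage: pretrain extractors
    extractors = []
    for i, ext_cfg in enumerate(cfg["extractors"]):
        extractors.append(
            build_extractor(ext_cfg, pre_manifest, seed + 10 + i, out / f"extractor_{i}")
        )

    # stage: extract embeddings
    emb_path = out / "embeddings.csv"
    fp = _fingerprint({"extractors": cfg["extractors"], "cohort": cfg["cohort"], "seed": seed})
    if _cached(out / "embeddings_stage", fp) and emb_path.is_file():
        table = EmbeddingTable.from_dataframe(pd.read_csv(emb_path))
        log.info("cache hit: embeddings")
    else:
        table = extract_cohort_table(extractors, coh_manifest)
        table.to_dataframe().to_csv(emb_path, index=False)
        _mark(out / "embeddings_stage", fp)

    # stage: ensemble + evaluation
    ens = cfg["ensemble"]

    def factory(fold_seed: int) -> EnsemblePipeline:
        return EnsemblePipeline(
            tags=ens["tags"],
            kind=ens["classifier"],
            task_grid=ens["task_grid"],
            meta_grid=ens["meta_grid"],
            protocol=ens["protocol"],
            seed=fold_seed,
            mlp_max_iter=ens["mlp_max_iter"],
        )

    report = repeated_cv(
        factory,
        table,
        repetitions=cfg["evaluation"]["repetitions"],
        k=cfg["evaluation"]["k"],
        base_seed=seed + 100,
        config_note={
            "tags": ens["tags"],
            "meta_feature_width": len(ens["tags"]) * len(table.tasks),
        },
    )
    report.to_json(out / "report.json")
    log.info("aggregate: %s", report.aggregate)
    return report
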
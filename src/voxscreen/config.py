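"""Experiment configuration: YAML schema with defaults and strict validation.

Unknown keys are rejected; seeds must be explicit (no wall-clock defaults).
"""

from __future__ import annotations

from pathlib import Path

import yaml

from voxscreen.errors import ArgumentError
from voxscreen.types import VALID_TAGS

_EXTRACTOR_DEFAULTS = {
    "kind": "tdnn",  # tdnn | resnet34 | ivector
    "feature": "mfcc",
    "size": "tiny",  # tiny | paper
    "epochs": None,  # None -> kind-specific default (18 tdnn / 21 resnet)
}

_SCHEMA = {
    "seed": None,  # required
    "out_dir": None,  # required
    "pretrain": {"n_speakers": 12, "utts_per_speaker": 6, "duration_s": 4.0},
    "cohort": {
        "n_depressed": 20,
        "n_healthy": 20,
        "n_tasks": 9,
        "effect_size": 2.0,
        "duration_s": 3.0,
    },
    "extractors": [dict(_EXTRACTOR_DEFAULTS)],
    "ensemble": {
        "tags": None,  # None -> all extractor tags
        "classifier": "svm",
        "protocol": "out_of_fold",
        "task_grid": None,
        "meta_grid": None,
        "mlp_max_iter": 500,
    },
    "evaluation": {"repetitions": 5, "k": 10},
}

_REQUIRED = ("seed", "out_dir")


def _merge(defaults: dict, given: dict, path: str) -> dict:
    unknown = set(given) - set(defaults)
    if unknown:
        raise ArgumentError(f"unknown config keys at {path or 'top level'}: {sorted(unknown)}")
    out = {}
    for key, default in defaults.items():
        if key in given:
            val = given[key]
            if isinstance(default, dict) and isinstance(val, dict):
                val = _merge(default, val, f"{path}.{key}" if path else key)
            out[key] = val
        else:
            out[key] = default
    return out


def normalize_config(raw: dict) -> dict:
    """Inject defaults, reject unknown keys, check cross-field consistency."""
    if not isinstance(raw, dict) or not raw:
        raise ArgumentError(f"config must be a non-empty mapping with keys {list(_SCHEMA)}")
    cfg = _merge(_SCHEMA, raw, "")
    missing = [k for k in _REQUIRED if cfg[k] is None]
    if missing:
        raise ArgumentError(f"missing required config keys: {missing}")
    if not isinstance(cfg["seed"], int):
        raise ArgumentError("seed must be an explicit integer")
    extractors = []
    for i, ext in enumerate(cfg["extractors"]):
        extractors.append(_merge(_EXTRACTOR_DEFAULTS, ext, f"extractors[{i}]"))
    cfg["extractors"] = extractors
    available_tags = {_tag_of(e) for e in extractors}
    tags = cfg["ensemble"]["tags"]
    if tags is None:
        cfg["ensemble"]["tags"] = sorted(available_tags)
    else:
        bad = [t for t in tags if t not in VALID_TAGS]
        if bad:
            raise ArgumentError(f"unknown embedding tags: {bad}")
        unresolvable = [t for t in tags if t not in available_tags]
        if unresolvable:
            raise ArgumentError(
                f"tags {unresolvable} are not produced by any configured extractor"
            )
    if cfg["ensemble"]["protocol"] not in ("out_of_fold", "in_sample"):
        raise ArgumentError("ensemble.protocol must be out_of_fold or in_sample")
    return cfg


def _tag_of(ext: dict) -> str:
    from voxscreen.types import embedding_tag

    return embedding_tag(ext["kind"], ext["feature"])


def validate_config(path: str | Path) -> dict:
    """Load + normalize a YAML experiment config file."""
    path = Path(path)
    if not path.is_file():
        raise ArgumentError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ArgumentError(f"YAML parse error in {path}: {exc}") from exc
    if raw is None:
        raise ArgumentError(f"config file {path} is empty; required keys: {list(_REQUIRED)}")
    return normalize_config(raw)
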
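"""Shared light-weight containers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: extractor-kind letter used in embedding nicknames
_KIND_LETTER = {"ivector": "I", "tdnn": "T", "resnet34": "R"}
#: feature-kind letter used in embedding nicknames
_FEAT_LETTER = {"mfcc": "m", "plp": "p", "fbank": "f"}


def embedding_tag(extractor_kind: str, feature_kind: str) -> str:
    """Nickname of an embedding type, e.g. ``R_m`` for MFCC-based ResNet x-vectors."""
    try:
        return f"{_KIND_LETTER[extractor_kind.lower()]}_{_FEAT_LETTER[feature_kind.lower()]}"
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"unknown extractor/feature kind: {exc}") from exc


VALID_TAGS = frozenset(
    embedding_tag(k, f) for k in _KIND_LETTER for f in _FEAT_LETTER
)


@dataclass
class SpeakerEmbedding:
    """Fixed-length utterance-level embedding with provenance metadata."""

    vector: np.ndarray
    subject_id: str
    task_id: int | None
    tag: str  # nickname, e.g. "R_m", "T_f", "I_m"

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=np.float64).ravel()
        if not np.all(np.isfinite(self.vector)):
            raise ValueError("embedding contains non-finite values")

    @property
    def dim(self) -> int:
        return self.vector.shape[0]
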
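"""Shared fixtures: small synthetic corpora and a trained tiny extractor.

Session-scoped so the expensive artifacts (rendered audio, extractor
training) are built once per run.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from sklearn.exceptions import ConvergenceWarning

warnings.filterwarnings("ignore", category=ConvergenceWarning)
warnings.filterwarnings("ignore", message=".*probability.*deprecated.*", category=FutureWarning)

from voxscreen.encoders import EncoderSpec
from voxscreen.pretrain import TrainingConfig, featurize_manifest, train_extractor
from voxscreen.synth import CohortConfig, generate_cohort, generate_pretrain_corpus


@pytest.fixture(scope="session")
def pretrain_corpus(tmp_path_factory):
    """6 speakers x 4 utterances, 2.5 s mean — enough for speaker-ID learning."""
    out = tmp_path_factory.mktemp("pretrain")
    manifest = generate_pretrain_corpus(6, 4, seed=11, out_dir=out, mean_duration_s=2.5)
    return manifest, out


@pytest.fixture(scope="session")
def cohort_small(tmp_path_factory):
    """8 + 8 subjects, 9 tasks, strong group separation."""
    out = tmp_path_factory.mktemp("cohort")
    cfg = CohortConfig(n_depressed=8, n_healthy=8, effect_size=2.0, duration_s=2.5, seed=21)
    manifest = generate_cohort(cfg, out_dir=out)
    return manifest, out, cfg


@pytest.fixture(scope="session")
def mfcc_features(pretrain_corpus):
    manifest, _ = pretrain_corpus
    return featurize_manifest(manifest, "mfcc")


@pytest.fixture(scope="session")
def tiny_tdnn_extractor(pretrain_corpus, mfcc_features):
    manifest, _ = pretrain_corpus
    cfg = TrainingConfig(epochs=8, batch_size=16, seed=5)
    return train_extractor(manifest, "mfcc", EncoderSpec.tiny_tdnn(), cfg, features=mfcc_features)


def autocorr_pitch(wav: np.ndarray, sr: int = 16000, fmin: float = 60.0, fmax: float = 400.0):
    """Frame-wise autocorrelation pitch tracker (independent measurement oracle).

    Returns F0 estimates for frames whose energy clears a silence gate.
    """
    frame, hop = int(0.04 * sr), int(0.02 * sr)
    lag_min, lag_max = int(sr / fmax), int(sr / fmin)
    f0s = []
    gate = 0.05 * np.sqrt(np.mean(np.square(wav)))
    for start in range(0, len(wav) - frame, hop):
        seg = wav[start : start + frame]
        rms = np.sqrt(np.mean(np.square(seg)))
        if rms < gate or rms < 1e-4:
            continue
        seg = seg - seg.mean()
        ac = np.correlate(seg, seg, mode="full")[frame - 1 :]
        if ac[0] <= 0:
            continue
        ac = ac / ac[0]
        window = ac[lag_min : lag_max + 1]
        lag = lag_min + int(np.argmax(window))
        if ac[lag] > 0.4:
            f0s.append(sr / lag)
    return np.asarray(f0s)
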
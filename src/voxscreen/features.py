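"""Frame-level acoustic features: 60-d MFCC, PLP and FBANK.

Framing follows the dominant speech-toolkit convention: 25 ms Hamming
windows, 10 ms shift, snip-edges (only full windows), pre-emphasis 0.97,
optional dither (off by default so silence and frame counts are exactly
reproducible). At 16 kHz this gives T = 1 + floor((N - 400)/160) frames.

The three feature kinds share the framing front end and all come out 60-d:

* FBANK — log energies of 60 mel filters.
* MFCC  — 20 cepstra (incl. C0) over 40 mel filters, plus deltas and
  delta-deltas (20 + 20 + 20 = 60). A "static" dialect with 60 cepstra over
  60 filters is available via :class:`FeatureConfig`.
* PLP   — Bark-scale critical bands with equal-loudness pre-emphasis and
  cube-root intensity-loudness compression, an order-19 autoregressive fit
  (20 cepstra incl. the gain term), plus deltas and delta-deltas.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.fft import dct, rfft
from scipy.linalg import solve_toeplitz

from voxscreen.audio import resample_to_16k
from voxscreen.errors import ArgumentError, DegenerateUtteranceError

FEATURE_KINDS = ("mfcc", "plp", "fbank")
FEATURE_DIM = 60

_LOG_FLOOR = 1e-10


@dataclass
class FeatureConfig:
    sample_rate: int = 16000
    frame_length_s: float = 0.025
    frame_shift_s: float = 0.010
    preemphasis: float = 0.97
    dither: float = 0.0  # std of additive noise in sample units; 0 disables
    n_fft: int = 512
    # FBANK / MFCC
    n_mels_fbank: int = 60
    n_mels_mfcc: int = 40
    n_ceps: int = 20  # static cepstra incl. C0; deltas bring the total to 60
    mfcc_static60: bool = False  # alternative dialect: 60 static cepstra / 60 mels
    fmin: float = 20.0
    fmax: float = 7600.0
    # PLP
    plp_order: int = 19  # AR model order -> order+1 = 20 cepstra
    n_barks: int = 21
    # CMVN
    cmvn_var_norm: bool = False

    @property
    def frame_length(self) -> int:
        return int(round(self.frame_length_s * self.sample_rate))

    @property
    def frame_shift(self) -> int:
        return int(round(self.frame_shift_s * self.sample_rate))


@dataclass
class FrameFeatures:
    """T x F matrix of per-frame features with framing metadata."""

    data: np.ndarray  # (T, 60)
    kind: str
    utt_id: str = ""
    frame_shift_s: float = 0.010
    frame_length_s: float = 0.025

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if self.data.shape[0] < 1:
            raise ArgumentError("FrameFeatures needs at least one frame")
        if not np.all(np.isfinite(self.data)):
            raise ArgumentError("FrameFeatures contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def dim(self) -> int:
        return self.data.shape[1]


def n_frames_snip(n_samples: int, cfg: FeatureConfig | None = None) -> int:
    """Frame count under snip-edges framing; 0 if shorter than one window."""
    cfg = cfg or FeatureConfig()
    if n_samples < cfg.frame_length:
        return 0
    return 1 + (n_samples - cfg.frame_length) // cfg.frame_shift


def frame_signal(x: np.ndarray, cfg: FeatureConfig) -> np.ndarray:
    """Snip-edges framing with pre-emphasis and Hamming window. (T, L)."""
    x = np.asarray(x, dtype=np.float64)
    T = n_frames_snip(x.shape[0], cfg)
    if T < 1:
        raise ArgumentError("waveform shorter than one frame")
    idx = np.arange(cfg.frame_length)[None, :] + cfg.frame_shift * np.arange(T)[:, None]
    frames = x[idx].copy()
    if cfg.dither > 0:
        rng = np.random.default_rng(12345)
        frames += rng.normal(0.0, cfg.dither, size=frames.shape)
    # per-frame pre-emphasis (first sample emphasised against itself)
    frames[:, 1:] -= cfg.preemphasis * frames[:, :-1]
    frames[:, 0] *= 1.0 - cfg.preemphasis
    return frames * np.hamming(cfg.frame_length)


def _power_spectrum(frames: np.ndarray, cfg: FeatureConfig) -> np.ndarray:
    spec = rfft(frames, n=cfg.n_fft, axis=1)
    return (spec.real**2 + spec.imag**2)


def _hz_to_mel(f):
    return 1127.0 * np.log1p(np.asarray(f, dtype=np.float64) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (np.expm1(np.asarray(m, dtype=np.float64) / 1127.0))


def mel_filterbank(n_filters: int, cfg: FeatureConfig) -> np.ndarray:
    """Triangular mel filterbank, (n_filters, n_fft//2 + 1)."""
    n_bins = cfg.n_fft // 2 + 1
    freqs = np.arange(n_bins) * cfg.sample_rate / cfg.n_fft
    edges = _mel_to_hz(np.linspace(_hz_to_mel(cfg.fmin), _hz_to_mel(cfg.fmax), n_filters + 2))
    fb = np.zeros((n_filters, n_bins))
    for i in range(n_filters):
        lo, ctr, hi = edges[i], edges[i + 1], edges[i + 2]
        up = (freqs - lo) / max(ctr - lo, 1e-9)
        down = (hi - freqs) / max(hi - ctr, 1e-9)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def _bark(f):
    return 6.0 * np.arcsinh(np.asarray(f, dtype=np.float64) / 600.0)


def bark_filterbank(n_filters: int, cfg: FeatureConfig) -> tuple[np.ndarray, np.ndarray]:
    """Triangular Bark-scale filterbank; returns (filters, center frequencies)."""
    n_bins = cfg.n_fft // 2 + 1
    freqs = np.arange(n_bins) * cfg.sample_rate / cfg.n_fft
    bark_bins = _bark(freqs)
    edges = np.linspace(_bark(cfg.fmin), _bark(cfg.fmax), n_filters + 2)
    centers_hz = 600.0 * np.sinh(edges[1:-1] / 6.0)
    fb = np.zeros((n_filters, n_bins))
    for i in range(n_filters):
        lo, ctr, hi = edges[i], edges[i + 1], edges[i + 2]
        up = (bark_bins - lo) / max(ctr - lo, 1e-9)
        down = (hi - bark_bins) / max(hi - ctr, 1e-9)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    return fb, centers_hz


def _equal_loudness(f: np.ndarray) -> np.ndarray:
    f2 = np.square(f) + 1e-9
    return (f2 / (f2 + 1.6e5)) ** 2 * ((f2 + 1.44e6) / (f2 + 9.61e6))


def compute_deltas(x: np.ndarray, window: int = 2) -> np.ndarray:
    """Regression deltas with edge replication (standard delta window N=2)."""
    T = x.shape[0]
    denom = 2.0 * sum(k * k for k in range(1, window + 1))
    padded = np.concatenate([x[:1].repeat(window, axis=0), x, x[-1:].repeat(window, axis=0)])
    out = np.zeros_like(x)
    for k in range(1, window + 1):
        out += k * (padded[window + k : window + k + T] - padded[window - k : window - k + T])
    return out / denom


def _fbank(frames: np.ndarray, cfg: FeatureConfig) -> np.ndarray:
    pspec = _power_spectrum(frames, cfg)
    energies = pspec @ mel_filterbank(cfg.n_mels_fbank, cfg).T
    return np.log(np.maximum(energies, _LOG_FLOOR))


def _mfcc(frames: np.ndarray, cfg: FeatureConfig) -> np.ndarray:
    if cfg.mfcc_static60:
        n_mels, n_ceps = FEATURE_DIM, FEATURE_DIM
    else:
        n_mels, n_ceps = cfg.n_mels_mfcc, cfg.n_ceps
    pspec = _power_spectrum(frames, cfg)
    logmel = np.log(np.maximum(pspec @ mel_filterbank(n_mels, cfg).T, _LOG_FLOOR))
    ceps = dct(logmel, type=2, norm="ortho", axis=1)[:, :n_ceps]
    if cfg.mfcc_static60:
        return ceps
    return np.hstack([ceps, compute_deltas(ceps), compute_deltas(compute_deltas(ceps))])


def _lpc_to_cepstrum(a: np.ndarray, gain: float, n_ceps: int) -> np.ndarray:
    """Cepstra of an all-pole model 1/A(z); c[0] = log gain."""
    order = a.shape[0]
    c = np.zeros(n_ceps)
    c[0] = np.log(max(gain, _LOG_FLOOR))
    for n in range(1, n_ceps):
        acc = a[n - 1] if n <= order else 0.0
        for k in range(1, n):
            if n - k <= order:
                acc += (k / n) * c[k] * a[n - k - 1]
        c[n] = acc
    return c


def _plp(frames: np.ndarray, cfg: FeatureConfig) -> np.ndarray:
    pspec = _power_spectrum(frames, cfg)
    fb, centers = bark_filterbank(cfg.n_barks, cfg)
    bands = np.maximum(pspec @ fb.T, _LOG_FLOOR)
    compressed = (bands * _equal_loudness(centers)) ** 0.33
    # Duplicate edge bands (Hermansky) and invert to autocorrelation.
    ext = np.hstack([compressed[:, :1], compressed, compressed[:, -1:]])
    nb = ext.shape[1]
    lags = np.arange(cfg.plp_order + 1)
    # symmetric spectrum sampled at nb points over [0, pi]
    omega = np.pi * np.arange(nb) / (nb - 1)
    weights = np.ones(nb)
    weights[0] = weights[-1] = 0.5
    cosmat = np.cos(np.outer(lags, omega)) * weights  # (order+1, nb)
    autoc = ext @ cosmat.T / (nb - 1)
    n_ceps = cfg.plp_order + 1
    out = np.zeros((frames.shape[0], n_ceps))
    for t in range(frames.shape[0]):
        r = autoc[t]
        r0 = max(r[0], _LOG_FLOOR)
        try:
            a = solve_toeplitz((r[:-1], r[:-1]), -r[1:])
        except np.linalg.LinAlgError:
            a = np.zeros(cfg.plp_order)
        gain = r0 + float(np.dot(a, r[1:]))
        out[t] = _lpc_to_cepstrum(a, max(gain, _LOG_FLOOR), n_ceps)
    return np.hstack([out, compute_deltas(out), compute_deltas(compute_deltas(out))])


def extract_features(
    waveform: np.ndarray,
    kind: str,
    config: FeatureConfig | None = None,
    *,
    sample_rate: int | None = None,
    utt_id: str = "",
) -> FrameFeatures:
    """Extract 60-d frame-level features of the requested kind.

    44.1 kHz input is resampled to 16 kHz; 16 kHz passes through unchanged.
    """
    cfg = config or FeatureConfig()
    kind = kind.lower()
    if kind not in FEATURE_KINDS:
        raise ArgumentError(f"unknown feature kind {kind!r}; expected one of {FEATURE_KINDS}")
    sr = sample_rate if sample_rate is not None else cfg.sample_rate
    waveform = resample_to_16k(np.asarray(waveform, dtype=np.float64), sr)
    frames = frame_signal(waveform, cfg)
    if kind == "fbank":
        data = _fbank(frames, cfg)
    elif kind == "mfcc":
        data = _mfcc(frames, cfg)
    else:
        data = _plp(frames, cfg)
    if data.shape[1] != FEATURE_DIM:
        raise AssertionError(f"{kind} produced {data.shape[1]} dims, expected {FEATURE_DIM}")
    return FrameFeatures(
        data=data,
        kind=kind,
        utt_id=utt_id,
        frame_shift_s=cfg.frame_shift_s,
        frame_length_s=cfg.frame_length_s,
    )


@dataclass
class VadConfig:
    k_sd: float = 0.5  # threshold at mean - k_sd * sd of frame log-energy
    floor_log_energy: float = -13.8  # ~ -60 dBFS rms; frames below are never voiced
    slack: float = 0.1  # absolute margin (nats) so stationary signals stay voiced


def energy_vad(waveform: np.ndarray, config: VadConfig | None = None, feature_config: FeatureConfig | None = None) -> np.ndarray:
    """Boolean voiced mask per frame from log frame energy.

    A frame is voiced when its log energy is at least (mean - k_sd * sd) over
    the utterance AND above an absolute silence floor. Raises
    :class:`DegenerateUtteranceError` when nothing survives.
    """
    vcfg = config or VadConfig()
    fcfg = feature_config or FeatureConfig()
    x = np.asarray(waveform, dtype=np.float64)
    T = n_frames_snip(x.shape[0], fcfg)
    if T < 1:
        raise ArgumentError("waveform shorter than one frame")
    idx = np.arange(fcfg.frame_length)[None, :] + fcfg.frame_shift * np.arange(T)[:, None]
    energy = np.mean(np.square(x[idx]), axis=1)
    log_e = np.log(np.maximum(energy, 1e-12))
    above_floor = log_e > vcfg.floor_log_energy
    thresh = log_e.mean() - vcfg.k_sd * log_e.std() - vcfg.slack
    mask = (log_e >= thresh) & above_floor
    if not mask.any():
        raise DegenerateUtteranceError("VAD removed every frame")
    return mask


def apply_cmvn(features: FrameFeatures, var_norm: bool | None = None) -> FrameFeatures:
    """Per-utterance cepstral mean (and optionally variance) normalization."""
    if features.n_frames < 2:
        raise ArgumentError("CMVN needs at least 2 frames")
    x = features.data - features.data.mean(axis=0, keepdims=True)
    if var_norm:
        sd = features.data.std(axis=0, keepdims=True)
        x = x / np.maximum(sd, 1e-10)
    return replace(features, data=x)
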
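"""WAV input/output and resampling.

All internal audio is float64 in [-1, 1] at 16 kHz mono. Files are RIFF PCM;
16- and 24-bit widths are read, 16-bit is written.
"""

from __future__ import annotations

import wave
from pathlib import Path

import numpy as np
from scipy.signal import resample_poly

from voxscreen.errors import ArgumentError

TARGET_RATE = 16000
ACCEPTED_RATES = (16000, 44100)


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a mono PCM WAV file. Returns (samples in [-1, 1], sample_rate)."""
    with wave.open(str(path), "rb") as wf:
        n_channels = wf.getnchannels()
        width = wf.getsampwidth()
        rate = wf.getframerate()
        raw = wf.readframes(wf.getnframes())
    if width == 2:
        x = np.frombuffer(raw, dtype="<i2").astype(np.float64) / 32768.0
    elif width == 3:
        b = np.frombuffer(raw, dtype=np.uint8).reshape(-1, 3)
        val = (
            b[:, 0].astype(np.int32)
            | (b[:, 1].astype(np.int32) << 8)
            | (b[:, 2].astype(np.int32) << 16)
        )
        val = np.where(val >= 1 << 23, val - (1 << 24), val)
        x = val.astype(np.float64) / float(1 << 23)
    else:
        raise ArgumentError(f"unsupported sample width: {width * 8} bit")
    if n_channels > 1:
        x = x.reshape(-1, n_channels).mean(axis=1)
    return x, rate


def write_wav(path: str | Path, samples: np.ndarray, rate: int = TARGET_RATE) -> None:
    """Write mono float samples in [-1, 1] as 16-bit PCM."""
    x = np.clip(np.asarray(samples, dtype=np.float64), -1.0, 1.0)
    pcm = np.round(x * 32767.0).astype("<i2")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with wave.open(str(path), "wb") as wf:
        wf.setnchannels(1)
        wf.setsampwidth(2)
        wf.setframerate(rate)
        wf.writeframes(pcm.tobytes())


def resample_to_16k(samples: np.ndarray, rate: int) -> np.ndarray:
    """Resample to 16 kHz. 16 kHz input is returned unchanged (idempotent)."""
    if rate == TARGET_RATE:
        return samples
    if rate == 44100:
        # 16000/44100 = 160/441
        return resample_poly(np.asarray(samples, dtype=np.float64), 160, 441)
    raise ArgumentError(f"unsupported sample rate {rate}; expected one of {ACCEPTED_RATES}")
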
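"""Mono WAV read/write for hydrophone recordings.

Reading goes through :func:`scipy.io.wavfile.read` (handles 16/24/32-bit PCM
and IEEE float); 24-bit PCM writing, which scipy does not support, is done
with the stdlib :mod:`wave` module and numpy byte packing.
"""

from __future__ import annotations

import wave
from pathlib import Path

import numpy as np
from scipy.io import wavfile

_PCM24_MAX = 2**23 - 1


def write_wav(path: str | Path, samples: np.ndarray, sample_rate: int, *, bit_depth: int = 24) -> None:
    """Write normalized samples in [-1, 1) as mono PCM.

    Values outside [-1, 1) are clipped to the representable integer range.
    """
    samples = np.asarray(samples)
    if samples.dtype not in (np.float32, np.float64):
        samples = samples.astype(np.float64)
    if samples.ndim != 1:
        raise ValueError("only mono signals are supported")
    if bit_depth == 24:
        scale, sampwidth = 2**23, 3
    elif bit_depth == 16:
        scale, sampwidth = 2**15, 2
    else:
        raise ValueError(f"unsupported bit depth: {bit_depth}")
    scaled = samples * scale
    np.rint(scaled, out=scaled)
    np.clip(scaled, -scale, scale - 1, out=scaled)
    q = scaled.astype(np.int32)
    if sampwidth == 3:
        # little-endian int32 -> drop the high byte of each sample
        frames = q.astype("<i4").view(np.uint8).reshape(-1, 4)[:, :3].tobytes()
    else:
        frames = q.astype("<i2").tobytes()
    with wave.open(str(path), "wb") as fh:
        fh.setnchannels(1)
        fh.setsampwidth(sampwidth)
        fh.setframerate(int(sample_rate))
        fh.writeframes(frames)


def read_wav(path: str | Path) -> tuple[int, np.ndarray]:
    """Read a mono WAV; return (sample_rate, samples normalized to [-1, 1))."""
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(f"{path}: only mono WAV files are supported")
    if data.dtype == np.int16:
        x = data.astype(np.float64) / 2**15
    elif data.dtype == np.int32:
        # scipy left-justifies 24-bit PCM into int32
        x = data.astype(np.float64) / 2**31
    elif data.dtype.kind == "f":
        x = data.astype(np.float64)
    elif data.dtype == np.uint8:
        x = (data.astype(np.float64) - 128.0) / 128.0
    else:
        raise ValueError(f"{path}: unsupported sample format {data.dtype}")
    return int(rate), x


def wav_info(path: str | Path) -> tuple[int, int]:
    """Return (sample_rate, n_frames) from the header without loading samples."""
    with wave.open(str(path), "rb") as fh:
        return fh.getframerate(), fh.getnframes()
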
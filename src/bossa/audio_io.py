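"""WAV input/output helpers (PCM 16/24/32 and IEEE float)."""

from __future__ import annotations

import logging

import numpy as np
from scipy.io import wavfile

log = logging.getLogger("bossa")


def read_wav(path) -> tuple[np.ndarray, float]:
    """Read a WAV file as float64 in [-1, 1]; returns (audio, fs).

    Integer PCM is scaled by its full-scale value; mono files come back as
    1-D arrays, multichannel as [n_samples, n_channels].
    """
    fs, data = wavfile.read(path)
    if data.dtype == np.uint8:
        audio = (data.astype(np.float64) - 128.0) / 128.0
    elif np.issubdtype(data.dtype, np.integer):
        audio = data.astype(np.float64) / float(np.iinfo(data.dtype).max + 1)
    else:
        audio = data.astype(np.float64)
    return audio, float(fs)


def write_wav(path, audio: np.ndarray, fs: float) -> None:
    """Write IEEE float32 WAV; logs a warning if samples clip |x| > 1."""
    audio = np.asarray(audio, dtype=np.float32)
    peak = float(np.max(np.abs(audio))) if audio.size else 0.0
    if peak > 1.0:
        log.warning("writing %s with clipped samples (peak %.3f > 1)", path, peak)
    wavfile.write(path, int(round(fs)), audio)
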
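"""Short-Time Objective Intelligibility (STOI), classic variant.

An intrusive intelligibility metric in [0, 1] comparing a degraded signal
against its clean reference. Both signals are resampled to 10 kHz, silent
frames (40 dB below the loudest reference frame) are removed, short-time
DFT magnitudes are grouped into 15 one-third-octave bands starting at
150 Hz, and for every band the correlation between clipped, normalized
temporal envelope segments of 384 ms is averaged.

Implemented here from the published definition; the package uses it both
for the model-parameter sweep and the end-to-end benefit checks.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import stft

from .peripheral import resample_to

FS_STOI = 10000
FRAME = 256  # 25.6 ms at 10 kHz, 50% overlap
NFFT = 512
N_BANDS = 15
CF_FIRST = 150.0
SEG = 30  # analysis segment: 30 frames = 384 ms
DYN_RANGE = 40.0  # silent-frame removal threshold, dB
BETA = -15.0  # SDR clipping bound, dB


def _third_octave_matrix() -> np.ndarray:
    """[n_bands, n_bins] 0/1 matrix pooling DFT bins into 1/3-octave bands."""
    f = np.linspace(0, FS_STOI / 2, NFFT // 2 + 1)
    cfs = CF_FIRST * 2.0 ** (np.arange(N_BANDS) / 3.0)
    lo = cfs * 2.0 ** (-1.0 / 6.0)
    hi = cfs * 2.0 ** (1.0 / 6.0)
    H = np.zeros((N_BANDS, len(f)))
    for i in range(N_BANDS):
        H[i, (f >= lo[i]) & (f < hi[i])] = 1.0
    return H


def _remove_silent_frames(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop frames whose reference energy is 40 dB below the loudest frame."""
    w = np.hanning(FRAME + 2)[1:-1]
    hop = FRAME // 2
    n_frames = (len(x) - FRAME) // hop + 1
    if n_frames < 1:
        return x, y
    frames = np.arange(n_frames) * hop
    energies = np.array(
        [20 * np.log10(np.linalg.norm(w * x[i : i + FRAME]) + 1e-30) for i in frames]
    )
    keep = energies >= energies.max() - DYN_RANGE
    xs = np.zeros((keep.sum() + 1) * hop + FRAME)
    ys = np.zeros_like(xs)
    pos = 0
    for i in frames[keep]:
        xs[pos : pos + FRAME] += w * x[i : i + FRAME]
        ys[pos : pos + FRAME] += w * y[i : i + FRAME]
        pos += hop
    return xs[: pos + hop], ys[: pos + hop]


def _band_envelopes(x: np.ndarray, H: np.ndarray) -> np.ndarray:
    """1/3-octave band temporal envelope, [n_bands, n_frames]."""
    w = np.hanning(FRAME + 2)[1:-1]
    _, _, Z = stft(
        x,
        nperseg=FRAME,
        noverlap=FRAME // 2,
        nfft=NFFT,
        window=w,
        boundary=None,
        padded=False,
    )
    return np.sqrt(H @ (np.abs(Z) ** 2))


def stoi(reference: np.ndarray, estimate: np.ndarray, fs: float) -> float:
    """Classic STOI of ``estimate`` against clean ``reference``.

    Inputs must share length; they are resampled internally to 10 kHz.
    Returns a scalar; identical signals score ~1, unrelated noise well
    below 0.2.
    """
    reference = np.asarray(reference, dtype=float).ravel()
    estimate = np.asarray(estimate, dtype=float).ravel()
    if reference.shape != estimate.shape:
        raise ValueError("reference and estimate must share length")
    if fs != FS_STOI:
        reference = resample_to(reference, fs, FS_STOI)
        estimate = resample_to(estimate, fs, FS_STOI)

    reference, estimate = _remove_silent_frames(reference, estimate)
    H = _third_octave_matrix()
    X = _band_envelopes(reference, H)
    Y = _band_envelopes(estimate, H)
    n_frames = X.shape[1]
    if n_frames < SEG:
        raise ValueError("signal too short for STOI (needs >= 384 ms of speech)")

    clip = 10.0 ** (-BETA / 20.0)
    scores = []
    for m in range(SEG, n_frames + 1):
        Xs = X[:, m - SEG : m]
        Ys = Y[:, m - SEG : m]
        # per band: scale the estimate segment to the reference energy, clip
        alpha = np.linalg.norm(Xs, axis=1, keepdims=True) / (
            np.linalg.norm(Ys, axis=1, keepdims=True) + 1e-30
        )
        Yp = np.minimum(Ys * alpha, Xs * (1.0 + clip))
        xm = Xs - Xs.mean(axis=1, keepdims=True)
        ym = Yp - Yp.mean(axis=1, keepdims=True)
        num = (xm * ym).sum(axis=1)
        den = np.linalg.norm(xm, axis=1) * np.linalg.norm(ym, axis=1) + 1e-30
        scores.append(num / den)
    return float(np.mean(scores))


def stoi_binaural(reference: np.ndarray, estimate: np.ndarray, fs: float) -> float:
    """Average per-ear STOI for [n, 2] stereo signals (mono falls through)."""
    reference = np.asarray(reference, dtype=float)
    estimate = np.asarray(estimate, dtype=float)
    if reference.ndim == 1:
        return stoi(reference, estimate, fs)
    return float(
        np.mean([stoi(reference[:, e], estimate[:, e], fs) for e in range(reference.shape[1])])
    )
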
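"""Binaural cue extraction per frequency channel.

Two running cues drive the spatially tuned neurons:

* interaural correlation evaluated at a probe lag — a normalized
  short-time cross-correlation between the left and right narrowband
  signals, with the right channel probed at the neuron's best ITD;
* interaural level difference (ILD) — the dB ratio of exponentially
  smoothed energy envelopes, positive when the left ear is louder.

Both cues are ratios of like quantities and are therefore invariant to
overall stimulus level, which is what the downstream neurons rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .peripheral import Subbands


@dataclass(frozen=True)
class CueParams:
    """Smoothing and guard parameters for cue extraction.

    corr_time_constant, env_time_constant : seconds
        Time constants of the exponential windows used for the running
        correlation and the energy envelope (default 5 ms: several cycles
        at low center frequencies, fast enough to track speech onsets).
    env_floor : dB
        Energy floor (re unit energy) added to both envelopes so that
        digital silence yields 0 correlation and 0 dB ILD. The default is
        low enough (-200 dB) that cues stay invariant to common gains of
        0.01-100 on typical signal levels.
    """

    corr_time_constant: float = 0.005
    env_time_constant: float = 0.005
    env_floor: float = -200.0
    log_envelope: bool = True

    def __post_init__(self) -> None:
        if self.corr_time_constant <= 0 or self.env_time_constant <= 0:
            raise ValueError("time constants must be positive")

    def floor_linear(self) -> float:
        return 10.0 ** (self.env_floor / 10.0)


@dataclass
class CueMap:
    """Time-frequency maps of binaural evidence.

    corr_at_lag : [n_samples, n_channels], in [-1, 1]
        Running interaural correlation at each channel's probe lag.
    ild_db : [n_samples, n_channels]
        Interaural level difference; positive = left ear louder.
    env_left, env_right : [n_samples, n_channels], non-negative
        Smoothed energy envelopes of each ear.
    """

    corr_at_lag: np.ndarray
    ild_db: np.ndarray
    env_left: np.ndarray
    env_right: np.ndarray
    fs: float
    center_freqs: np.ndarray = field(repr=False)


def _exp_smooth(x: np.ndarray, tau: float, fs: float) -> np.ndarray:
    """First-order exponential (leaky-integrator) smoothing along axis 0.

    Output magnitudes below 1e-30 are flushed to zero: the exponential
    decay otherwise runs into subnormal floats during silent stretches,
    which slows hardware arithmetic by orders of magnitude.
    """
    alpha = np.exp(-1.0 / (tau * fs))
    y = lfilter([1.0 - alpha], [1.0, -alpha], x, axis=0)
    y[np.abs(y) < 1e-30] = 0.0
    return y


def energy_envelope(subband: np.ndarray, params: CueParams, fs: float) -> np.ndarray:
    """Smoothed instantaneous energy of a narrowband signal.

    The squared signal is passed through a first-order exponential filter
    of time constant ``params.env_time_constant``; in steady state a
    sinusoid of amplitude A yields A^2/2.
    """
    x = np.asarray(subband, dtype=float)
    return _exp_smooth(x * x, params.env_time_constant, fs)


def _shift(x: np.ndarray, n: int) -> np.ndarray:
    """Advance by n samples (n > 0 shifts earlier); zero-padded."""
    if n == 0:
        return x
    out = np.zeros_like(x)
    if n > 0:
        out[:-n] = x[n:]
    else:
        out[-n:] = x[:n]
    return out


def running_xcorr_at_lag(
    uL: np.ndarray, uR: np.ndarray, lag: float, params: CueParams, fs: float
) -> np.ndarray:
    """Normalized running interaural correlation at one probe lag.

    corr(t) = <uL(t + lag) uR(t)> / sqrt(<uL(t + lag)^2> <uR(t)^2>)

    with <.> an exponential window of ``corr_time_constant``; the lag is
    realized as a shift of the left channel by round(lag * fs) samples, so a
    positive lag probes the configuration where the left ear lags (source on
    the listener's right). Both normalizers are floored so silence maps to 0.
    """
    uL = np.asarray(uL, dtype=float)
    uR = np.asarray(uR, dtype=float)
    if uL.shape != uR.shape:
        raise ValueError("ear signals must share shape")
    if abs(lag) >= 0.002:
        raise ValueError("probe lag must satisfy |lag| < 2 ms")
    n = int(round(lag * fs))
    uLs = _shift(uL, n)
    tau = params.corr_time_constant
    num = _exp_smooth(uLs * uR, tau, fs)
    eL = _exp_smooth(uLs * uLs, tau, fs)
    eR = _exp_smooth(uR * uR, tau, fs)
    floor = params.floor_linear()
    denom = np.sqrt((eL + floor) * (eR + floor))
    return num / denom


def ild_db(envL: np.ndarray, envR: np.ndarray, params: CueParams) -> np.ndarray:
    """Interaural level difference in dB from the two energy envelopes.

    10*log10((envL + floor)/(envR + floor)); positive means the left ear
    is louder. The floor guards digital silence (0 dB) and makes the cue
    exactly invariant to common gain well above the floor.
    """
    envL = np.asarray(envL, dtype=float)
    envR = np.asarray(envR, dtype=float)
    if envL.shape != envR.shape:
        raise ValueError("envelopes must share shape")
    floor = params.floor_linear()
    return 10.0 * np.log10((envL + floor) / (envR + floor))


def shared_cues(subbands: Subbands, params: CueParams = CueParams()) -> tuple:
    """Lag-independent cue components: (env_left, env_right, ild_db).

    The envelopes and the ILD do not depend on the correlation probe lag,
    so when several neuron sets (several lags) read the same scene these
    are computed once and shared.
    """
    fs = subbands.fs
    envL = energy_envelope(subbands.left, params, fs)
    envR = energy_envelope(subbands.right, params, fs)
    return envL, envR, ild_db(envL, envR, params)


def extract_cues(
    subbands: Subbands,
    probe_lag,
    params: CueParams = CueParams(),
    shared: tuple | None = None,
) -> CueMap:
    """Assemble the full cue map for one probe lag (one neuron set).

    Parameters
    ----------
    probe_lag : float or array of length n_channels, seconds
        The best ITD of the spatially tuned neuron set whose evidence is
        being collected; a scalar is broadcast over channels (the model
        treats ITD as frequency-independent) and then evaluated for all
        channels at once.
    shared : optional output of :func:`shared_cues` to reuse across sets.
    """
    n_ch = subbands.n_channels
    fs = subbands.fs
    lags = np.broadcast_to(np.asarray(probe_lag, dtype=float), (n_ch,))
    envL, envR, ild = shared if shared is not None else shared_cues(subbands, params)

    if np.all(lags == lags[0]):
        # common-lag fast path: one matrix shift + three matrix smoothings
        lag = float(lags[0])
        if abs(lag) >= 0.002:
            raise ValueError("probe lag must satisfy |lag| < 2 ms")
        n = int(round(lag * fs))
        uLs = _shift(subbands.left, n)
        tau = params.corr_time_constant
        num = _exp_smooth(uLs * subbands.right, tau, fs)
        eL = _exp_smooth(uLs * uLs, tau, fs)
        eR = _exp_smooth(subbands.right * subbands.right, tau, fs)
        floor = params.floor_linear()
        corr = num / np.sqrt((eL + floor) * (eR + floor))
    else:
        corr = np.empty_like(envL)
        for k in range(n_ch):
            corr[:, k] = running_xcorr_at_lag(
                subbands.left[:, k], subbands.right[:, k], lags[k], params, fs
            )
    return CueMap(
        corr_at_lag=corr,
        ild_db=ild,
        env_left=envL,
        env_right=envR,
        fs=fs,
        center_freqs=subbands.center_freqs,
    )


def save_cuemap_hdf5(cues: CueMap, path) -> None:
    """Dump a CueMap to HDF5 for offline inspection/plotting."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("corr", data=cues.corr_at_lag)
        f.create_dataset("ild_db", data=cues.ild_db)
        f.create_dataset("env_l", data=cues.env_left)
        f.create_dataset("env_r", data=cues.env_right)
        f.attrs["fs"] = cues.fs
        f.attrs["center_freqs"] = np.asarray(cues.center_freqs)
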
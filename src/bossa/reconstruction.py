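"""Spike-to-waveform reconstruction via time-frequency masks.

The spike trains of a spatially tuned neuron set are convolved per channel
with an alpha-function kernel h(t) = t * exp(-t/tau_h) to form a smoothed,
firing-rate-like non-binary mask (FRMask). Lateral-inhibition differencing
of the on-target mask against scaled off-target masks, followed by
rectification, yields the sharpened DiffMask:

    DiffMask = max(FRMask_0 - a * sum_theta FRMask_theta, 0)

with each FRMask first scaled to [0, 1] and a = 0.5 by default. Applying a
mask point-wise to both ears' subbands and summing channels (unweighted)
produces a binaural estimate of the attended source that retains the
natural spatial cues of the scene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve

from .midbrain import SpikeTrains
from .peripheral import Subbands


@dataclass
class Kernel:
    """Sampled alpha-function reconstruction kernel h(t) = t e^{-t/tau_h}."""

    samples: np.ndarray
    tau_h: float
    length: float
    fs: float


@dataclass
class Mask:
    """Non-negative time-frequency gain matrix.

    kind is "frmask" or "diffmask"; theta records which neuron set produced
    it; normalized flags values scaled into [0, 1].
    """

    values: np.ndarray
    kind: str
    theta: float = 0.0
    normalized: bool = False
    fs: float = 0.0

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("mask values must be non-negative")


def alpha_kernel(tau_h: float = 0.020, length: float = 0.100, fs: float = 44100.0) -> Kernel:
    """Alpha-function kernel, h[n] = (n/fs) exp(-(n/fs)/tau_h).

    h[0] = 0 and the maximum falls at t = tau_h (20 ms by default); the
    kernel is truncated at ``length`` (100 ms by default).
    """
    if tau_h <= 0 or length <= 0:
        raise ValueError("tau_h and length must be positive")
    t = np.arange(int(round(length * fs))) / fs
    return Kernel(samples=t * np.exp(-t / tau_h), tau_h=tau_h, length=length, fs=fs)


def _convolve_mask(matrix: np.ndarray, kernel: Kernel) -> np.ndarray:
    out = fftconvolve(matrix, kernel.samples[:, None], axes=0)[: matrix.shape[0]]
    return np.maximum(out, 0.0)  # clip fft round-off below zero


def compute_frmask(spikes: SpikeTrains, kernel: Kernel) -> Mask:
    """FRMask: per-channel causal convolution of spikes with the kernel."""
    if spikes.fs != kernel.fs:
        raise ValueError("spike and kernel sample rates differ")
    values = _convolve_mask(spikes.spikes.astype(float), kernel)
    return Mask(values=values, kind="frmask", theta=spikes.theta, fs=spikes.fs)


def rate_frmask(rate: np.ndarray, kernel: Kernel, theta: float = 0.0) -> Mask:
    """Expected FRMask computed directly from the firing rate.

    Convolving rate/fs with the kernel equals the expectation of the
    spike-based FRMask over Poisson draws, so the deterministic and spiking
    paths agree in the mean.
    """
    values = _convolve_mask(np.asarray(rate, dtype=float) / kernel.fs, kernel)
    return Mask(values=values, kind="frmask", theta=theta, fs=kernel.fs)


def scale_unit(mask: Mask, per_channel: bool = False) -> Mask:
    """Scale a mask into [0, 1] by its global (or per-channel) maximum.

    An all-zero mask is returned unchanged (no division). The default
    global-per-set scaling preserves the spectral profile of the response;
    per-channel scaling equalizes channels instead.
    """
    v = mask.values
    if per_channel:
        peak = v.max(axis=0, keepdims=True)
        scaled = np.divide(v, peak, out=np.zeros_like(v), where=peak > 0)
    else:
        peak = v.max()
        scaled = v / peak if peak > 0 else v.copy()
    return Mask(values=scaled, kind=mask.kind, theta=mask.theta, normalized=True, fs=mask.fs)


def scale_unit_streaming(mask: Mask) -> Mask:
    """Causal [0, 1] scaling by the running maximum seen so far.

    A streaming-friendly alternative to :func:`scale_unit`: each sample is
    divided by the largest mask value observed up to that time, so no
    lookahead over the utterance is needed.
    """
    v = mask.values
    running = np.maximum.accumulate(v.max(axis=1))
    running = np.maximum(running, 1e-30)
    scaled = np.minimum(v / running[:, None], 1.0)
    return Mask(values=scaled, kind=mask.kind, theta=mask.theta, normalized=True, fs=mask.fs)


def compute_diffmask(
    frmask_center: Mask,
    frmasks_off: Sequence[Mask],
    a: float = 0.5,
    per_channel: bool = False,
    prescaled: bool = False,
) -> Mask:
    """Lateral-inhibition mask: max(center - a * sum(off), 0).

    Masks are first scaled to [0, 1] (skip with ``prescaled`` when the
    caller already normalized them against a common reference, e.g. for
    tuning-curve analysis); ``a`` is fixed across frequencies and spatial
    channels.
    """
    for m in frmasks_off:
        if m.values.shape != frmask_center.values.shape:
            raise ValueError("all masks must share shape")
    if prescaled:
        center = frmask_center.values
        off = [m.values for m in frmasks_off]
    else:
        center = scale_unit(frmask_center, per_channel).values
        off = [scale_unit(m, per_channel).values for m in frmasks_off]
    acc = np.zeros_like(center)
    for o in off:
        acc += o
    values = np.maximum(center - a * acc, 0.0)
    return Mask(
        values=values,
        kind="diffmask",
        theta=frmask_center.theta,
        normalized=not per_channel,
        fs=frmask_center.fs,
    )


def apply_mask(mask: Mask, subbands: Subbands, latency_shift: float = 0.0) -> np.ndarray:
    """Apply a mask to both ears and sum channels into a binaural waveform.

    For each ear j: S_j(t) = sum_k mask(t; f_k) * u_j(t; f_k). The same
    mask on both ears cannot alter per-channel interaural ratios, so the
    output retains the scene's spatial cues. A positive ``latency_shift``
    (seconds, typically the kernel's tau_h) advances the mask to undo the
    kernel's rise-time lag; the default applies no compensation.
    """
    v = mask.values
    if v.shape != subbands.left.shape:
        raise ValueError("mask and subbands must share shape")
    if latency_shift > 0:
        shift = int(round(latency_shift * subbands.fs))
        if shift:
            v = np.vstack([v[shift:], np.zeros((shift, v.shape[1]))])
    left = (v * subbands.left).sum(axis=1)
    right = (v * subbands.right).sum(axis=1)
    return np.column_stack([left, right])


def save_mask_hdf5(mask: Mask, path, center_freqs=None) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=mask.values)
        f.attrs["fs"] = mask.fs
        f.attrs["kind"] = mask.kind
        f.attrs["theta"] = mask.theta
        if center_freqs is not None:
            f.attrs["center_freqs"] = np.asarray(center_freqs)
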
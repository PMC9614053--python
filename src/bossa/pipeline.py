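"""End-to-end segregation: stereo mixture in, binaural target estimate out."""

from __future__ import annotations

import numpy as np

from .config import PipelineConfig
from .midbrain import run_midbrain, run_rates
from .peripheral import analyze_binaural, resample_to
from .reconstruction import (
    alpha_kernel,
    apply_mask,
    compute_diffmask,
    compute_frmask,
    rate_frmask,
    scale_unit,
    scale_unit_streaming,
)


def segregate(
    stereo_in: np.ndarray,
    config: PipelineConfig | None = None,
    fs_in: float | None = None,
    use_spikes: bool = True,
    return_masks: bool = False,
    hrtf=None,
    bank=None,
):
    """Run the full pipeline on a stereo mixture.

    Both ears are split into gammatone subbands; every spatially tuned
    neuron set in the bank responds; the on-target (theta closest to 0)
    set's mask — sharpened by lateral inhibition when ``config.mask_kind``
    is "diffmask" — is applied to both ears and the channels are summed
    back into a binaural waveform of the input's length.

    Parameters
    ----------
    stereo_in : [n_samples, 2] array.
    fs_in : sample rate of the input if it differs from the configured
        pipeline rate (the input is then polyphase-resampled).
    use_spikes : route through the Poisson spike generator (the model's
        native path); False uses the deterministic firing rate instead.
    return_masks : also return the dict of per-theta masks and the applied
        mask.
    hrtf, bank : prebuilt HRTF set / neuron bank, to avoid re-deriving the
        best-ILD table when processing many signals under one config.
    """
    config = config or PipelineConfig()
    fs = config.filterbank.fs
    stereo = np.asarray(stereo_in, dtype=float)
    if stereo.ndim != 2 or stereo.shape[1] != 2:
        raise ValueError("expected a [n_samples, 2] stereo input")
    if fs_in is not None and fs_in != fs:
        stereo = resample_to(stereo, fs_in, fs)

    if bank is None:
        hrtf = hrtf if hrtf is not None else config.build_hrtf()
        bank = config.build_bank(hrtf=hrtf)
    subbands = analyze_binaural(stereo, config.filterbank)
    kernel = alpha_kernel(config.kernel.tau_h, config.kernel.length, fs)

    if use_spikes:
        trains = run_midbrain(subbands, bank, config.cues, seed=config.seed)
        masks = {p.theta: compute_frmask(tr, kernel) for p, tr in zip(bank, trains)}
    else:
        rates = run_rates(subbands, bank, config.cues)
        masks = {p.theta: rate_frmask(r, kernel, theta=p.theta) for p, r in zip(bank, rates)}

    center_theta = min(masks, key=lambda th: abs(th))
    if config.mask_kind == "diffmask":
        off = [masks[th] for th in config.diffmask.off_thetas if th in masks]
        if config.diffmask.scale_mode == "streaming":
            center = scale_unit_streaming(masks[center_theta])
            off = [scale_unit_streaming(m) for m in off]
            applied = compute_diffmask(center, off, a=config.diffmask.a, prescaled=True)
        else:
            applied = compute_diffmask(
                masks[center_theta],
                off,
                a=config.diffmask.a,
                per_channel=config.diffmask.scale_mode == "per_channel",
            )
    elif config.mask_kind == "frmask":
        applied = masks[center_theta]
    else:
        raise ValueError(f"unknown mask kind: {config.mask_kind}")

    shift = config.kernel.tau_h if config.diffmask.latency_compensation else 0.0
    out = apply_mask(applied, subbands, latency_shift=shift)
    if return_masks:
        return out, masks, applied
    return out
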
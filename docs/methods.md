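# Methods

This note documents the model as implemented, the parameters that matter,
the synthetic fixtures, and the design choices made where the design was
genuinely open. Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Peripheral stage

Each ear's waveform passes through a bank of 4th-order all-pole gammatone
filters (four cascaded biquads per channel, unit gain at the center
frequency). Center frequencies are uniformly spaced on the ERB-number
scale — the antiderivative of `1/ERB(f)` with `ERB(f) = f/Q + b`,
Q = 9.26449, b = 24.7 Hz — hitting the configured endpoints (defaults
200 Hz and 20 kHz, 64 channels) exactly. The default sample rate is
44.1 kHz; inputs at other rates are polyphase-resampled.

**Channel alignment.** The causal gammatone bank disperses group delay by
~10 ms between the lowest and highest channels, which drops the
correlation between a speech-band input and its unweighted subband sum to
≈0.64. Each channel is therefore delayed by (maximum peak latency − its
own impulse-response peak latency): a causal, per-channel pure delay that
aligns all envelope maxima at one common latency. It is applied
identically to both ears, so interaural cues are untouched, and it raises
the resynthesis correlation to ≈0.99 — which is what makes mask-based
reconstruction meaningful. `align_channels: false` restores the raw bank.

Subnormal filter tails (exponential decay during silence) are flushed to
zero below 1e−30; this is numerically invisible but avoids a
hardware-level slowdown of denormal arithmetic.

## Binaural cues

Per channel, two running cues with 5 ms exponential windows (several
cycles at the lowest center frequencies, fast enough to track speech
onsets; configurable):

* **Interaural correlation at a probe lag** — a normalized short-time
  cross-correlation, the lag realized as an integer-sample shift of the
  left channel. Positive lag probes "left ear lags", i.e. sources on the
  listener's right. Cauchy–Schwarz bounds the value to [−1, 1].
* **ILD** — `10·log10((E_L + ε)/(E_R + ε))` of the smoothed energy
  envelopes; positive = left louder. The floor ε (default −200 dB re unit
  energy) maps digital silence to 0 dB and 0 correlation while leaving
  the cues invariant to common gains of 0.01–100 at working signal
  levels.

Both cues are ratios of like quantities, hence stimulus-level invariant
by construction; no separate gain-control stage is modeled. Envelopes and
ILD are lag-independent and are computed once per scene, shared by all
neuron sets.

## Spatially tuned neurons

One set per preferred azimuth; defaults θ ∈ {0°, ±30°, ±60°} for
segregation and a nine-set bank {0°, ±30°, ±45°, ±60°, ±90°} for tuning
illustrations. Each neuron's best ITD is the frequency-independent
Woodworth delay (head radius 0.0875 m, c = 343 m/s); its best ILD
`ΔE(θ, f_k)` is measured by spatializing one white-noise token through
the configured HRTF at each azimuth and time-averaging the running ILD
per channel (reusing the same token across azimuths makes the table
exactly antisymmetric for symmetric HRTFs).

The subthreshold drive is

    drive = w_itd · max(corr, 0) + w_ild · gate · w_env

with unit mixing weights by default. The correlation is half-wave
rectified (negative correlation is no evidence of an on-axis source). The
ILD term is gated to the neuron's "preset range": nonzero only where the
running ILD is within ±5 dB (configurable) of the best ILD, and there it
equals the energy envelope of the ear ipsilateral to θ (mean of both ears
at θ = 0), normalized by its scene-wide maximum.

The drive maps to a rate through a sigmoid shared by all channels,
`rate = rate_max / (1 + exp(−(drive − s₀)/k))`, ceiling 500 spikes/s.
Neurons with exactly zero drive are silent (no spontaneous activity), so
digital silence produces no spikes. Spikes are Bernoulli draws per sample
with `p = rate/fs` (valid since rate_max ≪ fs), one independent
reproducible substream per neuron set.

**Sigmoid operating point.** `calibrate_sigmoid` implements the simple
rule s₀ = half the maximum drive of the frontal set for an on-target
white-noise probe, k = s₀/4 (≈1.0 and 0.25 for the spherical head). The
shipped defaults (s₀ = 1.25, k = 0.3) were then refined by the same
STOI-guided selection procedure used for the reconstruction parameters:
a midpoint slightly above the correlation-only drive plateau (≈1)
prevents ITD evidence alone from half-saturating every set, which
otherwise inflates off-target leakage.

## Reconstruction

Spike trains convolve per channel with the alpha kernel
`h[n] = (n/fs)·exp(−(n/fs)/τ_h)`, τ_h = 20 ms, truncated at 100 ms. The
resulting FRMask is applied at audio rate; `rate_frmask` provides the
spike-free expectation (the two paths agree in the mean, which the suite
verifies by Monte Carlo). DiffMask follows the printed formula
`max(FRMask₀ − a·Σ FRMask_θ, 0)` with a = 0.5 fixed across frequency and
space. Scaling each mask to [0, 1] is done per set over the whole
utterance (global max over time and frequency); per-channel scaling and a
causal running-max variant are available by configuration, and
tuning-curve analyses normalize by a per-set constant over the whole
azimuth sweep so curve shapes stay comparable.

**Mask latency.** The kernel peaks τ_h = 20 ms after a spike, so an
uncompensated mask lags the acoustic evidence it encodes. By default the
mask is advanced by τ_h before application (a pure shift); this is
measurably better on every fixture (FRMask STOI 0.43 → 0.55 at 0 dB TMR)
and can be disabled (`latency_compensation: false`). The output level is
defined only up to a gain (mask scale is arbitrary); STOI is
gain-invariant, and WAV export warns on clipping.

## Synthetic fixtures

* **Spherical-head HRTF.** Interaural delay = Woodworth ITD split evenly
  across the ears around a common base latency. The far ear gets a
  head-shadow filter with a single-pole lowpass magnitude (cutoff
  10 kHz → 1.6 kHz and broadband attenuation 0 → −4 dB as |θ| goes
  0 → 90°), the near ear a ≤2 dB high shelf. Both are **linear-phase**
  FIRs: a minimum-phase shadow would add a frequency-dependent phase
  delay on the far ear, biasing the effective ITD away from the Woodworth
  value the neurons probe and breaking the peak-at-own-azimuth property
  at ±90°. Azimuths are mirror-exact by construction. Measured sets load
  from SOFA (SimpleFreeFieldHRIR) files via HDF5, restricted to the
  horizontal plane, with nearest-neighbor fallback and resampling.
* **Speech-like talkers.** Harmonic complexes with drifting f0
  (100–300 Hz), three random formant-like resonances, 2–8 Hz amplitude
  modulation, organized into five onset-aligned segments on a grid shared
  across seeds — emulating time-aligned five-word test sentences. Energy
  is confined to 0.2–8 kHz. These capture the spectro-temporal statistics
  the cues operate on, but not phonetic content: STOI numbers on these
  fixtures characterize relative processing quality, not human word
  scores.
* **Mixtures.** Target at 0°, maskers at ±30°/±60°, each masker scaled
  (pre-spatialization, per-source RMS) to the 55 dB SPL reference —
  mapped to digital full scale by the fixed convention
  55 dB SPL ≡ −30 dBFS RMS — and the target to reference + TMR. The
  mixture is the plain sum of the spatialized components; the spatialized
  target alone is the evaluation reference.

## Evaluation

STOI (classic variant: 10 kHz, 15 one-third-octave bands from 150 Hz,
384 ms segments, −15 dB clipping) is implemented in-package and applied
per ear, then averaged, for binaural signals. Tuning curves integrate the
deterministic rates (mode `spikes` counts seeded Poisson spikes instead).
The parameter sweep scores the DiffMask output over seeded fixtures on a
(τ_h, a) grid and flags the argmax.

**Problem sizes.** Audio-bearing tests and the acceptance script use the
speech-band configuration — 64 channels, 200 Hz–8 kHz, 20 kHz sample
rate — with 0.4 s probes, 2 s mixtures, and 10 mixtures per STOI
estimate. The speech band carries all the information STOI evaluates
(its top band is ≈4.3 kHz), and per-channel tuning figures conventionally
show the 200 Hz–8 kHz range; the full-range defaults remain in place for
processing real audio.

## Known limitations

* **Objective vs perceptual benefit.** On these fixtures the DiffMask
  output scores *below* the unprocessed mixture and below FRMask in mean
  STOI (≈0.29 vs 0.39 vs 0.36 at 0 dB TMR over ten mixtures). The
  mechanism is visible in the mask statistics: binarized, the DiffMask
  keeps roughly 17% of time-frequency tiles where an ideal binary mask
  keeps ~42%, because off-target sets respond to a frontal source through
  rectified correlation at the wrong lag (cos(2πf·Δτ) > 0 over most of
  the low-frequency range and in aliasing bands above) and through ILD
  gates that cannot discriminate azimuth at low frequency. The
  subtraction therefore removes target-dominated tiles along with masker
  energy, and STOI — which rewards envelope fidelity — penalizes the
  sparseness that listeners may nevertheless experience as masker
  suppression. An ideal-ratio-mask oracle pushed through the same
  reconstruction scores 0.74–0.85, so the reconstruction path itself is
  not the bottleneck.
* Lateral inhibition can fully silence low-frequency channels even for a
  lone frontal talker; with measured (manikin) HRTFs this is expected
  below ≈300 Hz, where spatial acuity is poorest.
* The spherical-head fixture underestimates the mid-frequency ILDs of a
  real head with pinnae; measured SOFA sets sharpen the ILD gates.
* Cues are computed per channel independently; no across-frequency
  integration, no reverberation, no moving sources, no membrane dynamics
  or refractoriness.
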
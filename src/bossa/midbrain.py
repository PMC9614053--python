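"""Spatially tuned neurons (STNs): from binaural cues to spike trains.

One STN set per preferred azimuth theta holds one neuron per frequency
channel. Each neuron carries a best ITD tau(theta) — frequency-independent,
from the Woodworth spherical-head formula — and a frequency-dependent best
ILD DeltaE(theta, f_k) measured from narrowband noise spatialized through
the configured HRTF. ITD and ILD evidence are combined additively at the
subthreshold level, passed through a sigmoid to an instantaneous firing
rate, and realized as spikes by a Bernoulli-per-sample Poisson generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cues import CueMap, CueParams, extract_cues
from .peripheral import FilterbankSpec, Subbands, analyze, erb_center_frequencies

SPEED_OF_SOUND = 343.0  # m/s
HEAD_RADIUS = 0.0875  # m


def woodworth_itd(
    theta: float, head_radius: float = HEAD_RADIUS, c_sound: float = SPEED_OF_SOUND
) -> float:
    """Woodworth spherical-head ITD for a front-hemifield azimuth.

    tau = (a/c) * (theta + sin theta), theta in radians; positive azimuth
    (listener's right) gives positive tau (left ear lags). The model treats
    ITD as frequency-independent.
    """
    if abs(theta) > 90:
        raise ValueError("azimuth must lie in the front hemifield [-90, 90] deg")
    th = np.deg2rad(theta)
    return (head_radius / c_sound) * (th + np.sin(th))


@dataclass
class STNParams:
    """Parameters of one spatially tuned neuron set (one per azimuth).

    theta : degrees, positive = listener's right.
    best_itd : seconds; the probe lag for the interaural correlation.
    best_ild : dB per channel, length n_channels (DeltaE(theta, f_k)).
    ild_tolerance : dB half-width of the window within which ILD evidence
        is admitted (the neuron's "preset range").
    itd_weight, ild_weight : mixing weights of the two evidence streams.
    sigmoid_midpoint, sigmoid_slope : drive units; shared by all channels.
    rate_max : spikes/s ceiling of the sigmoid.
    """

    theta: float
    best_itd: float
    best_ild: np.ndarray
    ild_tolerance: float = 5.0
    itd_weight: float = 1.0
    ild_weight: float = 1.0
    sigmoid_midpoint: float = 1.0
    sigmoid_slope: float = 0.25
    rate_max: float = 500.0

    def __post_init__(self) -> None:
        self.best_ild = np.asarray(self.best_ild, dtype=float)
        if self.rate_max <= 0 or self.sigmoid_slope <= 0 or self.ild_tolerance <= 0:
            raise ValueError("rate_max, sigmoid_slope, ild_tolerance must be positive")


@dataclass
class SpikeTrains:
    """Binary spike matrix of one STN set at audio rate."""

    spikes: np.ndarray  # [n_samples, n_channels], uint8 in {0, 1}
    fs: float
    theta: float
    seed: int

    def to_events(self) -> np.ndarray:
        """Event list [time_s, channel_index, theta_deg] for raster plots."""
        t_idx, ch = np.nonzero(self.spikes)
        return np.column_stack([t_idx / self.fs, ch, np.full(len(ch), self.theta)])


def derive_ild_table(
    hrtf,
    thetas: Sequence[float],
    spec: FilterbankSpec,
    seed: int = 0,
    duration: float = 0.5,
    cue_params: CueParams | None = None,
) -> np.ndarray:
    """Best-ILD table DeltaE(theta, f_k) in dB, [len(thetas), n_channels].

    For each azimuth, white Gaussian noise is spatialized through the HRTF
    and split into the filterbank's narrowband channels (equivalently,
    narrowband noise per channel placed at that azimuth — the operations
    commute since everything is LTI); the table entry is the time-averaged
    running ILD over the steady state. The same noise token is reused for
    every azimuth so that left/right-symmetric HRTFs yield an exactly
    antisymmetric table.
    """
    from .cues import energy_envelope, ild_db
    from .spatial import spatialize

    cue_params = cue_params or CueParams()
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(int(duration * spec.fs)) * 0.05
    n_ch = spec.n_channels
    table = np.empty((len(thetas), n_ch))
    skip = int(5 * cue_params.env_time_constant * spec.fs)
    for i, th in enumerate(thetas):
        stereo = spatialize(noise, th, hrtf)
        sbL = analyze(stereo[:, 0], spec)
        sbR = analyze(stereo[:, 1], spec)
        envL = energy_envelope(sbL, cue_params, spec.fs)
        envR = energy_envelope(sbR, cue_params, spec.fs)
        table[i] = ild_db(envL, envR, cue_params)[skip:].mean(axis=0)
    return table


def stn_drive(cues: CueMap, params: STNParams) -> np.ndarray:
    """Subthreshold drive of one STN set, [n_samples, n_channels].

    drive = itd_weight * max(corr_at_lag, 0) + ild_weight * ild_evidence

    The ILD evidence is gated: it is nonzero only where the running ILD
    falls within ild_tolerance of the neuron's best ILD, and there it
    equals the normalized energy envelope of the ear ipsilateral to the
    preferred azimuth (mean of both ears for theta = 0). Half-wave
    rectification of the correlation keeps the drive a non-negative
    excitation.
    """
    corr = cues.corr_at_lag
    ild = cues.ild_db
    if ild.shape[1] != len(params.best_ild):
        raise ValueError("cue map and best_ild channel counts differ")
    gate = np.abs(ild - params.best_ild[None, :]) <= params.ild_tolerance
    if params.theta > 0:
        env = cues.env_right
    elif params.theta < 0:
        env = cues.env_left
    else:
        env = 0.5 * (cues.env_left + cues.env_right)
    peak = env.max()
    w = env / peak if peak > 0 else env
    return params.itd_weight * np.maximum(corr, 0.0) + params.ild_weight * gate * w


def activation(drive: np.ndarray, params: STNParams) -> np.ndarray:
    """Sigmoid drive-to-rate nonlinearity, identical for all channels.

    rate = rate_max / (1 + exp(-(drive - midpoint)/slope)), in spikes/s.
    Neurons with exactly zero subthreshold drive are silent (the model has
    no spontaneous activity, so digital silence produces no spikes).
    """
    drive = np.asarray(drive, dtype=float)
    z = (drive - params.sigmoid_midpoint) / params.sigmoid_slope
    with np.errstate(over="ignore"):
        rate = params.rate_max / (1.0 + np.exp(-z))
    rate[drive == 0.0] = 0.0
    return rate


def poisson_spikes(rate: np.ndarray, fs: float, seed: int, theta: float = 0.0) -> SpikeTrains:
    """Bernoulli-per-sample Poisson spike generator.

    Each sample independently spikes with probability rate/fs, which
    requires rate < fs everywhere; reproducible for a given seed.
    """
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0):
        raise ValueError("rates must be non-negative")
    p = rate / fs
    if np.any(p >= 1.0):
        raise ValueError("rate/fs must stay below 1 for the Bernoulli approximation")
    rng = np.random.default_rng(seed)
    spikes = (rng.random(rate.shape) < p).astype(np.uint8)
    return SpikeTrains(spikes=spikes, fs=fs, theta=theta, seed=seed)


def build_stn_bank(
    thetas: Sequence[float],
    hrtf,
    spec: FilterbankSpec,
    ild_table: np.ndarray | None = None,
    seed: int = 0,
    ild_tolerance: float = 5.0,
    sigmoid_midpoint: float = 1.0,
    sigmoid_slope: float = 0.25,
    rate_max: float = 500.0,
) -> list[STNParams]:
    """Construct one STNParams per azimuth, deriving the ILD table if needed."""
    if ild_table is None:
        ild_table = derive_ild_table(hrtf, thetas, spec, seed=seed)
    bank = []
    for i, th in enumerate(thetas):
        bank.append(
            STNParams(
                theta=float(th),
                best_itd=woodworth_itd(th),
                best_ild=ild_table[i],
                ild_tolerance=ild_tolerance,
                sigmoid_midpoint=sigmoid_midpoint,
                sigmoid_slope=sigmoid_slope,
                rate_max=rate_max,
            )
        )
    return bank


def run_rates(
    subbands: Subbands, bank: Sequence[STNParams], cue_params: CueParams = CueParams()
) -> list[np.ndarray]:
    """Deterministic instantaneous firing rates, one matrix per STN set."""
    from .cues import shared_cues

    shared = shared_cues(subbands, cue_params)
    rates = []
    for params in bank:
        cues = extract_cues(subbands, params.best_itd, cue_params, shared=shared)
        rates.append(activation(stn_drive(cues, params), params))
    return rates


def run_midbrain(
    subbands: Subbands,
    bank: Sequence[STNParams],
    cue_params: CueParams = CueParams(),
    seed: int = 0,
) -> list[SpikeTrains]:
    """Full midbrain pass: cues -> drive -> rate -> Poisson spikes per theta.

    Each theta draws from an independent substream of the given seed so the
    sets are mutually independent yet jointly reproducible.
    """
    rates = run_rates(subbands, bank, cue_params)
    out = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(bank))
    for params, rate, child in zip(bank, rates, children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        out.append(poisson_spikes(rate, subbands.fs, sub_seed, theta=params.theta))
    return out


def calibrate_sigmoid(
    hrtf,
    spec: FilterbankSpec,
    cue_params: CueParams = CueParams(),
    duration: float = 0.5,
    seed: int = 12345,
) -> tuple[float, float]:
    """Pick sigmoid (midpoint, slope) from an on-target diotic noise probe.

    The midpoint is set to half the maximum drive the 0-degree set sees for
    a frontal white-noise probe, and the slope to midpoint/4, placing the
    operating point mid-dynamic-range. Returns (midpoint, slope).
    """
    from .spatial import spatialize

    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(int(duration * spec.fs)) * 0.05
    stereo = spatialize(noise, 0.0, hrtf)
    sb = Subbands(
        left=analyze(stereo[:, 0], spec),
        right=analyze(stereo[:, 1], spec),
        fs=spec.fs,
        center_freqs=erb_center_frequencies(spec),
    )
    ild_table = derive_ild_table(hrtf, [0.0], spec, seed=seed)
    probe = STNParams(theta=0.0, best_itd=0.0, best_ild=ild_table[0])
    cues = extract_cues(sb, 0.0, cue_params)
    drive = stn_drive(cues, probe)
    s0 = 0.5 * float(drive.max())
    return s0, s0 / 4.0


def spikes_to_csv(trains: SpikeTrains, path) -> None:
    """Write an event list (time_s, channel_index, theta_deg) as CSV."""
    np.savetxt(
        path,
        trains.to_events(),
        delimiter=",",
        header="time_s,channel_index,theta_deg",
        comments="",
        fmt=["%.6f", "%d", "%.1f"],
    )


def save_spikes_hdf5(trains: SpikeTrains, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("spikes", data=trains.spikes, compression="gzip")
        f.attrs["fs"] = trains.fs
        f.attrs["theta"] = trains.theta
        f.attrs["seed"] = trains.seed


def ild_table_to_csv(table: np.ndarray, thetas, center_freqs, path) -> None:
    """Cache a DeltaE table as CSV (rows: theta; columns: center frequency)."""
    header = "theta_deg," + ",".join(f"{f:.1f}" for f in center_freqs)
    body = np.column_stack([np.asarray(thetas, dtype=float), table])
    np.savetxt(path, body, delimiter=",", header=header, comments="", fmt="%.4f")


def ild_table_from_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a cached DeltaE table; returns (thetas, table)."""
    body = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return body[:, 0], body[:, 1:]
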
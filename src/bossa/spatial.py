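"""Spatial audio fixtures: HRTFs, spatialization, and test-signal generators.

Everything needed to exercise the segregation pipeline without measured
data: a spherical-head synthetic HRTF (Woodworth interaural delay plus a
frequency-dependent head-shadow model), a reader for measured HRTFs in
SOFA SimpleFreeFieldHRIR form, binaural spatialization by convolution, and
deterministic generators for white-noise probes, speech-like signals, and
the five-source cocktail-party mixture geometry (frontal target, four
maskers at +/-30 and +/-60 degrees).

Azimuth convention: positive = listener's right; for a source on the right
the left ear lags and is shadowed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve, lfilter

from .midbrain import woodworth_itd

# digital level convention: 55 dB SPL reference maps to -30 dBFS RMS
SPL_REFERENCE_DB = 55.0
DBFS_AT_REFERENCE = -30.0


def spl_to_rms(level_db_spl: float) -> float:
    """Digital RMS amplitude for a nominal SPL, by the fixed convention."""
    dbfs = DBFS_AT_REFERENCE + (level_db_spl - SPL_REFERENCE_DB)
    return 10.0 ** (dbfs / 20.0)


@dataclass
class HRTFSet:
    """Azimuth-indexed pairs of ear impulse responses.

    impulse_responses[azimuth] is a [n_taps, 2] array (left, right).
    """

    azimuths: list
    impulse_responses: dict
    fs: float
    source_kind: str = "spherical_model"

    def get(self, theta: float) -> np.ndarray:
        key = float(theta)
        if key in self.impulse_responses:
            return self.impulse_responses[key]
        # nearest-neighbor fallback for unmeasured directions
        arr = np.asarray(self.azimuths, dtype=float)
        nearest = float(arr[np.argmin(np.abs(arr - key))])
        import warnings

        warnings.warn(
            f"azimuth {theta} deg not in HRTF set; using nearest {nearest} deg"
        )
        return self.impulse_responses[nearest]


def _linear_phase_fir(gain_of_f, fs: float, numtaps: int = 255) -> np.ndarray:
    """Symmetric (linear-phase) FIR matching a magnitude response.

    Linear phase keeps the interaural *phase* relation of the synthetic
    HRTF a pure Woodworth delay at all frequencies: a minimum-phase shadow
    filter would add a frequency-dependent phase delay on the far ear and
    bias the effective ITD away from the spherical-head value.
    """
    from scipy.signal import firwin2

    f = np.linspace(0.0, fs / 2.0, 128)
    return firwin2(numtaps, f, gain_of_f(f), fs=fs)


def spherical_hrtf(
    theta: float,
    head_radius: float = 0.0875,
    fs: float = 44100.0,
    n_taps: int = 512,
    numtaps_fir: int = 255,
) -> np.ndarray:
    """Synthetic ear-pair impulse responses for a spherical head, [n_taps, 2].

    The interaural delay is the Woodworth ITD split evenly between the two
    ears around a common base latency. The contralateral (far) ear receives
    a head-shadow lowpass with a single-pole magnitude response whose
    cutoff falls, and whose broadband attenuation grows, with |theta|; the
    ipsilateral ear receives a mild high-shelf boost. Both shaping filters
    are linear-phase, so the interaural time relation is the pure Woodworth
    delay at every frequency. At theta = 0 both ears are identical.
    """
    if abs(theta) > 90:
        raise ValueError("azimuth must lie in the front hemifield [-90, 90] deg")
    itd = woodworth_itd(theta, head_radius=head_radius)
    half = itd * fs / 2.0
    base_delay = (n_taps - numtaps_fir) // 2
    # positive theta: source on the right, left ear lags
    delay_l = base_delay + int(round(half))
    delay_r = base_delay - int(round(half))

    s = abs(np.sin(np.deg2rad(theta)))
    center = np.zeros(numtaps_fir)
    center[numtaps_fir // 2] = 1.0  # pure delay, exactly identical ears at 0 deg
    if s == 0.0:
        shadow = near = center
    else:
        # far ear: |H| = atten / sqrt(1 + (f/fc)^2), cutoff 10 kHz -> 1.6 kHz
        # and broadband attenuation 0 -> -4 dB as |theta| goes 0 -> 90
        cutoff = 10000.0 * (1.0 - 0.84 * s)
        atten = 10.0 ** (-4.0 * s / 20.0)
        shadow = _linear_phase_fir(
            lambda f: atten / np.sqrt(1.0 + (f / cutoff) ** 2), fs, numtaps_fir
        )
        # near ear: mild high-shelf, +2 dB at most, rising around 4 kHz
        g = 10.0 ** (2.0 * s / 20.0) - 1.0
        near = _linear_phase_fir(
            lambda f: 1.0 + g * (1.0 - 1.0 / np.sqrt(1.0 + (f / 4000.0) ** 2)), fs, numtaps_fir
        )

    irs = np.zeros((n_taps, 2))
    delay_far = delay_l if theta > 0 else delay_r
    delay_near = delay_r if theta > 0 else delay_l
    far, near_idx = (0, 1) if theta > 0 else (1, 0)
    if theta == 0:
        delay_far, delay_near = delay_l, delay_r
    irs[delay_far : delay_far + numtaps_fir, far] = shadow
    irs[delay_near : delay_near + numtaps_fir, near_idx] = near
    return irs


def make_spherical_hrtf_set(
    azimuths: Sequence[float] = (0, 30, -30, 45, -45, 60, -60, 90, -90),
    head_radius: float = 0.0875,
    fs: float = 44100.0,
) -> HRTFSet:
    """Spherical-model HRTFSet covering the demo azimuth grid."""
    irs = {
        float(th): spherical_hrtf(th, head_radius=head_radius, fs=fs)
        for th in azimuths
    }
    return HRTFSet(
        azimuths=[float(t) for t in azimuths],
        impulse_responses=irs,
        fs=fs,
        source_kind="spherical_model",
    )


def load_sofa(path, fs_out: float | None = None) -> HRTFSet:
    """Load a SOFA SimpleFreeFieldHRIR file as an HRTFSet.

    SOFA files are HDF5 containers; the relevant variables are Data.IR
    [n_measurements, 2, n_taps], SourcePosition [n_measurements, 3]
    (azimuth deg, elevation deg, distance) and Data.SamplingRate. Only
    horizontal-plane measurements (|elevation| <= 5 deg) are kept, with
    SOFA's counterclockwise 0-360 azimuth mapped to the signed convention
    used here (positive = right). IRs are resampled to ``fs_out`` when given.
    """
    import h5py

    from .peripheral import resample_to

    try:
        f = h5py.File(path, "r")
    except OSError as e:
        raise ValueError(f"not a readable SOFA/HDF5 file: {path}") from e
    with f:
        if "Data.IR" not in f or "SourcePosition" not in f:
            raise ValueError("missing Data.IR/SourcePosition: not SimpleFreeFieldHRIR")
        ir = np.asarray(f["Data.IR"])
        pos = np.asarray(f["SourcePosition"])
        fs = float(np.asarray(f["Data.SamplingRate"]).reshape(-1)[0])
    if ir.ndim != 3 or ir.shape[1] != 2:
        raise ValueError("Data.IR must be [measurements, 2 ears, taps]")

    horizontal = np.abs(pos[:, 1]) <= 5.0
    irs: dict = {}
    azis: list = []
    for m in np.nonzero(horizontal)[0]:
        az = pos[m, 0] % 360.0
        # SOFA azimuth is counterclockwise from front: 90 = left.
        signed = -az if az <= 180 else 360.0 - az
        if abs(signed) > 90 + 1e-9:
            continue  # rear hemifield sources are out of scope
        pair = ir[m].T  # [n_taps, 2]
        if fs_out is not None and fs_out != fs:
            pair = resample_to(pair, fs, fs_out)
        key = float(round(signed, 3))
        irs[key] = pair
        azis.append(key)
    if not irs:
        raise ValueError("no horizontal-plane measurements found in SOFA file")
    return HRTFSet(
        azimuths=sorted(irs),
        impulse_responses=irs,
        fs=fs_out or fs,
        source_kind="sofa_file",
    )


def spatialize(mono: np.ndarray, theta: float, hrtf: HRTFSet) -> np.ndarray:
    """Convolve a mono source with the ear pair for one azimuth.

    Returns [n_samples, 2]; the full convolution is trimmed to the input
    length so sources of equal length stay summable.
    """
    mono = np.asarray(mono, dtype=float)
    if mono.ndim != 1:
        raise ValueError("spatialize expects a mono source")
    pair = hrtf.get(theta)
    n = len(mono)
    out = np.empty((n, 2))
    for ear in (0, 1):
        out[:, ear] = fftconvolve(mono, pair[:, ear])[:n]
    return out


def white_noise(duration: float, fs: float, seed: int, rms: float = 0.05) -> np.ndarray:
    """Gaussian white-noise probe of a given RMS, reproducible by seed."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(int(round(duration * fs)))
    return x * (rms / np.sqrt(np.mean(x**2)))


def synth_speechlike(
    duration: float,
    seed: int,
    fs: float = 44100.0,
    n_segments: int = 5,
) -> np.ndarray:
    """Deterministic speech-like mono signal.

    A harmonic complex with a slowly drifting fundamental (100-300 Hz),
    shaped by three drifting formant-like resonances, amplitude-modulated
    at syllabic rates (2-8 Hz), and organized into ``n_segments`` onset
    segments on a fixed grid — a stand-in for time-aligned five-word test
    sentences. Long-term spectrum lies within 0.2-8 kHz. The onset grid is
    identical across seeds, so concurrently generated talkers are
    word-aligned by construction.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    # drifting f0: random-walk-ish sum of slow sinusoids within 100-300 Hz
    f0 = 200.0 + 60.0 * np.sin(2 * np.pi * rng.uniform(0.2, 0.6) * t + rng.uniform(0, 2 * np.pi))
    f0 += 40.0 * np.sin(2 * np.pi * rng.uniform(0.7, 1.3) * t + rng.uniform(0, 2 * np.pi))
    phase = 2 * np.pi * np.cumsum(f0) / fs

    # harmonic stack up to 8 kHz with formant-like spectral weighting
    formants = rng.uniform([300, 900, 1900], [800, 1700, 3000])
    bw = np.array([120.0, 180.0, 250.0])
    x = np.zeros(n)
    for h in range(1, 41):
        fh = h * f0
        if np.min(fh) > 8000:
            break
        w = np.zeros(n)
        for fc, b in zip(formants, bw):
            w += np.exp(-0.5 * ((fh - fc) / (3 * b)) ** 2)
        w += 0.05
        w[fh > 8000] = 0.0
        x += w * np.sin(h * phase + rng.uniform(0, 2 * np.pi))

    # syllabic amplitude modulation, 2-8 Hz
    fm = rng.uniform(2.0, 8.0)
    am = 0.55 + 0.45 * np.sin(2 * np.pi * fm * t + rng.uniform(0, 2 * np.pi))

    # fixed segment grid: common onsets across seeds (word alignment)
    seg = np.ones(n)
    seg_len = n // n_segments
    ramp = max(int(0.02 * fs), 2)
    gap = max(int(0.04 * fs), 2)
    for i in range(n_segments):
        a = i * seg_len
        seg[a : a + gap] = 0.0
        rise = min(ramp, n - a - gap)
        seg[a + gap : a + gap + rise] *= np.linspace(0, 1, rise)
    x = x * am * seg
    return x / np.sqrt(np.mean(x**2) + 1e-30) * 0.05


@dataclass
class MixtureSpec:
    """Geometry and levels of the five-source cocktail-party fixture.

    The target sits at ``target_azimuth``; each masker is scaled to the
    common reference level (55 dB SPL nominal) and the target to reference
    + tmr_db, all pre-spatialization on per-source RMS.
    """

    target_azimuth: float = 0.0
    masker_azimuths: tuple = (30.0, -30.0, 60.0, -60.0)
    tmr_db: float = 0.0
    masker_level_db_spl: float = SPL_REFERENCE_DB
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.masker_azimuths) == 0:
            pass  # target-only mixtures are allowed (used for transparency checks)
        if self.target_azimuth in self.masker_azimuths:
            raise ValueError("masker azimuths must differ from the target azimuth")


def make_mixture(
    spec: MixtureSpec, hrtf: HRTFSet, sources: Sequence[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble a spatial mixture; returns (stereo mixture, stereo clean target).

    sources[0] is the target; sources[1:] are the maskers, matched to
    ``spec.masker_azimuths`` in order. All sources must share length.
    Levels are set pre-spatialization: maskers to the reference RMS and the
    target to reference + tmr_db. The clean reference is the spatialized
    target alone at its in-mixture level.
    """
    if len(sources) != 1 + len(spec.masker_azimuths):
        raise ValueError("need one target plus one source per masker azimuth")
    lengths = {len(s) for s in sources}
    if len(lengths) != 1:
        raise ValueError("all sources must share duration")

    ref_rms = spl_to_rms(spec.masker_level_db_spl)
    target_rms = ref_rms * 10.0 ** (spec.tmr_db / 20.0)

    def scaled(x, rms):
        return np.asarray(x, dtype=float) * (rms / np.sqrt(np.mean(np.square(x)) + 1e-30))

    target = spatialize(scaled(sources[0], target_rms), spec.target_azimuth, hrtf)
    mixture = target.copy()
    for src, az in zip(sources[1:], spec.masker_azimuths):
        mixture += spatialize(scaled(src, ref_rms), az, hrtf)
    return mixture, target


def default_mixture(
    spec: MixtureSpec, hrtf: HRTFSet, duration: float = 2.0, fs: float = 44100.0
) -> tuple[np.ndarray, np.ndarray]:
    """Five speech-like talkers in the standard geometry, seeded by spec.seed."""
    ss = np.random.SeedSequence(spec.seed)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(1 + len(spec.masker_azimuths))]
    sources = [synth_speechlike(duration, s, fs=fs) for s in seeds]
    return make_mixture(spec, hrtf, sources)


def mixture_manifest_csv(spec: MixtureSpec, path) -> None:
    """Write the fixture manifest (source index, azimuth, level, seed)."""
    rows = [(0, spec.target_azimuth, spec.masker_level_db_spl + spec.tmr_db, spec.seed)]
    for i, az in enumerate(spec.masker_azimuths, start=1):
        rows.append((i, az, spec.masker_level_db_spl, spec.seed))
    np.savetxt(
        path,
        np.asarray(rows, dtype=float),
        delimiter=",",
        header="source_index,azimuth_deg,level_db_spl,seed",
        comments="",
        fmt="%.1f",
    )
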
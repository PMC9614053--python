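"""Spatial fixtures: spherical HRTF, SOFA loading, generators, mixtures."""

import numpy as np
import pytest

from bossa import (
    MixtureSpec,
    make_mixture,
    spatialize,
    spherical_hrtf,
    synth_speechlike,
    white_noise,
    woodworth_itd,
)
from bossa.spatial import load_sofa, make_spherical_hrtf_set, spl_to_rms

FS = 20000.0


class TestSphericalHrtf:
    def test_frontal_ears_identical(self):
        irs = spherical_hrtf(0.0, fs=FS)
        assert np.array_equal(irs[:, 0], irs[:, 1])

    def test_interaural_delay_matches_woodworth(self):
        """Broadband delay between ears at 90 degrees equals the Woodworth
        ITD within one sample."""
        irs = spherical_hrtf(90.0, fs=FS)
        x = white_noise(0.2, FS, seed=0)
        l = np.convolve(x, irs[:, 0])
        r = np.convolve(x, irs[:, 1])
        xc = np.correlate(l, r, mode="full")
        lag = np.argmax(xc) - (len(l) - 1)
        assert abs(lag - woodworth_itd(90.0) * FS) <= 1.0

    def test_rear_hemifield_rejected(self):
        with pytest.raises(ValueError):
            spherical_hrtf(135.0, fs=FS)

    def test_head_shadow_ild_grows_with_frequency(self, hrtf, speech_spec):
        """|ILD| of a 60-degree source is larger in the 8 kHz channel than
        in the 500 Hz channel (the far-ear shadow is a lowpass)."""
        from bossa import CueParams, analyze_binaural
        from bossa.cues import energy_envelope, ild_db
        from bossa.peripheral import erb_center_frequencies

        stereo = spatialize(white_noise(0.3, FS, seed=1), 60.0, hrtf)
        sb = analyze_binaural(stereo, speech_spec)
        cp = CueParams()
        ild = ild_db(
            energy_envelope(sb.left, cp, FS), energy_envelope(sb.right, cp, FS), cp
        )[int(0.05 * FS) :].mean(axis=0)
        cf = erb_center_frequencies(speech_spec)
        k500 = int(np.argmin(np.abs(cf - 500)))
        k8k = int(np.argmin(np.abs(cf - 8000)))
        assert abs(ild[k8k]) > abs(ild[k500])


class TestSpatialize:
    def test_frontal_spherical_ears_equal(self, hrtf, rng):
        x = rng.standard_normal(2000)
        out = spatialize(x, 0.0, hrtf)
        assert np.allclose(out[:, 0], out[:, 1], atol=1e-12)

    def test_mirror_symmetry(self, hrtf, rng):
        x = rng.standard_normal(2000)
        assert np.allclose(spatialize(x, -45.0, hrtf), spatialize(x, 45.0, hrtf)[:, ::-1])

    def test_output_length_equals_input(self, hrtf, rng):
        x = rng.standard_normal(1234)
        assert spatialize(x, 30.0, hrtf).shape == (1234, 2)

    def test_energy_bounded_by_filter_gain(self, hrtf, rng):
        x = rng.standard_normal(4000)
        out = spatialize(x, 60.0, hrtf)
        pair = hrtf.get(60.0)
        for ear in (0, 1):
            bound = (x**2).sum() * (np.abs(pair[:, ear]).sum()) ** 2
            assert (out[:, ear] ** 2).sum() <= bound


class TestSofa:
    @pytest.fixture()
    def sofa_path(self, tmp_path, hrtf):
        """Synthetic SOFA (SimpleFreeFieldHRIR layout) built from the
        spherical-model IR pairs; stands in for a measured set."""
        import h5py

        azis = [0.0, 30.0, -30.0, 90.0]
        n_taps = hrtf.get(0.0).shape[0]
        ir = np.stack([hrtf.get(a).T for a in azis])  # [m, 2, taps]
        pos = np.array([[(-a) % 360.0, 0.0, 1.5] for a in azis])  # SOFA: ccw azimuth
        path = tmp_path / "synthetic_kemar_standin.sofa"
        with h5py.File(path, "w") as f:
            f.create_dataset("Data.IR", data=ir)
            f.create_dataset("SourcePosition", data=pos)
            f.create_dataset("Data.SamplingRate", data=np.array([FS]))
        return path

    def test_round_trip_uses_measurement_exactly(self, sofa_path, hrtf):
        loaded = load_sofa(sofa_path)
        assert loaded.source_kind == "sofa_file"
        assert np.allclose(loaded.get(30.0), hrtf.get(30.0))

    def test_resampling_scales_ir_length(self, sofa_path):
        loaded = load_sofa(sofa_path, fs_out=2 * FS)
        assert loaded.fs == 2 * FS
        n_orig = load_sofa(sofa_path).get(0.0).shape[0]
        assert loaded.get(0.0).shape[0] == pytest.approx(2 * n_orig, abs=2)

    def test_non_sofa_file_rejected(self, tmp_path):
        bad = tmp_path / "not_a_sofa.sofa"
        bad.write_text("plain text")
        with pytest.raises(ValueError):
            load_sofa(bad)

    def test_missing_azimuth_falls_back_with_warning(self, sofa_path):
        loaded = load_sofa(sofa_path)
        with pytest.warns(UserWarning):
            loaded.get(47.0)


class TestSpeechlike:
    def test_deterministic_given_seed(self):
        a = synth_speechlike(0.5, seed=3, fs=FS)
        b = synth_speechlike(0.5, seed=3, fs=FS)
        assert np.array_equal(a, b)

    def test_different_seeds_decorrelate(self):
        """Peak normalized cross-correlation between talkers < 0.5 over
        10 seed pairs."""
        peaks = []
        for s in range(10):
            a = synth_speechlike(0.5, seed=s, fs=FS)
            b = synth_speechlike(0.5, seed=s + 100, fs=FS)
            c = np.correlate(a, b, mode="full")
            peaks.append(np.max(np.abs(c)) / np.sqrt((a**2).sum() * (b**2).sum()))
        assert max(peaks) < 0.5

    def test_modulation_spectrum_peaks_at_syllabic_rates(self):
        """Envelope modulation energy concentrates in 2-8 Hz."""
        from scipy.signal import hilbert

        acc = np.zeros(0)
        x = synth_speechlike(2.0, seed=5, fs=FS)
        env = np.abs(hilbert(x))
        env = env - env.mean()
        spec = np.abs(np.fft.rfft(env)) ** 2
        freqs = np.fft.rfftfreq(len(env), 1 / FS)
        band = lambda lo, hi: spec[(freqs >= lo) & (freqs < hi)].sum()
        assert band(2, 8) > band(8, 20)
        assert band(2, 8) > band(0.25, 2)

    def test_spectrum_within_speech_band(self):
        x = synth_speechlike(1.0, seed=9, fs=FS)
        spec = np.abs(np.fft.rfft(x)) ** 2
        freqs = np.fft.rfftfreq(len(x), 1 / FS)
        assert spec[freqs > 8500].sum() < 0.01 * spec.sum()


class TestMakeMixture:
    def _sources(self, n, dur=0.5):
        return [synth_speechlike(dur, seed=s, fs=FS) for s in range(n)]

    def test_tmr_zero_equalizes_rms(self, hrtf):
        spec = MixtureSpec(tmr_db=0.0, seed=0)
        ref = spl_to_rms(spec.masker_level_db_spl)
        # target pre-spatialization RMS equals each masker's reference RMS
        assert ref * 10 ** (spec.tmr_db / 20.0) == ref

    def test_no_maskers_mixture_is_target(self, hrtf):
        spec = MixtureSpec(masker_azimuths=(), tmr_db=5.0)
        src = self._sources(1)
        mix, clean = make_mixture(spec, hrtf, src)
        assert np.array_equal(mix, clean)

    def test_default_geometry_five_sources(self):
        spec = MixtureSpec()
        assert spec.target_azimuth == 0.0
        assert sorted(spec.masker_azimuths) == [-60.0, -30.0, 30.0, 60.0]

    def test_additivity_of_components(self, hrtf):
        """The mixture equals the sum of the individually spatialized,
        individually scaled components (no hidden normalization)."""
        spec = MixtureSpec(tmr_db=3.0, seed=0)
        srcs = self._sources(5)
        mix, clean = make_mixture(spec, hrtf, srcs)
        ref = spl_to_rms(spec.masker_level_db_spl)

        def scaled(x, rms):
            return x * rms / np.sqrt(np.mean(x**2))

        acc = spatialize(scaled(srcs[0], ref * 10 ** (spec.tmr_db / 20)), 0.0, hrtf)
        for s, az in zip(srcs[1:], spec.masker_azimuths):
            acc = acc + spatialize(scaled(s, ref), az, hrtf)
        assert np.allclose(mix, acc, atol=1e-9)

    def test_duration_mismatch_rejected(self, hrtf):
        srcs = self._sources(4) + [synth_speechlike(0.3, seed=99, fs=FS)]
        with pytest.raises(ValueError):
            make_mixture(MixtureSpec(), hrtf, srcs)

    def test_masker_at_target_azimuth_rejected(self):
        with pytest.raises(ValueError):
            MixtureSpec(masker_azimuths=(0.0, 30.0))
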
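"""Mask construction and application: alpha kernel, FRMask, DiffMask."""

import numpy as np
import pytest

from bossa import (
    Mask,
    SpikeTrains,
    alpha_kernel,
    apply_mask,
    compute_diffmask,
    compute_frmask,
    rate_frmask,
    scale_unit,
    scale_unit_streaming,
)

FS = 20000.0


class TestAlphaKernel:
    def test_starts_at_zero(self):
        assert alpha_kernel(fs=FS).samples[0] == 0.0

    def test_peak_at_tau_h(self):
        k = alpha_kernel(tau_h=0.020, fs=FS)
        assert int(np.argmax(k.samples)) == int(round(0.020 * FS))

    def test_default_length_100ms(self):
        assert len(alpha_kernel(fs=FS).samples) == int(round(0.100 * FS))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            alpha_kernel(tau_h=-1.0, fs=FS)
        with pytest.raises(ValueError):
            alpha_kernel(length=0.0, fs=FS)


def _train(spike_array, theta=0.0):
    return SpikeTrains(spikes=spike_array.astype(np.uint8), fs=FS, theta=theta, seed=0)


class TestFrMask:
    def test_no_spikes_zero_mask(self):
        k = alpha_kernel(fs=FS)
        m = compute_frmask(_train(np.zeros((500, 3))), k)
        assert m.kind == "frmask" and not m.values.any()

    def test_single_spike_stamps_kernel(self):
        k = alpha_kernel(fs=FS)
        sp = np.zeros((4000, 3))
        n0 = 100
        sp[n0, 1] = 1
        m = compute_frmask(_train(sp), k)
        seg = m.values[n0 : n0 + len(k.samples), 1]
        assert np.allclose(seg, k.samples[: len(seg)], atol=1e-12)
        assert not m.values[:, 0].any() and not m.values[:, 2].any()

    def test_superposition_of_disjoint_trains(self, rng):
        k = alpha_kernel(fs=FS)
        a = (rng.random((3000, 2)) < 0.01).astype(float)
        b = (rng.random((3000, 2)) < 0.01).astype(float)
        b[a > 0] = 0  # keep the trains disjoint so the sum stays binary
        lhs = compute_frmask(_train(a + b), k).values
        rhs = compute_frmask(_train(a), k).values + compute_frmask(_train(b), k).values
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_fs_mismatch_rejected(self):
        k = alpha_kernel(fs=44100.0)
        with pytest.raises(ValueError):
            compute_frmask(_train(np.zeros((10, 1))), k)


class TestRateFrMask:
    def test_zero_rate(self):
        k = alpha_kernel(fs=FS)
        assert not rate_frmask(np.zeros((100, 2)), k).values.any()

    def test_constant_rate_plateau(self):
        """For constant rate lambda the mask plateaus at (lambda/fs) * sum(h)."""
        k = alpha_kernel(fs=FS)
        lam = 80.0
        n = int(0.5 * FS)
        m = rate_frmask(np.full((n, 1), lam), k)
        plateau = (lam / FS) * k.samples.sum()
        assert m.values[len(k.samples) :, 0] == pytest.approx(plateau, rel=1e-6)

    def test_expectation_of_spike_path(self):
        """Mean spike-based FRMask over 100 seeds matches the rate-based
        mask within 3 Monte-Carlo standard errors (averaged over tiles)."""
        from bossa import poisson_spikes

        k = alpha_kernel(fs=FS)
        rng = np.random.default_rng(987656)  # distinct from every spike seed
        rate = rng.random((2000, 4)) * 300.0
        expected = rate_frmask(rate, k).values
        n_seeds = 100
        acc = np.zeros_like(expected)
        acc_sq = np.zeros_like(expected)
        for s in range(n_seeds):
            v = compute_frmask(poisson_spikes(rate, FS, seed=s), k).values
            acc += v
            acc_sq += v**2
        mean = acc / n_seeds
        var = acc_sq / n_seeds - mean**2
        se = np.sqrt(np.maximum(var, 1e-30) / n_seeds)
        active = expected > expected.max() * 0.1
        z = np.abs(mean - expected)[active] / np.maximum(se[active], 1e-12)
        assert np.mean(z) <= 3.0


class TestDiffMask:
    def _unit(self, shape, val=1.0):
        return Mask(values=np.full(shape, val), kind="frmask", fs=FS)

    def test_printed_formula_with_four_unit_masks(self):
        """center 1, four off-masks 1, a = 0.5: max(1 - 0.5*4, 0) = 0."""
        c = self._unit((10, 3))
        off = [self._unit((10, 3)) for _ in range(4)]
        dm = compute_diffmask(c, off, a=0.5)
        assert not dm.values.any()
        assert dm.kind == "diffmask"

    def test_zero_off_masks_passthrough(self, rng):
        c = Mask(values=rng.random((20, 4)), kind="frmask", fs=FS)
        off = [self._unit((20, 4), 0.0) for _ in range(4)]
        dm = compute_diffmask(c, off, a=0.5)
        assert np.allclose(dm.values, scale_unit(c).values)

    def test_a_zero_passthrough(self, rng):
        c = Mask(values=rng.random((20, 4)), kind="frmask", fs=FS)
        off = [Mask(values=rng.random((20, 4)), kind="frmask", fs=FS)]
        dm = compute_diffmask(c, off, a=0.0)
        assert np.allclose(dm.values, scale_unit(c).values)

    def test_nonnegative_and_bounded_by_center(self, rng):
        c = Mask(values=rng.random((50, 6)), kind="frmask", fs=FS)
        off = [Mask(values=rng.random((50, 6)), kind="frmask", fs=FS) for _ in range(4)]
        dm = compute_diffmask(c, off, a=0.5)
        assert (dm.values >= 0).all()
        assert np.all(dm.values <= scale_unit(c).values + 1e-12)

    def test_more_off_masks_subtract_at_least_as_much(self, rng):
        c = Mask(values=rng.random((50, 6)), kind="frmask", fs=FS)
        off = [Mask(values=rng.random((50, 6)), kind="frmask", fs=FS) for _ in range(4)]
        full = compute_diffmask(c, off, a=0.5).values
        half = compute_diffmask(c, off[:2], a=0.5).values
        assert np.all(full <= half + 1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_diffmask(self._unit((10, 3)), [self._unit((5, 3))])

    def test_all_zero_mask_scales_to_zero(self):
        z = Mask(values=np.zeros((10, 2)), kind="frmask", fs=FS)
        assert not scale_unit(z).values.any()

    def test_streaming_scaling_is_causal_and_bounded(self, rng):
        m = Mask(values=rng.random((100, 3)), kind="frmask", fs=FS)
        s = scale_unit_streaming(m)
        assert s.values.max() <= 1.0
        # the first row's running max is its own max
        assert s.values[0].max() == pytest.approx(1.0)


class TestApplyMask:
    def test_zero_mask_gives_silence(self, small_spec, rng):
        from bossa import Subbands
        from bossa.peripheral import erb_center_frequencies

        n = 500
        sb = Subbands(
            left=rng.standard_normal((n, small_spec.n_channels)),
            right=rng.standard_normal((n, small_spec.n_channels)),
            fs=FS,
            center_freqs=erb_center_frequencies(small_spec),
        )
        out = apply_mask(Mask(values=np.zeros((n, small_spec.n_channels)), kind="frmask", fs=FS), sb)
        assert out.shape == (n, 2)
        assert not out.any()

    def test_single_channel_mask_passes_that_channel(self, small_spec, rng):
        from bossa import Subbands
        from bossa.peripheral import erb_center_frequencies

        n, n_ch = 400, small_spec.n_channels
        sb = Subbands(
            left=rng.standard_normal((n, n_ch)),
            right=rng.standard_normal((n, n_ch)),
            fs=FS,
            center_freqs=erb_center_frequencies(small_spec),
        )
        v = np.zeros((n, n_ch))
        v[:, 3] = 1.0
        out = apply_mask(Mask(values=v, kind="frmask", fs=FS), sb)
        assert np.allclose(out[:, 0], sb.left[:, 3])
        assert np.allclose(out[:, 1], sb.right[:, 3])

    def test_unit_mask_preserves_broadband_ild(self, speech_spec, hrtf, rng):
        """A common mask on both ears cannot alter interaural level: for a
        lateral source, output broadband ILD matches the input's within 1 dB."""
        from bossa import analyze_binaural, white_noise
        from bossa.spatial import spatialize

        stereo = spatialize(white_noise(0.4, FS, seed=2), 60.0, hrtf)
        sb = analyze_binaural(stereo, speech_spec)
        ones = Mask(values=np.ones_like(sb.left), kind="frmask", fs=FS)
        out = apply_mask(ones, sb)

        def bb_ild(x):
            return 10 * np.log10((x[:, 0] ** 2).sum() / (x[:, 1] ** 2).sum())

        assert bb_ild(out) == pytest.approx(bb_ild(stereo), abs=1.0)
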
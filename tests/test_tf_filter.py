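"""Masking contracts, noise reduction, ISTFT reconstruction."""

import numpy as np
import pytest

from echolabel import (
    BoundingBox,
    MaskSpec,
    StftParams,
    Waveform,
    apply_band_filter,
    apply_box_filter,
    compute_stft,
    reconstruct,
    reduce_noise_rowwise,
)
from echolabel.fixtures import SyntheticEvent, make_signal
from echolabel.spectrogram import ComplexSpectrogram

from conftest import multitone


def energy(wave: Waveform) -> float:
    return float(np.sum(wave.samples**2))


@pytest.fixture(scope="module")
def tone_spec(tone_clip, default_params):
    return compute_stft(tone_clip, default_params)


class TestBoxMask:
    def test_full_extent_box_is_identity(self, tone_spec):
        box = BoundingBox(0.0, tone_spec.time_span_seconds, 0.0, tone_spec.nyquist_khz)
        for mode in ("zero", "attenuate"):
            out = apply_box_filter(tone_spec, MaskSpec(box=box, mode=mode))
            np.testing.assert_array_equal(out.values, tone_spec.values)

    def test_attenuate_scales_outside_by_exactly_1_over_100(self, tone_spec):
        box = BoundingBox(3.0, 6.0, 1.0, 5.0)
        out = apply_box_filter(tone_spec, MaskSpec(box=box, mode="attenuate"))
        inside = out.values == tone_spec.values
        ratio = np.abs(out.values[~inside]) / np.abs(tone_spec.values[~inside])
        np.testing.assert_allclose(ratio, 0.01, rtol=1e-12)
        # inside cells are bit-identical
        t_in = (tone_spec.times >= 3.0) & (tone_spec.times <= 6.0)
        f_in = (tone_spec.freqs_khz >= 1.0) & (tone_spec.freqs_khz <= 5.0)
        np.testing.assert_array_equal(
            out.values[np.ix_(f_in, t_in)], tone_spec.values[np.ix_(f_in, t_in)]
        )

    def test_zero_mode_outside_exactly_zero(self, tone_spec):
        box = BoundingBox(3.0, 6.0, 1.0, 5.0)
        out = apply_box_filter(tone_spec, MaskSpec(box=box))
        t_in = (tone_spec.times >= 3.0) & (tone_spec.times <= 6.0)
        f_in = (tone_spec.freqs_khz >= 1.0) & (tone_spec.freqs_khz <= 5.0)
        outside = ~(f_in[:, None] & t_in[None, :])
        assert np.all(out.values[outside] == 0.0 + 0.0j)

    def test_phase_preserved_in_attenuate(self, tone_spec):
        out = apply_box_filter(
            tone_spec, MaskSpec(box=BoundingBox(3.0, 6.0, 1.0, 5.0), mode="attenuate")
        )
        nz = np.abs(tone_spec.values) > 1e-12
        np.testing.assert_allclose(
            np.angle(out.values[nz]), np.angle(tone_spec.values[nz]), atol=1e-12
        )

    def test_empty_selection_rejected(self, tone_spec):
        with pytest.raises(ValueError):
            apply_box_filter(tone_spec, MaskSpec(box=BoundingBox(100.0, 101.0, 1.0, 5.0)))

    def test_zero_mask_idempotent_and_attenuate_squares(self, tone_spec):
        mask = MaskSpec(box=BoundingBox(3.0, 6.0, 1.0, 5.0))
        once = apply_box_filter(tone_spec, mask)
        np.testing.assert_array_equal(apply_box_filter(once, mask).values, once.values)
        att = MaskSpec(box=mask.box, mode="attenuate")
        twice = apply_box_filter(apply_box_filter(tone_spec, att), att)
        outside = twice.values != tone_spec.values
        np.testing.assert_allclose(
            np.abs(twice.values[outside]),
            np.abs(tone_spec.values[outside]) * 1e-4,
            rtol=1e-12,
        )

    def test_masking_never_increases_energy(self, tone_spec):
        total = np.sum(np.abs(tone_spec.values) ** 2)
        for mask in (
            MaskSpec(box=BoundingBox(3.0, 6.0, 1.0, 5.0)),
            MaskSpec(box=BoundingBox(3.0, 6.0, 1.0, 5.0), mode="attenuate"),
            MaskSpec(box=BoundingBox(0.1, 0.2, 0.0, 11.9), epsilon=1e-4),
        ):
            out = apply_box_filter(tone_spec, mask)
            assert np.sum(np.abs(out.values) ** 2) <= total


class TestBandFilter:
    def test_full_band_identity(self, tone_spec):
        out = apply_band_filter(tone_spec, 0.0, tone_spec.nyquist_khz)
        np.testing.assert_array_equal(out.values, tone_spec.values)

    def test_enclosing_band_keeps_tone_energy(self, tone_clip, tone_spec):
        filtered = reconstruct(apply_band_filter(tone_spec, 1.5, 2.5))
        assert energy(filtered) >= 0.95 * energy(tone_clip)

    def test_disjoint_band_removes_tone_energy(self, tone_clip, tone_spec):
        filtered = reconstruct(apply_band_filter(tone_spec, 4.0, 5.0))
        assert energy(filtered) <= 0.01 * energy(tone_clip)

    def test_inverted_band_rejected(self, tone_spec):
        with pytest.raises(ValueError):
            apply_band_filter(tone_spec, 5.0, 4.0)


class TestRowwiseNoiseReduction:
    def test_constant_row_vanishes(self, default_params):
        # a pure steady tone at an exact bin frequency -> near-constant row magnitude
        values = np.zeros((128, 10), dtype=complex)
        values[40, :] = 3.0 + 1.0j
        cspec = ComplexSpectrogram(values, 24_000, default_params)
        out = reduce_noise_rowwise(cspec)
        assert np.all(out.values[40, :] == 0)

    def test_sparse_transient_survives(self, default_params):
        values = np.zeros((128, 11), dtype=complex)
        values[10, 5] = 2.0 - 1.0j  # single loud frame, row median stays 0
        cspec = ComplexSpectrogram(values, 24_000, default_params)
        out = reduce_noise_rowwise(cspec)
        assert out.values[10, 5] == 2.0 - 1.0j

    def test_chirp_in_stationary_noise(self):
        """Frozen oracle: median subtraction removes 76.1% of Gaussian noise
        magnitude in expectation (closed form for Rayleigh magnitudes) while
        a sparse chirp loses well under half its magnitude."""
        mix = make_signal(
            [SyntheticEvent("chirp", 7.0, 7.5, 3.0, 5.0, amplitude=0.5)],
            15.0, 24_000, noise_floor=0.05, seed=2,
        )
        cspec = compute_stft(mix, StftParams())
        out = reduce_noise_rowwise(cspec)
        t_in = (cspec.times >= 7.0) & (cspec.times <= 7.5)
        f_in = (cspec.freqs_khz >= 3.0) & (cspec.freqs_khz <= 5.0)
        chirp_cells = np.ix_(f_in, t_in)
        noise_cells = np.ix_(f_in, ~t_in)
        chirp_loss = 1 - np.abs(out.values[chirp_cells]).mean() / np.abs(cspec.values[chirp_cells]).mean()
        noise_loss = 1 - np.abs(out.values[noise_cells]).mean() / np.abs(cspec.values[noise_cells]).mean()
        assert chirp_loss < 0.5
        assert noise_loss == pytest.approx(0.761, abs=0.05)

    def test_phase_preserved(self, tone_spec):
        out = reduce_noise_rowwise(tone_spec)
        nz = np.abs(out.values) > 1e-12
        np.testing.assert_allclose(np.angle(out.values[nz]), np.angle(tone_spec.values[nz]), atol=1e-12)

    def test_needs_two_frames(self, default_params):
        cspec = ComplexSpectrogram(np.ones((128, 1), dtype=complex), 24_000, default_params)
        with pytest.raises(ValueError):
            reduce_noise_rowwise(cspec)


class TestReconstruction:
    def test_round_trip_on_band_limited_signals(self, default_params):
        n = default_params.window_length
        for seed in range(20):
            wave = multitone(seed)
            rebuilt = reconstruct(compute_stft(wave, default_params))
            err = np.abs(
                rebuilt.samples[n : wave.samples.size - n]
                - wave.samples[n : wave.samples.size - n]
            ).max()
            assert err < 1e-6

    def test_output_length_contract(self, tone_spec):
        out = reconstruct(tone_spec)
        expected = (tone_spec.frames - 1) * tone_spec.params.hop + tone_spec.params.window_length
        assert out.samples.size == expected

    def test_all_zero_spectrogram_is_silence(self, default_params):
        cspec = ComplexSpectrogram(np.zeros((128, 50), dtype=complex), 24_000, default_params)
        out = reconstruct(cspec)
        assert np.all(out.samples == 0.0)

    def test_identity_mask_propagates_exactly(self, tone_spec):
        box = BoundingBox(0.0, tone_spec.time_span_seconds, 0.0, tone_spec.nyquist_khz)
        masked = apply_box_filter(tone_spec, MaskSpec(box=box))
        np.testing.assert_array_equal(
            reconstruct(masked).samples, reconstruct(tone_spec).samples
        )

    def test_linearity(self, default_params):
        wave = multitone(99, n_samples=8192)
        cspec = compute_stft(wave, default_params)
        scaled = ComplexSpectrogram(2.5 * cspec.values, cspec.sample_rate, default_params)
        np.testing.assert_allclose(
            reconstruct(scaled).samples, 2.5 * reconstruct(cspec).samples, atol=1e-12
        )

    def test_cola_violation_names_parameters(self):
        wave = Waveform(np.random.default_rng(0).uniform(-1, 1, 4096), 24_000)
        params = StftParams(window_length=256, overlap=0.25)
        cspec = compute_stft(wave, params)
        with pytest.raises(ValueError, match="0.25"):
            reconstruct(cspec)
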
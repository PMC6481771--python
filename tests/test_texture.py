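import numpy as np
import pytest

from plumavis import (
    bandpass_stack,
    edge_fraction,
    granularity_spectrum,
    green_channel_luminance,
    normalize_peak_filter,
    summarize,
)
from plumavis.texture import TextureStats, band_edges_cycles_per_px, roi_mask_from_polygon
from plumavis.synthetic import gen_texture_image

SIZE = (256, 256)


def grating(cycles):
    return gen_texture_image("grating", SIZE, cycles=cycles)


def predicted_band(cycles, n_bands=8):
    f = cycles / SIZE[1]
    edges = band_edges_cycles_per_px(SIZE, n_bands)
    return int(np.searchsorted(edges, f, side="left") - 1)


class TestBandpassStack:
    def test_bands_partition_and_reconstruct(self, rng):
        img = rng.uniform(0, 1, SIZE)
        stack = bandpass_stack(img, 8)
        recon = np.sum(stack, axis=0) + img.mean()
        assert np.allclose(recon, img, atol=1e-9)

    @pytest.mark.parametrize("cycles", [3, 8, 16, 32, 60])
    def test_sinusoid_energy_in_predicted_band(self, cycles):
        stack = bandpass_stack(grating(cycles), 8)
        energies = np.array([b.std() for b in stack])
        assert int(np.argmax(energies)) == predicted_band(cycles)
        # essentially all energy in that one band
        assert energies.max() / energies.sum() > 0.99

    def test_white_noise_energy_tracks_annulus_area(self, rng):
        img = rng.standard_normal((256, 256))
        stack = bandpass_stack(img, 6)
        fy = np.fft.fftfreq(256)[:, None]
        fx = np.fft.fftfreq(256)[None, :]
        r = np.sqrt(fy**2 + fx**2)
        edges = band_edges_cycles_per_px((256, 256), 6)
        areas = np.array(
            [((r > lo) & (r <= hi)).sum() for lo, hi in zip(edges[:-1], edges[1:])]
        )
        var = np.array([b.var() for b in stack])
        # flat power spectrum: variance proportional to annulus bin count,
        # within chi-squared sampling error (~sqrt(2/bins) relative SD)
        ratio = var / areas * 256**2
        tol = 4.0 * np.sqrt(2.0 / areas)
        assert np.all(np.abs(ratio - 1.0) < np.maximum(tol, 0.05))

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            bandpass_stack(np.zeros((64, 64)), 8)


class TestGranularitySpectrum:
    def test_constant_image_zero_energy_any_roi(self):
        img = np.full(SIZE, 0.5)
        mask = roi_mask_from_polygon(
            np.array([[10, 10], [10, 100], [90, 60]]), SIZE
        )
        spec = granularity_spectrum(img, mask)
        assert np.allclose(spec.energy, 0.0)

    def test_shape_correction_kills_mask_outline(self):
        # constant ROI on a constant background of a different level: with
        # no internal pattern, every band must score zero despite the edge
        img = np.full(SIZE, 0.2)
        mask = np.zeros(SIZE, dtype=bool)
        mask[30:90, 20:110] = True
        img[mask] = 0.8
        spec = granularity_spectrum(img, mask)
        assert np.allclose(spec.energy, 0.0, atol=1e-9)

    def test_full_frame_grating_peaks_in_predicted_band(self):
        spec = granularity_spectrum(grating(16), None)
        assert int(np.argmax(spec.energy)) == predicted_band(16)

    def test_energy_linear_in_contrast(self):
        img = grating(8)
        base = granularity_spectrum(img, None).energy
        scaled = granularity_spectrum(3.0 * img, None).energy
        assert np.allclose(scaled, 3.0 * base, rtol=1e-9, atol=1e-12)

    def test_degenerate_roi_rejected(self):
        mask = np.zeros(SIZE, dtype=bool)
        mask[5, 5] = True
        with pytest.raises(ValueError):
            granularity_spectrum(np.zeros(SIZE), mask)

    def test_blob_scale_orders_peak_frequency(self):
        small = gen_texture_image("blob_field", SIZE, seed=1, scale_px=3.0)
        large = gen_texture_image("blob_field", SIZE, seed=1, scale_px=12.0)
        peak_small = summarize(granularity_spectrum(small, None)).peak_filter
        peak_large = summarize(granularity_spectrum(large, None)).peak_filter
        assert peak_large < peak_small


class TestSummarize:
    def _spec(self, energy):
        from plumavis import GranularitySpectrum

        bands = np.geomspace(0.01, 0.5, len(energy))
        return GranularitySpectrum(bands, np.asarray(energy, float))

    def test_single_band_dominance(self):
        s = summarize(self._spec([0, 0, 2.0, 0]))
        assert s.proportion_energy == 1.0
        assert s.peak_filter == self._spec([0, 0, 2.0, 0]).bands[2]

    def test_tie_breaks_to_lower_frequency(self):
        spec = self._spec([0, 1.0, 1.0, 0])
        s = summarize(spec)
        assert s.proportion_energy == 0.5
        assert s.peak_filter == spec.bands[1]

    def test_uniform_spectrum_proportion(self):
        s = summarize(self._spec([1.0] * 5))
        assert s.proportion_energy == pytest.approx(0.2)

    def test_all_zero_flags_undefined(self):
        s = summarize(self._spec([0.0, 0.0, 0.0]))
        assert not s.defined
        assert np.isnan(s.peak_filter)

    def test_normalized_energy_sums_to_one(self):
        spec = self._spec([0.2, 0.5, 0.3])
        assert spec.normalized_energy.sum() == pytest.approx(1.0)


class TestEdgeFraction:
    def test_constant_image_has_no_edges(self):
        assert edge_fraction(np.full(SIZE, 0.3)) == 0.0

    def test_step_edge_matches_pixel_count_oracle(self):
        # a single vertical step should mark about one column of edge
        # pixels: fraction ~ c/N for a small constant c
        n = 128
        img = np.zeros((n, n))
        img[:, n // 2 :] = 1.0
        frac = edge_fraction(img, sigma=3, threshold=0.15, preprocess=False)
        marked_columns = frac * n  # oracle: edge pixels / rows
        assert 1.0 <= marked_columns <= 3.0

    def test_non_increasing_in_threshold(self):
        img = gen_texture_image("blob_field", SIZE, seed=5, scale_px=4.0)
        img -= img.min()
        fracs = [
            edge_fraction(img, threshold=t, preprocess=False)
            for t in (0.05, 0.10, 0.15, 0.20, 0.30)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(fracs, fracs[1:]))

    def test_roi_restriction(self):
        n = 128
        img = np.zeros((n, n))
        img[:, n // 2 :] = 1.0
        far = np.zeros((n, n), dtype=bool)
        far[:, :20] = True  # ROI far away from the step
        assert edge_fraction(img, far, preprocess=False) == 0.0


class TestGreenChannel:
    def test_pure_green_is_ones(self):
        img = np.zeros((4, 4, 3))
        img[..., 1] = 1.0
        assert np.allclose(green_channel_luminance(img), 1.0)

    def test_pure_red_is_zeros(self):
        img = np.zeros((4, 4, 3))
        img[..., 0] = 1.0
        assert np.allclose(green_channel_luminance(img), 0.0)

    def test_exact_channel_slice(self, rng):
        img = rng.uniform(0, 1, (5, 6, 3))
        assert np.array_equal(green_channel_luminance(img), img[..., 1])

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError):
            green_channel_luminance(np.zeros((4, 4)))


class TestNormalizePeakFilter:
    def _stats(self, peak, defined=True):
        return TextureStats(1.0, 0.5, peak, defined=defined)

    def test_reference_maps_to_one(self):
        out = normalize_peak_filter({"train": self._stats(0.1)}, "train")
        assert out["train"] == pytest.approx(1.0)

    def test_equal_peaks_both_one(self):
        out = normalize_peak_filter(
            {"train": self._stats(0.1), "brush": self._stats(0.1)}, "train"
        )
        assert out["brush"] == pytest.approx(1.0)

    def test_ratio_reported(self):
        out = normalize_peak_filter(
            {"train": self._stats(0.1), "trees": self._stats(0.2)}, "train"
        )
        assert out["trees"] == pytest.approx(2.0)

    def test_undefined_reference_rejected(self):
        with pytest.raises(ValueError):
            normalize_peak_filter(
                {"train": TextureStats(0, float("nan"), float("nan"), defined=False)},
                "train",
            )
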
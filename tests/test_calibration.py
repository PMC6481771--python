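import numpy as np
import pytest

from plumavis import (
    GrayscaleStandard,
    MultispectralImage,
    SlogParams,
    apply_cone_mapping,
    fit_cone_mapping,
    fit_slog,
    invert_slog,
    linearize,
    validate_colorspace,
)
from plumavis.calibration import apply_slog, channel_catches
from plumavis.spectra import d65_illuminant
from plumavis.synthetic import (
    gen_camera_channels,
    gen_grayscale_observations,
    gen_spectra_library,
)
from plumavis.viewers import ConeClass, ViewerModel, gaussian_sensitivity, quantum_catch

TRUE = SlogParams(A=-0.9, T_o=80.0, C=0.95, channel="vis_g")
STEPS = np.linspace(0.05, 0.9, 8)


class TestSlogFit:
    def test_noiseless_parameter_recovery(self):
        std = gen_grayscale_observations(TRUE, STEPS, noise_sd=0.0)
        fit = fit_slog(std, "vis_g")
        for got, true in [(fit.A, TRUE.A), (fit.T_o, TRUE.T_o), (fit.C, TRUE.C)]:
            assert got == pytest.approx(true, rel=1e-6)
        assert fit.fit_quality > 0.999999

    def test_noisy_recovery_within_five_percent(self):
        std = gen_grayscale_observations(TRUE, STEPS, noise_sd=0.01, seed=7)
        fit = fit_slog(std, "vis_g")
        for got, true in [(fit.A, TRUE.A), (fit.T_o, TRUE.T_o), (fit.C, TRUE.C)]:
            assert got == pytest.approx(true, rel=0.05)

    def test_constant_reflectance_is_degenerate(self):
        with pytest.raises((RuntimeError, ValueError)):
            std = GrayscaleStandard(
                np.full(8, 0.5), {"vis_g": np.linspace(10, 200, 8)}
            )
            fit_slog(std, "vis_g")

    def test_too_few_steps_rejected(self):
        with pytest.raises(ValueError):
            GrayscaleStandard(np.array([0.1, 0.5, 0.9]), {"vis_g": np.arange(3.0)})

    def test_round_trip_apply_invert_identity(self):
        r = np.linspace(0.06, 0.9, 50)
        assert np.allclose(apply_slog(TRUE, invert_slog(TRUE, r)), r, atol=1e-9)


class TestLinearize:
    def _image(self, values):
        return MultispectralImage({"vis_g": values}, linearized=False)

    def test_grayscale_round_trip(self):
        std = gen_grayscale_observations(TRUE, STEPS, noise_sd=0.0)
        fit = fit_slog(std, "vis_g")
        img = self._image(std.pixel_values["vis_g"].reshape(2, 4))
        out = linearize(img, {"vis_g": fit})
        assert out.linearized
        assert np.allclose(out.channels["vis_g"].ravel(), STEPS, atol=1e-6)

    def test_equal_pixels_map_equal(self):
        img = self._image(np.full((3, 3), 120.0))
        out = linearize(img, {"vis_g": TRUE})
        assert np.ptp(out.channels["vis_g"]) == 0.0

    def test_monotone_pixel_values_map_monotone(self):
        img = self._image(np.linspace(10, 300, 9).reshape(3, 3))
        out = linearize(img, {"vis_g": TRUE})
        # A < 0: R increases with V
        assert np.all(np.diff(out.channels["vis_g"].ravel()) >= 0)

    def test_missing_channel_params_rejected(self):
        with pytest.raises(KeyError):
            linearize(self._image(np.ones((2, 2))), {})

    def test_output_clipped_to_unit_interval(self):
        img = self._image(np.array([[0.0, 1e4]]))
        out = linearize(img, {"vis_g": TRUE})
        assert out.channels["vis_g"].min() >= 0.0
        assert out.channels["vis_g"].max() <= 1.0


@pytest.fixture(scope="module")
def illum():
    return d65_illuminant()


@pytest.fixture(scope="module")
def channels():
    return gen_camera_channels()


@pytest.fixture(scope="module")
def library():
    return gen_spectra_library(n=80, seed=3)


class TestConeMapping:
    def test_self_mapping_is_identity(self, illum, library):
        # channel curves identical to cone curves: the fitted map must be
        # the identity, with interaction terms vanishing
        chans = gen_camera_channels()
        cones = tuple(
            ConeClass(name, s) for name, s in chans.items()
        )
        viewer = ViewerModel("selfmap", cones, cones[-1], 0.1, 0.1, 5.0)
        mapping = fit_cone_mapping(chans, viewer, library, illum, include_luminance=False)
        n = len(chans)
        for i in range(n):
            coef = mapping.coefficients[i]
            expect = np.zeros(coef.size)
            expect[i] = 1.0
            assert np.allclose(coef, expect, atol=1e-8)
            assert abs(mapping.intercepts[i]) < 1e-8

    def test_linear_combination_recovered_exactly(self, illum, library, channels):
        # cone sensitivity = average of two channel curves; quantum catch is
        # linear in sensitivity only through the numerator, so build the
        # target cone directly in catch space instead: y = 0.3*x0 + 0.7*x2
        X = np.stack([channel_catches(illum, r, channels) for r in library])
        y = 0.3 * X[:, 0] + 0.7 * X[:, 2]
        from sklearn.linear_model import LinearRegression
        from sklearn.preprocessing import PolynomialFeatures

        pf = PolynomialFeatures(degree=2, interaction_only=True, include_bias=False)
        reg = LinearRegression().fit(pf.fit_transform(X), y)
        coef = np.zeros(pf.n_output_features_)
        coef[0], coef[2] = 0.3, 0.7
        assert np.allclose(reg.coef_, coef, atol=1e-8)
        assert reg.score(pf.fit_transform(X), y) == pytest.approx(1.0)

    def test_library_fit_quality(self, illum, library, channels, peafowl):
        mapping = fit_cone_mapping(channels, peafowl, library, illum)
        assert np.all(mapping.fit_quality >= 0.99)

    def test_no_gross_overfit_on_held_out_spectra(self, illum, channels, peafowl):
        train = gen_spectra_library(n=80, seed=11)
        test = gen_spectra_library(n=40, seed=99)[5:]  # drop shared archetypes
        mapping = fit_cone_mapping(channels, peafowl, train, illum)

        def rmse(spectra):
            X = np.stack([channel_catches(illum, r, channels) for r in spectra])
            cones = list(peafowl.chromatic_cones) + [peafowl.luminance_cone]
            Y = np.stack([[quantum_catch(illum, r, c) for c in cones] for r in spectra])
            return np.sqrt(((mapping.predict(X) - Y) ** 2).mean())

        assert rmse(test) < 2.0 * rmse(train) + 1e-4

    def test_too_small_library_rejected(self, illum, channels, peafowl):
        with pytest.raises(ValueError, match="50"):
            fit_cone_mapping(channels, peafowl, gen_spectra_library(n=10), illum)

    def test_json_round_trip(self, illum, library, channels, predator, tmp_path):
        from plumavis import ConeMapping

        mapping = fit_cone_mapping(channels, predator, library, illum)
        p = tmp_path / "map.json"
        mapping.to_json(p)
        back = ConeMapping.from_json(p)
        assert back.cone_names == mapping.cone_names
        assert np.allclose(back.coefficients, mapping.coefficients)


class TestApplyConeMapping:
    def test_uniform_image_gives_uniform_catches(self, illum, library, channels, predator):
        mapping = fit_cone_mapping(channels, predator, library, illum)
        img = MultispectralImage(
            {c: np.full((4, 5), 0.4) for c in channels}, linearized=True
        )
        out = apply_cone_mapping(img, mapping)
        for arr in out.values():
            assert np.ptp(arr) < 1e-12

    def test_zero_image_floored_for_logs(self, illum, library, channels, predator):
        mapping = fit_cone_mapping(channels, predator, library, illum)
        img = MultispectralImage(
            {c: np.zeros((3, 3)) for c in channels}, linearized=True
        )
        out = apply_cone_mapping(img, mapping)
        for arr in out.values():
            assert np.all(arr > 0)
            assert np.all(np.isfinite(np.log(arr)))

    def test_unlinearized_input_rejected(self, illum, library, channels, predator):
        mapping = fit_cone_mapping(channels, predator, library, illum)
        img = MultispectralImage(
            {c: np.zeros((3, 3)) for c in channels}, linearized=False
        )
        with pytest.raises(ValueError, match="linearized"):
            apply_cone_mapping(img, mapping)


class TestValidateColorspace:
    def test_identity_inputs(self):
        sw = np.array([0.1, 0.3, 0.5, 0.7, 0.2, 0.6])
        slope, intercept, r2 = validate_colorspace(sw, sw)
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(1.0)

    def test_six_patch_synthetic_chart(self, illum, channels, predator, library):
        # spectra-path sw vs image-path sw through the fitted mapping
        from plumavis.viewers import catch_vector, normalized_coords

        mapping = fit_cone_mapping(channels, predator, library, illum)
        patches = gen_spectra_library(n=20, seed=42)[5:11]
        sw_r, sw_m = [], []
        for refl in patches:
            qc = catch_vector(illum, refl, predator)
            sw_r.append(normalized_coords(qc)[0])
            x = channel_catches(illum, refl, channels)
            q = np.clip(mapping.predict(x[None, :])[0][:2], 1e-6, None)
            sw_m.append(q[0] / q.sum())
        slope, intercept, r2 = validate_colorspace(np.array(sw_m), np.array(sw_r))
        assert 0.9 <= slope <= 1.1
        assert abs(intercept) <= 0.05
        assert r2 > 0.95

    def test_constant_reference_rejected(self):
        with pytest.raises(ValueError):
            validate_colorspace(np.array([0.1, 0.2, 0.3]), np.full(3, 0.4))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            validate_colorspace(np.array([0.1, 0.2]), np.array([0.1, 0.2]))
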
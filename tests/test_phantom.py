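"""Ground-truth fields, the fiber forward model, camera rendering and noise."""

import numpy as np
import pytest

from scifidose import (
    CameraSpec,
    DetectorGeometry,
    DoseField2D,
    FiberSignalVector,
    GridSpec,
    NoiseModel,
    add_noise,
    cone_dose_field,
    cone_radial_dose,
    project_field,
    render_detector_image,
    square_dose_field,
)
from scifidose.metrics import fwhm

from conftest import abel_projection


class TestConeField:
    @pytest.mark.parametrize(
        "r, expected",
        [
            (0.0, 1.000),  # flat top: edge is 10 sigma away
            (5.0, 0.500),  # field edge sits at the 50% level
            (5.0 - 0.8416 * 0.5, 0.800),  # normal quantile: 80% level
            (5.0 + 0.8416 * 0.5, 0.200),  # 20% level
        ],
    )
    def test_radial_dose_levels(self, r, expected):
        dose = cone_radial_dose(r, diameter=10.0, peak_dose=1.0, penumbra_sigma=0.5)
        assert dose == pytest.approx(expected, abs=5e-4)

    def test_field_is_radially_symmetric(self):
        field = cone_dose_field(10.0, 1.0, 0.5)
        assert np.allclose(field.values, field.values[::-1, :], atol=1e-12)
        assert np.allclose(field.values, field.values.T, atol=1e-12)

    def test_grid_must_contain_footprint(self):
        small = GridSpec.centered(3.0, 0.1)
        with pytest.raises(ValueError, match="footprint"):
            cone_dose_field(10.0, 1.0, 0.5, grid=small)


class TestSquareField:
    def test_rotation_by_90_degrees_is_identity(self):
        a = square_dose_field(10.0, angle=0.0, penumbra_sigma=0.3)
        b = square_dose_field(10.0, angle=90.0, penumbra_sigma=0.3)
        assert np.allclose(a.values, b.values, atol=1e-9)

    def test_sharp_interior_reaches_peak(self):
        field = square_dose_field(30.0, angle=0.0, peak_dose=2.5, penumbra_sigma=0.01)
        x = field.x_axis
        ix = np.argmin(np.abs(x))
        assert field.values[ix, ix] == pytest.approx(2.5, rel=1e-6)

    def test_45_degree_projection_is_triangular(self, geometry):
        # projecting a sharp diamond gives chord length 2*(s/sqrt(2) - |x|)
        side = 10.0
        field = square_dose_field(side, angle=45.0, penumbra_sigma=0.02)
        signals = project_field(field, geometry)
        half_diag = side / np.sqrt(2.0)
        expected = 2.0 * np.clip(half_diag - np.abs(signals.fiber_x), 0.0, None)
        interior = np.abs(signals.fiber_x) < half_diag - 0.5
        peak = expected.max()
        assert np.all(
            np.abs(signals.signal[interior] - expected[interior]) < 0.01 * peak
        )


class TestProjectField:
    def test_zero_field_projects_to_zero(self, geometry):
        field = DoseField2D(np.zeros((41, 41)), 0.5, (-10.0, -10.0))
        signals = project_field(field, geometry)
        assert np.all(signals.signal == 0)

    def test_flat_disk_matches_chord_formula(self, geometry):
        # per-fiber signal of a uniform disk is the chord length 2*D*sqrt(R^2-x^2)
        R, D, h = 7.5, 1.0, 0.05
        grid = GridSpec.centered(12.0, h)
        field = cone_dose_field(2 * R, D, penumbra_sigma=0.01, grid=grid)
        signals = project_field(field, geometry)
        expected = 2.0 * D * np.sqrt(
            np.clip(R**2 - signals.fiber_x**2, 0.0, None)
        )
        interior = np.abs(signals.fiber_x) < R - 2 * h
        peak = 2.0 * D * R
        err = np.abs(signals.signal[interior] - expected[interior])
        assert err.max() < 0.005 * peak

    def test_gaussian_field_projects_to_gaussian_same_sigma(self, geometry):
        # the Abel transform of exp(-r^2/2s^2) is a Gaussian with the same s
        s = 2.0
        grid = GridSpec.centered(15.0, 0.05)
        x, z = grid.axes()
        rr = np.hypot(x[:, None], z[None, :])
        field = DoseField2D(np.exp(-(rr**2) / (2 * s**2)), 0.05, (x[0], z[0]))
        signals = project_field(field, geometry)
        measured = fwhm((signals.fiber_x, signals.signal), half=False)
        expected = 2 * s * np.sqrt(2 * np.log(2))
        assert abs(measured - expected) < geometry.effective_pitch

    def test_projection_is_linear(self, geometry):
        grid = GridSpec.centered(12.0, 0.1)
        f1 = cone_dose_field(8.0, 1.0, 0.5, grid=grid)
        f2 = cone_dose_field(4.0, 0.7, 0.8, grid=grid)
        combo = DoseField2D(
            2.0 * f1.values + 3.0 * f2.values, f1.grid_spacing, f1.origin
        )
        p1 = project_field(f1, geometry).signal
        p2 = project_field(f2, geometry).signal
        pc = project_field(combo, geometry).signal
        assert np.allclose(pc, 2.0 * p1 + 3.0 * p2, rtol=1e-12, atol=1e-12)

    def test_tophat_averaging_close_to_line_sampling(self, geometry):
        grid = GridSpec.centered(12.0, 0.05)
        field = cone_dose_field(10.0, 1.0, 0.8, grid=grid)
        line = project_field(field, geometry, fiber_averaging="line").signal
        tophat = project_field(field, geometry, fiber_averaging="tophat").signal
        assert np.abs(line - tophat).max() < 0.01 * line.max()


class TestRenderAndNoise:
    def test_single_fiber_renders_one_stripe_with_matching_sum(self, geometry):
        fx = geometry.fiber_positions()
        sig = np.zeros_like(fx)
        sig[len(sig) // 2] = 3.7
        image = render_detector_image(FiberSignalVector(fx, sig), geometry)
        col = image.pixels.sum(axis=0)
        assert col.sum() == pytest.approx(3.7, rel=1e-9)
        # stripe is localized: everything within 1 mm of the fiber
        x = image.x_axis
        assert col[np.abs(x - fx[len(sig) // 2]) > 1.0].sum() < 1e-9 * 3.7

    def test_equal_signals_render_flat_profile(self, geometry):
        fx = geometry.fiber_positions()
        image = render_detector_image(
            FiberSignalVector(fx, np.ones_like(fx)), geometry
        )
        col = image.pixels.sum(axis=0)
        interior = np.abs(image.x_axis) < 20.0
        ripple = (col[interior].max() - col[interior].min()) / col[interior].mean()
        assert ripple < 1e-3

    def test_rendering_is_linear(self, geometry):
        fx = geometry.fiber_positions()
        rng = np.random.default_rng(7)
        sig = rng.random(fx.size)
        one = render_detector_image(FiberSignalVector(fx, sig), geometry)
        two = render_detector_image(FiberSignalVector(fx, 2 * sig), geometry)
        assert np.allclose(two.pixels, 2 * one.pixels, rtol=1e-12, atol=1e-15)

    def test_unresolving_camera_rejected(self, geometry):
        camera = CameraSpec(pixel_pitch=0.2)
        fx = geometry.fiber_positions()
        with pytest.raises(ValueError, match="resolve"):
            render_detector_image(
                FiberSignalVector(fx, np.ones_like(fx)), geometry, camera
            )

    def test_zero_noise_is_identity(self, geometry):
        fx = geometry.fiber_positions()
        image = render_detector_image(FiberSignalVector(fx, np.ones_like(fx)), geometry)
        out = add_noise(image, NoiseModel(gaussian_sigma=0.0, impulse_rate=0.0, seed=3))
        assert np.array_equal(out.pixels, image.pixels)

    def test_same_seed_gives_identical_noise(self, geometry):
        fx = geometry.fiber_positions()
        image = render_detector_image(FiberSignalVector(fx, np.ones_like(fx)), geometry)
        model = NoiseModel(gaussian_sigma=0.1, impulse_rate=1e-3,
                           impulse_amplitude=10.0, seed=11)
        a = add_noise(image, model)
        b = add_noise(image, model)
        assert np.array_equal(a.pixels, b.pixels)

    def test_impulse_count_matches_binomial_expectation(self):
        from scifidose import DetectorImage

        image = DetectorImage(np.full((1000, 1000), 50.0), 0.1)
        model = NoiseModel(impulse_rate=1e-3, impulse_amplitude=1000.0, seed=5)
        noisy = add_noise(image, model)
        n_hits = int(np.sum(noisy.pixels > 500.0))
        # binomial sd = sqrt(n p (1-p)) ~ 31.6; allow 5 sd
        assert abs(n_hits - 1000) < 5 * 31.6

    def test_invalid_noise_parameters_rejected(self):
        with pytest.raises(ValueError):
            NoiseModel(gaussian_sigma=-1.0)
        with pytest.raises(ValueError):
            NoiseModel(impulse_rate=1.5)


def test_numeric_projection_oracle_agrees_with_forward_model(geometry):
    """Cross-check project_field against the independent quadrature oracle."""
    grid = GridSpec.centered(12.0, 0.05)
    field = cone_dose_field(10.0, 1.0, 0.8, grid=grid)
    signals = project_field(field, geometry)
    inner = np.abs(signals.fiber_x) < 8.0
    expected = abel_projection(
        lambda r: cone_radial_dose(r, 10.0, 1.0, 0.8), signals.fiber_x[inner]
    )
    assert np.abs(signals.signal[inner] - expected).max() < 0.003 * expected.max()
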
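"""Angular-spectrum propagation, Fourier aperture relation, GSW synthesis."""
import numpy as np
import pytest

from ringfus import (
    FieldGrid,
    Hologram,
    Medium,
    PatternRecipe,
    RingArraySpec,
    TargetPattern,
    angular_spectrum_propagate,
    aperture_to_image,
    build_ring_geometry,
    evaluate_field,
    gsw_synthesize,
    image_to_aperture,
    measure_beam_widths,
    pattern_quality,
    render_pattern,
    sample_hologram_to_elements,
)
from ringfus.holography import _plane_coords
from ringfus.propagation import PressureField


PITCH = 0.0375  # mm, lambda/2 at 20 MHz in water


def band_limited_field(rng, n=64, pitch=PITCH, medium=Medium(), freq=20.0, frac=0.8):
    """Random complex field restricted to a fraction of the propagating band."""
    k = medium.wavenumber_per_mm(freq)
    f = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
    kx = 2 * np.pi * np.fft.fftfreq(n, d=pitch)
    kr2 = kx[None, :] ** 2 + kx[:, None] ** 2
    spec = np.fft.fft2(f)
    spec[kr2 > (frac * k) ** 2] = 0.0
    return np.fft.ifft2(spec)


class TestAngularSpectrum:
    def test_zero_distance_is_identity(self, rng, medium):
        f = band_limited_field(rng)
        out = angular_spectrum_propagate(f, PITCH, 0.0, medium, 20.0)
        assert np.allclose(out, f, atol=1e-12)

    def test_round_trip_identity(self, rng, medium):
        f = band_limited_field(rng)
        fwd = angular_spectrum_propagate(f, PITCH, 7.0, medium, 20.0)
        back = angular_spectrum_propagate(fwd, PITCH, -7.0, medium, 20.0)
        assert np.max(np.abs(back - f)) < 1e-10 * np.max(np.abs(f))

    def test_energy_conserved_on_propagating_band(self, rng, medium):
        f = band_limited_field(rng)
        out = angular_spectrum_propagate(f, PITCH, 5.0, medium, 20.0)
        e_in = np.sum(np.abs(f) ** 2)
        e_out = np.sum(np.abs(out) ** 2)
        assert abs(e_out - e_in) / e_in < 1e-9

    def test_matches_direct_rayleigh_sommerfeld_summation(self, medium):
        """A small Gaussian source propagated 7 mm agrees with a direct
        first-Rayleigh-integral sum inside the paraxial window."""
        n, dz, freq = 128, 7.0, 20.0
        lam = medium.wavelength_mm(freq)
        x = (np.arange(n) - (n - 1) / 2) * PITCH
        xx, yy = np.meshgrid(x, x)
        w0 = 0.15
        src = np.exp(-(xx**2 + yy**2) / w0**2).astype(complex)
        out = angular_spectrum_propagate(src, PITCH, dz, medium, freq, pad_factor=2)

        # direct summation over source pixels (first Rayleigh integral,
        # paraxial obliquity ~ 1)
        k = 2 * np.pi / lam
        active = src.real > 1e-6
        sx, sy, amp = xx[active], yy[active], src.real[active]
        targets = x[np.abs(x) <= 0.6]
        direct = np.empty(len(targets), dtype=complex)
        for i, tx in enumerate(targets):
            d = np.sqrt((tx - sx) ** 2 + sy**2 + dz**2)
            direct[i] = np.sum(amp * np.exp(-1j * k * d) / d) * PITCH**2 / (1j * lam)
        row = out[(n - 1) // 2, np.abs(x) <= 0.6]
        ratio = np.abs(row) / np.abs(direct)
        assert np.max(np.abs(ratio / ratio.mean() - 1)) < 0.02
        # and the absolute scale agrees too
        assert ratio.mean() == pytest.approx(1.0, abs=0.02)

    def test_rejects_non_2d_input(self, medium):
        with pytest.raises(ValueError):
            angular_spectrum_propagate(np.zeros(8), PITCH, 1.0, medium, 20.0)

    def test_warns_on_coarse_sampling(self, medium):
        with pytest.warns(UserWarning, match="lambda/2"):
            angular_spectrum_propagate(np.zeros((8, 8)), 0.1, 1.0, medium, 20.0)


class TestFourierAperture:
    def test_delta_gives_flat_aperture(self, medium):
        img = np.zeros((64, 64))
        img[32, 32] = 1.0
        target = TargetPattern(img)
        a = image_to_aperture(target, medium, 20.0)
        mag = np.abs(a)
        assert np.ptp(mag) / mag.mean() < 1e-12

    def test_forward_transform_recovers_image(self, rng, medium):
        img = rng.uniform(0, 1, (64, 64))
        target = TargetPattern(img)
        a = image_to_aperture(target, medium, 20.0)
        back = aperture_to_image(a, target, medium, 20.0)
        assert np.max(np.abs(back - target.amplitude)) < 1e-10

    def test_shift_theorem(self, medium):
        img = np.zeros((64, 64))
        img[30:34, 30:34] = 1.0
        t0 = TargetPattern(img)
        t1 = TargetPattern(np.roll(img, 5, axis=1))
        a0 = image_to_aperture(t0, medium, 20.0)
        a1 = image_to_aperture(t1, medium, 20.0)
        cols = np.arange(64) - 32
        ramp = np.exp(2j * np.pi * 5 * cols / 64)[None, :]
        assert np.allclose(a1, a0 * ramp, atol=1e-12 * np.abs(a0).max())


class TestGSW:
    def test_single_point_reduces_to_conjugate_lens(self, medium):
        target = render_pattern(
            PatternRecipe("points", size_px=128, pixel_pitch=PITCH)
        )
        res = gsw_synthesize(target, medium, 20.0, max_iter=20)
        xx, yy = _plane_coords(target.amplitude.shape, PITCH)
        k = medium.wavenumber_per_mm(20.0)
        lens = k * np.sqrt(xx**2 + yy**2 + target.depth**2)
        coherence = np.abs(np.mean(np.exp(1j * (res.hologram.phase - lens))))
        assert coherence > 0.8  # global-phase-aligned agreement
        peak = np.unravel_index(
            np.argmax(res.achieved_field.magnitude), target.amplitude.shape
        )
        assert peak == (64, 64)

    def test_uniformity_history_non_decreasing(self, medium):
        target = render_pattern(
            PatternRecipe(
                "points", size_px=128, params={"points": [(40, 40), (40, 88), (88, 64)]}
            )
        )
        res = gsw_synthesize(target, medium, 20.0, max_iter=40)
        diffs = np.diff(res.uniformity_history)
        assert np.all(diffs >= -1e-6)
        assert res.uniformity_history[-1] > 0.95

    def test_hologram_is_exactly_phase_only(self, medium):
        target = render_pattern(PatternRecipe("disks", size_px=64))
        res = gsw_synthesize(target, medium, 20.0, max_iter=5)
        source = res.hologram.complex_field()
        assert np.max(np.abs(np.abs(source[res.hologram.support]) - 1.0)) < 1e-12
        assert np.all(res.hologram.phase > -np.pi)
        assert np.all(res.hologram.phase <= np.pi)

    def test_three_disk_pattern_correlation(self, medium):
        target = render_pattern(PatternRecipe("disks", size_px=200))
        res = gsw_synthesize(target, medium, 20.0)
        q = pattern_quality(res.achieved_field, target)
        assert q.correlation >= 0.7

    def test_empty_support_raises(self, medium):
        blank = TargetPattern(np.zeros((32, 32)))
        with pytest.raises(ValueError):
            gsw_synthesize(blank, medium, 20.0)

    def test_resolution_collapses_below_wavelength_separation(self, medium):
        """Two-point targets: a multi-wavelength separation shows a clear
        intensity dip between the spots, a one-wavelength one does not
        (diffraction limit ~ lambda)."""
        dip = {}
        for sep_px, label in ((16, "far"), (2, "near")):  # 8 lambda vs 1 lambda
            img = np.zeros((96, 96))
            c = 48
            img[c, c - sep_px // 2] = 1.0
            img[c, c + sep_px // 2] = 1.0
            target = TargetPattern(img, pixel_pitch=PITCH)
            res = gsw_synthesize(target, medium, 20.0, max_iter=25)
            mag = res.achieved_field.magnitude
            peaks = (mag[c, c - sep_px // 2] + mag[c, c + sep_px // 2]) / 2
            dip[label] = mag[c, c] / peaks
        assert dip["far"] < 0.3   # resolved: deep valley between the spots
        assert dip["near"] > 0.3  # merged: no valley at the midpoint


class TestHologramSampling:
    def test_flat_array_limit_has_no_sag_correction(self, medium):
        geom = build_ring_geometry(RingArraySpec(curvature_radius=1e6))
        holo = Hologram(
            phase=np.zeros((256, 256)), source_pixel_pitch=0.05, target_depth=7.0
        )
        exc = sample_hologram_to_elements(holo, geom, medium, 20.0)
        assert np.abs(exc.phase).max() < 1e-2

    def test_constant_hologram_gives_pure_sag_compensation(self, medium, ring_geometry):
        holo = Hologram(
            phase=np.zeros((256, 256)), source_pixel_pitch=0.05, target_depth=7.0
        )
        exc = sample_hologram_to_elements(holo, ring_geometry, medium, 20.0)
        k = medium.wavenumber_per_mm(20.0)
        p = ring_geometry.positions
        r2 = p[:, 0] ** 2 + p[:, 1] ** 2
        delta = np.sqrt(r2 + 49.0) - np.sqrt(r2 + (7.0 - p[:, 2]) ** 2)
        expected = np.exp(-1j * k * delta)
        assert np.allclose(exc.values, expected, atol=1e-12)

    def test_elements_outside_hologram_extent_raise(self, medium, ring_geometry):
        holo = Hologram(
            phase=np.zeros((64, 64)), source_pixel_pitch=0.035, target_depth=7.0
        )
        with pytest.raises(ValueError, match="outside"):
            sample_hologram_to_elements(holo, ring_geometry, medium, 20.0)

    def test_end_to_end_single_point_focus(self, medium, ring_geometry):
        """Hologram -> element sampling -> Rayleigh-Sommerfeld field peaks
        at the requested point."""
        target = render_pattern(
            PatternRecipe(
                "points", size_px=320, pixel_pitch=PITCH, params={"points": [(160, 160)]}
            )
        )
        res = gsw_synthesize(target, medium, 20.0, max_iter=20)
        exc = sample_hologram_to_elements(res.hologram, ring_geometry, medium, 20.0)
        grid = FieldGrid(extent=(0.4, 0.4), spacing=0.01, depth=7.0)
        f = evaluate_field(ring_geometry, exc, grid, medium, 20.0)
        m = measure_beam_widths(f)
        assert np.max(np.abs(m.peak_point[:2])) <= grid.spacings[0] + 1e-12


class TestPatternQuality:
    def test_scaled_copy_scores_unit_correlation(self):
        img = render_pattern(PatternRecipe("checkerboard", size_px=64)).amplitude
        target = TargetPattern(img)
        grid = FieldGrid(extent=(63 * 0.035, 63 * 0.035), spacing=0.035, depth=7.0)
        achieved = PressureField(grid=grid, pressure=3.7 * img.astype(complex))
        q = pattern_quality(achieved, target)
        assert q.correlation == pytest.approx(1.0, abs=1e-12)

    def test_constant_field_scores_zero(self):
        img = render_pattern(PatternRecipe("checkerboard", size_px=64)).amplitude
        target = TargetPattern(img)
        grid = FieldGrid(extent=(63 * 0.035, 63 * 0.035), spacing=0.035, depth=7.0)
        achieved = PressureField(grid=grid, pressure=np.ones((64, 64), dtype=complex))
        q = pattern_quality(achieved, target)
        assert abs(q.correlation) < 1e-9

    def test_extent_mismatch_raises(self):
        target = TargetPattern(np.ones((64, 64)))
        grid = FieldGrid(extent=(1.0, 1.0), spacing=0.05, depth=7.0)
        achieved = PressureField(grid=grid, pressure=np.ones((21, 21), dtype=complex))
        with pytest.raises(ValueError, match="extent"):
            pattern_quality(achieved, target)
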
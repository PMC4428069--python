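"""Fresnel propagator, hologram simulation, illumination and flat-field."""

import numpy as np
import pytest

from zoomtomo.geometry import BeamGeometry, wavelength_from_energy
from zoomtomo.propagation import (
    Wavefield,
    empty_beam_correct,
    fresnel_propagate,
    photons_per_pixel,
    simulate_hologram,
    synth_illumination,
)

from conftest import weak_phase_object

LAM = wavelength_from_energy(13.8)


def random_field(n=128, seed=0):
    gen = np.random.default_rng(seed)
    return Wavefield(np.exp(1j * 0.2 * gen.standard_normal((n, n))), 1e-7, LAM)


class TestPropagator:
    def test_zero_distance_is_identity(self):
        w = random_field()
        out = fresnel_propagate(w, 0.0)
        np.testing.assert_array_equal(out.amplitude, w.amplitude)

    def test_unitarity(self):
        w = random_field()
        out = fresnel_propagate(w, 0.01, pad=False)
        power_in = np.sum(np.abs(w.amplitude) ** 2)
        power_out = np.sum(np.abs(out.amplitude) ** 2)
        assert abs(power_out / power_in - 1) < 1e-10

    def test_group_property(self):
        w = random_field()
        direct = fresnel_propagate(w, 0.01, pad=False)
        stepped = fresnel_propagate(
            fresnel_propagate(w, 0.004, pad=False), 0.006, pad=False
        )
        err = np.abs(stepped.amplitude - direct.amplitude).max()
        assert err < 1e-10 * np.abs(direct.amplitude).max()

    def test_forward_backward_inverse(self):
        w = random_field()
        back = fresnel_propagate(fresnel_propagate(w, 0.02, pad=False), -0.02,
                                 pad=False)
        np.testing.assert_allclose(back.amplitude, w.amplitude, atol=1e-12)

    def test_gaussian_beam_analytic_width(self):
        n, px, w0, z = 512, 1e-7, 2e-6, 0.05
        x = (np.arange(n) - n // 2) * px
        X, Y = np.meshgrid(x, x)
        field = Wavefield(np.exp(-(X**2 + Y**2) / w0**2), px, LAM)
        out = fresnel_propagate(field, z).intensity
        w_analytic = w0 * np.sqrt(1 + (LAM * z / (np.pi * w0**2)) ** 2)
        # amplitude waist w: intensity second moment <x^2> = w^2/4
        w_num = np.sqrt(4 * (out * X**2).sum() / out.sum())
        assert abs(w_num / w_analytic - 1) < 1e-3

    def test_aliasing_warning_and_strict_error(self):
        w = random_field(n=64)
        with pytest.warns(RuntimeWarning, match="undersampled"):
            fresnel_propagate(w, 10.0)
        from zoomtomo.propagation import AliasingError

        with pytest.raises(AliasingError):
            fresnel_propagate(w, 10.0, strict=True)


class TestSimulateHologram:
    GEOM = BeamGeometry(0.040, 5.03, 13.8, 6.54e-6)

    def test_empty_object_gives_flat_hologram(self):
        zero = np.zeros((128, 128))
        holo = simulate_hologram(zero, zero, self.GEOM)
        np.testing.assert_allclose(holo.intensity, 1.0, atol=1e-10)

    def test_cone_equals_fresnel_scaled_parallel(self):
        phi = weak_phase_object(256, amplitude=0.2)
        zero = np.zeros_like(phi)
        cone = simulate_hologram(phi, zero, self.GEOM)
        parallel_geom = BeamGeometry(
            np.inf, self.GEOM.effective_distance, 13.8, self.GEOM.effective_pixel
        )
        parallel = simulate_hologram(phi, zero, parallel_geom)
        err = np.abs(cone.intensity - parallel.intensity).max()
        assert err < 1e-8 * parallel.intensity.max()

    def test_weak_object_spectrum_has_ctf_zeros(self):
        # the hologram contrast power must vanish at the zeros of sin(chi)
        n = 256
        phi = weak_phase_object(n, amplitude=0.02)
        geom = BeamGeometry(np.inf, 0.002, 13.8, 5.2e-8)
        holo = simulate_hologram(phi, np.zeros_like(phi), geom)
        import scipy.fft as sfft

        contrast = sfft.fft2(holo.intensity - 1.0)
        phi_hat = sfft.fft2(phi)
        fy = sfft.fftfreq(n, d=geom.effective_pixel)
        chi = np.pi * geom.wavelength * geom.effective_distance * (
            fy[:, None] ** 2 + fy[None, :] ** 2
        )
        strong = np.abs(phi_hat) > 0.05 * np.abs(phi_hat).max()
        ring = (np.abs(np.sin(chi)) < 0.05) & strong
        transfer = (np.abs(contrast) / np.clip(np.abs(phi_hat), 1e-30, None))
        # transferred amplitude in the rings is far below the passband
        passband = (np.abs(np.sin(chi)) > 0.8) & strong
        assert transfer[ring].mean() < 0.2 * transfer[passband].mean()

    def test_direct_regime_contrast_is_phase_laplacian(self):
        # F ~ 1: I - 1 ~ -(lambda z / 2 pi) * laplacian(phi)
        n = 256
        phi = weak_phase_object(n, amplitude=0.05)
        px = 5.2e-8
        z = (10 * px) ** 2 / (LAM * 2.0)  # F = 2 at ten-pixel features
        geom = BeamGeometry(np.inf, z, 13.8, px)
        holo = simulate_hologram(phi, np.zeros_like(phi), geom)
        lap = (
            np.roll(phi, 1, 0) + np.roll(phi, -1, 0)
            + np.roll(phi, 1, 1) + np.roll(phi, -1, 1) - 4 * phi
        ) / px**2
        predicted = -LAM * z / (2 * np.pi) * lap
        measured = holo.intensity - 1.0
        r = np.corrcoef(measured.ravel(), predicted.ravel())[0, 1]
        assert r > 0.99

    def test_poisson_noise_variance_matches_mean(self):
        zero = np.zeros((256, 256))
        holo = simulate_hologram(zero, zero, self.GEOM, fluence=1e4,
                                 n_frames=1, rng=0)
        n_ph = photons_per_pixel(1e4, 1, self.GEOM.effective_pixel)
        var_counts = holo.intensity.var() * n_ph
        assert var_counts == pytest.approx(1.0, rel=0.05)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            simulate_hologram(np.zeros((8, 8)), np.zeros((9, 9)), self.GEOM)

    def test_negative_fluence_rejected(self):
        zero = np.zeros((8, 8))
        with pytest.raises(ValueError):
            simulate_hologram(zero, zero, self.GEOM, fluence=-1.0)


class TestIllumination:
    def test_flat_is_ones(self):
        np.testing.assert_array_equal(
            synth_illumination((32, 32), "flat"), np.ones((32, 32))
        )

    def test_kb_has_more_high_frequency_power_than_waveguide(self):
        import scipy.fft as sfft

        kb = synth_illumination((256, 256), "kb_artifacts", seed=1)
        wg = synth_illumination((256, 256), "waveguide", seed=1)
        assert kb.mean() == pytest.approx(wg.mean())

        def hf_power(img):
            spec = sfft.fft2(img)
            spec[0, 0] = 0
            f = sfft.fftfreq(256)
            r = np.sqrt(f[:, None] ** 2 + f[None, :] ** 2)
            return (np.abs(spec) ** 2)[r > 0.05].sum()

        assert hf_power(kb) > 5 * hf_power(wg)

    def test_deterministic_in_seed(self):
        a = synth_illumination((64, 64), "kb_artifacts", seed=5)
        b = synth_illumination((64, 64), "kb_artifacts", seed=5)
        np.testing.assert_array_equal(a, b)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            synth_illumination((8, 8), "bendy-mirror")


class TestEmptyBeamCorrection:
    def test_identical_images_give_unity(self):
        img = 1.0 + np.random.default_rng(0).random((32, 32))
        out = empty_beam_correct(img, img)
        np.testing.assert_allclose(out.intensity, 1.0)
        assert out.empty_beam_corrected

    def test_round_trip_removes_illumination(self):
        phi = weak_phase_object(256, amplitude=0.1)
        geom = BeamGeometry(np.inf, 0.002, 13.8, 5.2e-8)
        illum = synth_illumination((256, 256), "waveguide", seed=2)
        sample = simulate_hologram(phi, np.zeros_like(phi), geom,
                                   illumination=illum)
        empty = simulate_hologram(np.zeros_like(phi), np.zeros_like(phi), geom,
                                  illumination=illum)
        corrected = empty_beam_correct(sample, empty.intensity)
        flat = simulate_hologram(phi, np.zeros_like(phi), geom)
        assert np.abs(corrected.intensity - flat.intensity).max() < 0.01

    def test_dead_pixels_floored_no_nan(self):
        img = np.ones((16, 16))
        empty = np.ones((16, 16))
        empty[3, 4] = 0.0
        out = empty_beam_correct(img, empty)
        assert np.isfinite(out.intensity).all()

    def test_zero_empty_image_rejected(self):
        with pytest.raises(ValueError):
            empty_beam_correct(np.ones((8, 8)), np.zeros((8, 8)))
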
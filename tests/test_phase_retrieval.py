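"""Multi-distance CTF inversion and single-distance TIE inversion."""

import numpy as np
import pytest
import scipy.fft as sfft
from scipy import ndimage

from zoomtomo.geometry import BeamGeometry
from zoomtomo.phase_retrieval import ctf_factors, ctf_retrieve, tie_retrieve
from zoomtomo.propagation import Hologram, simulate_hologram

from conftest import four_distance_geometries, simulate_corrected_set, weak_phase_object


@pytest.fixture(scope="module")
def geoms():
    return four_distance_geometries()


class TestCTFFactors:
    def test_contact_plane_has_no_phase_contrast(self):
        g = BeamGeometry(0.1, 0.0, 13.8, 6.54e-6)
        model = ctf_factors([g], (32, 32))
        assert np.allclose(model.chi[0], 0)
        assert np.allclose(np.sin(model.chi[0]), 0)

    def test_first_zero_location(self, geoms):
        g = geoms[0]
        model = ctf_factors([g], (256, 256), effective_pixel=g.effective_pixel)
        f_zero = 1.0 / np.sqrt(g.wavelength * g.effective_distance)
        fy = sfft.fftfreq(model.padded_shape[0], d=g.effective_pixel)
        # sin(chi) along the frequency axis turns negative past the zero
        positive = np.sort(fy[fy > 0])
        chi_axis = np.pi * g.wavelength * g.effective_distance * positive**2
        crossing = positive[np.argmax(np.sin(chi_axis) < 0)]
        df = positive[0]
        assert abs(crossing - f_zero) <= 1.5 * df

    def test_four_distances_fill_single_distance_zeros(self, geoms):
        ref_px = geoms[0].effective_pixel
        multi = ctf_factors(geoms, (128, 128), effective_pixel=ref_px)
        single = ctf_factors([geoms[0]], (128, 128), effective_pixel=ref_px)
        fy = sfft.fftfreq(multi.padded_shape[0], d=ref_px)
        band = (np.abs(fy[:, None]) > 0) | (np.abs(fy[None, :]) > 0)
        sum_multi = sum(s**2 for s in multi.s)
        sum_single = single.s[0] ** 2
        assert sum_multi[band].min() > 10 * sum_single[band].min()

    def test_inconsistent_pixels_rejected(self, geoms):
        with pytest.raises(ValueError, match="effective pixel"):
            ctf_factors(geoms, (32, 32))  # no explicit reference pixel


class TestCTFRetrieve:
    def test_flat_holograms_give_zero_phase(self, geoms):
        model = ctf_factors(geoms, (64, 64),
                            effective_pixel=geoms[0].effective_pixel)
        flat = [np.ones((64, 64)) for _ in geoms]
        pm = ctf_retrieve(flat, model)
        assert np.abs(pm.values).max() < 1e-12

    def test_four_distance_noiseless_round_trip(self, geoms):
        phi = weak_phase_object(256, amplitude=0.1)
        holos = simulate_corrected_set(phi, geoms)
        model = ctf_factors(geoms, phi.shape,
                            effective_pixel=geoms[0].effective_pixel)
        pm = ctf_retrieve(holos, model)
        rmse = np.sqrt(((pm.values - phi) ** 2).mean())
        assert rmse < 0.005

    def test_noisy_round_trip_keeps_feature_scale_correlation(self, geoms):
        # photon budget of the zoom scan: 2.1e8 photons/um^2 over 900
        # projections
        phi = weak_phase_object(256, amplitude=0.1)
        holos = simulate_corrected_set(phi, geoms, fluence=2.1e8,
                                       n_frames=900, seed=10)
        model = ctf_factors(geoms, phi.shape,
                            effective_pixel=geoms[0].effective_pixel)
        pm = ctf_retrieve(holos, model)
        raw = np.corrcoef(pm.values.ravel(), phi.ravel())[0, 1]
        assert raw > 0.7
        # over the well-transferred band (feature scale) the maps agree
        a = ndimage.gaussian_filter(pm.values, 2)
        b = ndimage.gaussian_filter(phi, 2)
        assert np.corrcoef(a.ravel(), b.ravel())[0, 1] > 0.95

    def test_uncorrected_hologram_rejected(self, geoms):
        model = ctf_factors([geoms[0]], (32, 32),
                            effective_pixel=geoms[0].effective_pixel)
        holo = Hologram(np.ones((32, 32)), geoms[0], empty_beam_corrected=False)
        with pytest.raises(ValueError, match="corrected"):
            ctf_retrieve([holo], model)

    def test_single_distance_zero_alpha_singular(self, geoms):
        model = ctf_factors([geoms[0]], (32, 32),
                            effective_pixel=geoms[0].effective_pixel,
                            alpha_low=0.0, alpha_high=0.0)
        with pytest.raises(ValueError, match="singular"):
            ctf_retrieve([np.ones((32, 32))], model)

    def test_linearity_in_hologram_contrast(self, geoms):
        phi_a = weak_phase_object(128, amplitude=0.02, seed=3)
        phi_b = weak_phase_object(128, amplitude=0.02, seed=4)
        model = ctf_factors(geoms, (128, 128),
                            effective_pixel=geoms[0].effective_pixel)
        ha = simulate_corrected_set(phi_a, geoms)
        hb = simulate_corrected_set(phi_b, geoms)
        hsum = [
            Hologram(a.intensity + b.intensity - 1.0, a.geometry,
                     empty_beam_corrected=True)
            for a, b in zip(ha, hb)
        ]
        pa = ctf_retrieve(ha, model, margin=8).values
        pb = ctf_retrieve(hb, model, margin=8).values
        psum = ctf_retrieve(hsum, model, margin=8).values
        # weak-object linearity up to the (quadratic) simulation error
        np.testing.assert_allclose(psum, pa + pb, atol=5e-4)

    def test_alpha_ladder_converges_to_truth(self, geoms):
        phi = weak_phase_object(128, amplitude=0.05)
        holos = simulate_corrected_set(phi, geoms)
        errors = []
        for alpha in (1.0, 3e-1, 1e-1, 3e-2, 1e-2):
            model = ctf_factors(geoms, phi.shape,
                                effective_pixel=geoms[0].effective_pixel,
                                alpha_low=alpha, alpha_high=alpha)
            pm = ctf_retrieve(holos, model)
            errors.append(np.sqrt(((pm.values - phi) ** 2).mean()))
        assert all(a > b for a, b in zip(errors, errors[1:]))

    def test_single_distance_error_concentrates_in_zero_rings(self, geoms):
        phi = weak_phase_object(256, amplitude=0.1)
        holos = simulate_corrected_set(phi, geoms)
        ref_px = geoms[0].effective_pixel
        multi = ctf_factors(geoms, phi.shape, effective_pixel=ref_px)
        single = ctf_factors([geoms[0]], phi.shape, effective_pixel=ref_px)
        err_m = ctf_retrieve(holos, multi).values - phi
        err_s = ctf_retrieve([holos[0]], single).values - phi
        fy = sfft.fftfreq(phi.shape[0], d=ref_px)
        f2 = fy[:, None] ** 2 + fy[None, :] ** 2
        chi = np.pi * geoms[0].wavelength * geoms[0].effective_distance * f2
        ring = (np.abs(np.sin(chi)) < 0.2) & (f2 > 0)
        e_m = np.sqrt((np.abs(sfft.fft2(err_m))[ring] ** 2).mean())
        e_s = np.sqrt((np.abs(sfft.fft2(err_s))[ring] ** 2).mean())
        assert e_s / e_m >= 5.0


class TestTIE:
    def test_flat_hologram_gives_zero_phase(self, geoms):
        holo = Hologram(np.ones((64, 64)), geoms[0], empty_beam_corrected=True)
        pm = tie_retrieve(holo)
        assert np.abs(pm.values).max() < 1e-12

    def test_direct_regime_tie_matches_ctf(self):
        # F ~ 1 at the ten-pixel feature scale, smooth object
        px = 5.16e-8
        lam = BeamGeometry(np.inf, 1.0, 13.8, px).wavelength
        z = (10 * px) ** 2 / (lam * 1.0)
        geom = BeamGeometry(np.inf, z, 13.8, px)
        gen = np.random.default_rng(5)
        field = ndimage.gaussian_filter(gen.standard_normal((256, 256)), 6)
        window = np.zeros((256, 256))
        window[40:-40, 40:-40] = 1.0
        window = ndimage.gaussian_filter(window, 8)
        phi = field * window
        phi *= 0.05 / np.abs(phi).max()
        holo = simulate_hologram(phi, np.zeros_like(phi), geom)
        holo.empty_beam_corrected = True
        ctf_pm = ctf_retrieve([holo], ctf_factors([geom], phi.shape))
        tie_pm = tie_retrieve(holo)
        r = np.corrcoef(ctf_pm.values.ravel(), tie_pm.values.ravel())[0, 1]
        assert r > 0.98

    def test_holographic_regime_tie_loses_to_ctf(self):
        px = 5.16e-8
        lam = BeamGeometry(np.inf, 1.0, 13.8, px).wavelength
        z = (10 * px) ** 2 / (lam * 0.01)  # F = 0.01
        geom = BeamGeometry(np.inf, z, 13.8, px)
        phi = weak_phase_object(256, amplitude=0.1)
        holo = simulate_hologram(phi, np.zeros_like(phi), geom)
        holo.empty_beam_corrected = True
        ctf_pm = ctf_retrieve([holo], ctf_factors([geom], phi.shape))
        with pytest.warns(RuntimeWarning, match="direct-contrast"):
            tie_pm = tie_retrieve(holo)
        e_ctf = np.sqrt(((ctf_pm.values - phi) ** 2).mean())
        e_tie = np.sqrt(((tie_pm.values - phi) ** 2).mean())
        assert e_tie / e_ctf >= 2.0

    def test_zero_distance_rejected(self):
        g = BeamGeometry(0.1, 0.0, 13.8, 6.54e-6)
        holo = Hologram(np.ones((16, 16)), g, empty_beam_corrected=True)
        with pytest.raises(ValueError, match="effective distance"):
            tie_retrieve(holo)
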
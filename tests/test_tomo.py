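"""Rotation-center estimation and filtered back-projection."""

import numpy as np
import pytest
from scipy import ndimage
from skimage.transform import radon

from zoomtomo.geometry import wavelength_from_energy
from zoomtomo.phantom import PhantomSpec, generate_lung_phantom, project_volume
from zoomtomo.tomo import (
    Sinogram,
    fbp_reconstruct,
    find_rotation_center,
    reconstruct_volume,
)

VOX = 1e-7


def cylinder_slice(n=64, radius=20, value=1e-6):
    yy, xx = np.mgrid[:n, :n]
    c = (n - 1) / 2
    return (((yy - c) ** 2 + (xx - c) ** 2) <= radius**2) * value


def sinogram_of(image, angles):
    rows = [radon(image, theta=[np.degrees(a)], circle=False).ravel()
            for a in angles]
    return np.stack(rows) * VOX


@pytest.fixture(scope="module")
def cylinder_sino():
    angles = np.linspace(0, np.pi, 720, endpoint=False)
    return Sinogram(sinogram_of(cylinder_slice(), angles), angles)


class TestRotationCenter:
    def test_centered_sinogram(self, cylinder_sino):
        est = find_rotation_center(cylinder_sino)
        mid = (cylinder_sino.values.shape[1] - 1) / 2
        assert not est.degenerate
        assert est.center == pytest.approx(mid, abs=0.25)

    def test_injected_offset_recovered(self):
        angles = np.linspace(0, np.pi, 360, endpoint=False)
        yy, xx = np.mgrid[:64, :64]
        blob = (((yy - 25) ** 2 + (xx - 38) ** 2) <= 100) * 1e-6
        sino = sinogram_of(blob, angles)
        shifted = ndimage.shift(sino, (0, 5.0), order=3, mode="nearest")
        est = find_rotation_center(Sinogram(shifted, angles))
        mid = (sino.shape[1] - 1) / 2
        assert est.center == pytest.approx(mid + 5.0, abs=0.25)

    def test_constant_sinogram_degenerate(self):
        angles = np.linspace(0, np.pi, 90, endpoint=False)
        est = find_rotation_center(Sinogram(np.ones((90, 33)), angles))
        assert est.degenerate

    def test_insufficient_coverage_rejected(self):
        angles = np.linspace(0, np.pi / 2, 45, endpoint=False)
        with pytest.raises(ValueError, match="coverage"):
            find_rotation_center(Sinogram(np.ones((45, 33)), angles))


class TestFBP:
    def test_zero_sinogram_gives_zero_slice(self):
        angles = np.linspace(0, np.pi, 90, endpoint=False)
        out = fbp_reconstruct(Sinogram(np.zeros((90, 33)), angles),
                              voxel_size=VOX)
        assert np.abs(out).max() < 1e-15

    def test_cylinder_interior_value_and_edge_width(self, cylinder_sino):
        recon = fbp_reconstruct(cylinder_sino, voxel_size=VOX)
        n_det = cylinder_sino.values.shape[1]
        pad = (n_det - 64) // 2
        recon = recon[pad : pad + 64, pad : pad + 64]
        truth = cylinder_slice()
        yy, xx = np.mgrid[:64, :64]
        c = (64 - 1) / 2
        interior = ((yy - c) ** 2 + (xx - c) ** 2) <= 17**2
        assert recon[interior].mean() == pytest.approx(1e-6, rel=0.02)
        # 10-90% edge response width along the midline
        row = recon[32, :]
        lo, hi = 0.1e-6, 0.9e-6
        rising = row[:32]
        x10 = np.interp(lo, rising, np.arange(32))
        x90 = np.interp(hi, rising, np.arange(32))
        assert (x90 - x10) <= 2.0

    def test_linearity(self, cylinder_sino):
        base = fbp_reconstruct(cylinder_sino, voxel_size=VOX)
        scaled_sino = Sinogram(3.0 * cylinder_sino.values, cylinder_sino.angles)
        scaled = fbp_reconstruct(scaled_sino, voxel_size=VOX)
        np.testing.assert_allclose(scaled, 3.0 * base, rtol=1e-10, atol=1e-18)

    def test_nan_rejected(self):
        angles = np.linspace(0, np.pi, 90, endpoint=False)
        values = np.zeros((90, 33))
        values[5, 5] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            fbp_reconstruct(Sinogram(values, angles), voxel_size=VOX)

    def test_projection_theorem_round_trip(self, cylinder_sino):
        """Reprojecting the reconstruction reproduces the sinogram."""
        recon = fbp_reconstruct(cylinder_sino, voxel_size=VOX)
        angles = cylinder_sino.angles[::24]
        reproj = sinogram_of(recon / VOX * VOX, angles) / VOX * VOX
        reproj = np.stack([
            radon(recon, theta=[np.degrees(a)], circle=False).ravel() * VOX
            for a in angles
        ])
        # radon of the (padded) recon is wider; compare central overlap
        n_in = cylinder_sino.values.shape[1]
        n_out = reproj.shape[1]
        lo = (n_out - n_in) // 2
        reproj_c = reproj[:, lo : lo + n_in]
        ref = cylinder_sino.values[::24]
        err = np.linalg.norm(reproj_c - ref) / np.linalg.norm(ref)
        assert err < 0.05

    def test_angular_undersampling_stable_interior(self):
        full = np.linspace(0, np.pi, 720, endpoint=False)
        half = full[::2]
        img = cylinder_slice()
        yy, xx = np.mgrid[:64, :64]
        interior = ((yy - 31.5) ** 2 + (xx - 31.5) ** 2) <= 17**2
        means = []
        for angles in (full, half):
            sino = Sinogram(sinogram_of(img, angles), angles)
            rec = fbp_reconstruct(sino, voxel_size=VOX)
            pad = (sino.values.shape[1] - 64) // 2
            means.append(rec[pad : pad + 64, pad : pad + 64][interior].mean())
        assert abs(means[1] / means[0] - 1) < 0.02


class TestReconstructVolume:
    @pytest.fixture(scope="class")
    def phantom_and_recon(self):
        vol = generate_lung_phantom(PhantomSpec(voxel_size=52e-9, seed=1))
        angles = np.linspace(0, np.pi, 180, endpoint=False)
        stack = np.stack([project_volume(vol, a)[0] for a in angles])
        recon = reconstruct_volume(
            stack, angles,
            wavelength=wavelength_from_energy(13.8), voxel_size=52e-9,
        )
        return vol, recon

    def test_volume_correlates_with_truth(self, phantom_and_recon):
        vol, recon = phantom_and_recon
        r = np.corrcoef(recon.delta.ravel(), vol.delta.ravel())[0, 1]
        assert r > 0.95

    def test_cluster_centroids_recovered(self, phantom_and_recon):
        vol, recon = phantom_and_recon
        for c in vol.clusters:
            zl, yl, xl = (int(round(v)) for v in c.centroid)
            sub = np.clip(
                recon.delta[zl - 3 : zl + 4, yl - 3 : yl + 4, xl - 3 : xl + 4]
                - 2e-6, 0, None,
            )
            com = ndimage.center_of_mass(sub)
            est = np.array([zl - 3 + com[0], yl - 3 + com[1], xl - 3 + com[2]])
            assert np.linalg.norm(est - np.array(c.centroid)) < 1.0

    def test_identical_phase_maps_reconstruct_symmetric(self):
        # a full-turn scan of identical projections must reconstruct a
        # rotationally symmetric slice
        gen = np.random.default_rng(0)
        from scipy.ndimage import gaussian_filter

        row = gaussian_filter(gen.standard_normal(64), 4)
        row -= row[:4].mean()
        phase_map = np.tile(row, (8, 1)) * 0.01
        stack = np.tile(phase_map, (360, 1, 1))
        angles = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        recon = reconstruct_volume(
            stack, angles,
            wavelength=wavelength_from_energy(13.8), voxel_size=52e-9,
            center=(64 - 1) / 2,
        )
        sl = recon.delta[4]
        rot = np.rot90(sl)
        yy, xx = np.mgrid[:64, :64]
        inside = (yy - 31.5) ** 2 + (xx - 31.5) ** 2 < 25**2
        denom = np.abs(sl[inside]).max()
        assert np.abs((sl - rot)[inside]).max() / denom < 0.02

    def test_missing_angles_reported(self):
        angles = np.concatenate([
            np.linspace(0, 1.0, 40, endpoint=False),
            np.linspace(1.8, np.pi, 40, endpoint=False),
        ])
        stack = np.zeros((80, 4, 16))
        with pytest.raises(ValueError, match="missing"):
            reconstruct_volume(stack, angles,
                               wavelength=1e-10, voxel_size=52e-9)
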
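"""Shared fixtures: geometries, weak-phase objects, simulated hologram sets."""

import numpy as np
import pytest
from scipy import ndimage

from zoomtomo.geometry import BeamGeometry
from zoomtomo.propagation import simulate_hologram


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def weak_phase_object(n: int, amplitude: float = 0.1, seed: int = 1) -> np.ndarray:
    """Smooth, compactly supported random phase map with zero margins."""
    gen = np.random.default_rng(seed)
    field = ndimage.gaussian_filter(gen.standard_normal((n, n)), 4)
    window = np.zeros((n, n))
    m = max(8, n // 6)
    window[m:-m, m:-m] = 1.0
    window = ndimage.gaussian_filter(window, m / 5)
    phi = field * window
    return phi * (amplitude / np.abs(phi).max())


def four_distance_geometries(energy_kev: float = 13.8) -> list[BeamGeometry]:
    """Zoom-style defocus series: four distances at a fixed 5.07 m detector."""
    z_tot = 5.07
    return [
        BeamGeometry(z1, z_tot - z1, energy_kev, 6.54e-6)
        for z1 in (0.0403, 0.0433, 0.0463, 0.0493)
    ]


def constant_mag_geometries(energy_kev: float = 13.8) -> list[BeamGeometry]:
    """Constant-magnification defocus series (detector follows the
    sample): shared effective pixel, distinct effective distances."""
    magnification = 0.19 / 0.0015
    return [
        BeamGeometry(z1, z1 * magnification - z1, energy_kev, 6.54e-6)
        for z1 in (0.0015, 0.0018, 0.0021, 0.0024)
    ]


def simulate_corrected_set(phi, geometries, reference=None, fluence=None,
                           n_frames=1, seed=None):
    """Noise-optional corrected holograms of one weak-phase projection,
    simulated on the reference effective-pixel grid (pre-resampled data)."""
    ref = reference or geometries[0]
    out = []
    for i, g in enumerate(geometries):
        parallel = BeamGeometry(np.inf, g.effective_distance, g.energy_kev,
                                ref.effective_pixel)
        holo = simulate_hologram(
            phi, np.zeros_like(phi), parallel,
            fluence=fluence, n_frames=n_frames,
            rng=None if seed is None else seed + i,
        )
        holo.empty_beam_corrected = True
        holo.geometry = g
        out.append(holo)
    return out


@pytest.fixture(autouse=True)
def _quiet_aliasing_warnings():
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="Fresnel kernel undersampled", category=RuntimeWarning
        )
        yield
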
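"""Forward holography: Fresnel propagation and hologram simulation.

Propagation is spectral: the wavefield spectrum is multiplied by the
paraxial free-space kernel ``H(f) = exp(-i*pi*lambda*z*|f|^2)`` (the global
plane-wave phase is dropped).  The cone beam of a point source is handled
entirely by the Fresnel scaling theorem: a hologram recorded at
magnification M equals the plane-wave hologram at the effective distance
``z_eff = z1*z2/(z1+z2)`` sampled on the effective-pixel grid ``p/M``, so
``simulate_hologram`` always propagates the parallel-equivalent problem.

Simulated intensities are normalized to unit mean illumination; photon
noise is applied as Poisson counts at the per-pixel photon budget implied
by the scan fluence.  Illumination (empty-beam) structure can be synthetic
KB-mirror stripes or the smooth envelope of a waveguide-filtered beam, and
``empty_beam_correct`` performs the standard flat-field ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import fft as sp_fft
from scipy import ndimage

from zoomtomo.geometry import BeamGeometry

__all__ = [
    "Wavefield",
    "Hologram",
    "AliasingError",
    "fresnel_propagate",
    "simulate_hologram",
    "synth_illumination",
    "empty_beam_correct",
    "photons_per_pixel",
]


class AliasingError(ValueError):
    """Kernel sampling is inadequate and strict mode was requested."""


@dataclass
class Wavefield:
    """Complex scalar wave on a regular 2D grid."""

    amplitude: np.ndarray  # complex 2D
    pixel_size: float  # m
    wavelength: float  # m

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=np.complex128)
        if self.amplitude.ndim != 2:
            raise ValueError("wavefield must be 2D")
        if not np.all(np.isfinite(self.amplitude)):
            raise ValueError("wavefield contains non-finite values")
        if self.pixel_size <= 0 or self.wavelength <= 0:
            raise ValueError("pixel size and wavelength must be positive")

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.amplitude) ** 2


@dataclass
class Hologram:
    """Measured (or simulated) near-field intensity with its geometry."""

    intensity: np.ndarray
    geometry: BeamGeometry | None = None
    fresnel_number: float | None = None
    fluence: float | None = None  # photons/um^2 attributed to this frame
    empty_beam_corrected: bool = False

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if (self.intensity < 0).any():
            raise ValueError("hologram intensities must be nonnegative")


def _kernel_phase_step_ok(n: int, pixel: float, wavelength: float, z: float) -> bool:
    """True when the kernel phase changes < pi per sample at the grid edge."""
    f_max = 1.0 / (2.0 * pixel)
    df = 1.0 / (n * pixel)
    return 2.0 * np.pi * wavelength * abs(z) * f_max * df <= np.pi


def fresnel_propagate(
    field: Wavefield,
    distance: float,
    *,
    pad: bool = True,
    strict: bool = False,
) -> Wavefield:
    """Propagate a wavefield by ``distance`` metres (may be negative).

    ``pad=True`` reflect-pads to twice the linear size before the FFT and
    crops afterwards, suppressing wrap-around fringes.  With ``pad=False``
    the operator is exactly unitary and forms a one-parameter group in the
    propagation distance (propagating z1 then z2 equals z1+z2 to rounding).

    If the kernel phase step at the edge of the (padded) grid exceeds pi
    per sample the quadratic phase is undersampled; a warning is emitted,
    or :class:`AliasingError` raised when ``strict``.
    """
    if distance == 0.0:
        return replace(field, amplitude=field.amplitude.copy())
    a = field.amplitude
    ny, nx = a.shape
    if pad:
        py, px = ny // 2, nx // 2
        a = np.pad(a, ((py, py), (px, px)), mode="reflect")
    my, mx = a.shape
    if not (
        _kernel_phase_step_ok(my, field.pixel_size, field.wavelength, distance)
        and _kernel_phase_step_ok(mx, field.pixel_size, field.wavelength, distance)
    ):
        msg = (
            "Fresnel kernel undersampled at the grid edge "
            f"(N={a.shape}, pixel={field.pixel_size:.3g} m, z={distance:.3g} m); "
            "wrap-around replicas will alias"
        )
        if strict:
            raise AliasingError(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
    fy = sp_fft.fftfreq(my, d=field.pixel_size)
    fx = sp_fft.fftfreq(mx, d=field.pixel_size)
    f2 = fy[:, None] ** 2 + fx[None, :] ** 2
    kernel = np.exp(-1j * np.pi * field.wavelength * distance * f2)
    out = sp_fft.ifft2(sp_fft.fft2(a) * kernel)
    if pad:
        out = out[py : py + ny, px : px + nx]
    return replace(field, amplitude=out)


def photons_per_pixel(
    total_fluence: float, n_frames: int, effective_pixel: float
) -> float:
    """Photon budget per detector pixel per frame.

    ``total_fluence`` is the scan total in photons/um^2 (the convention of
    scan metadata), split evenly over ``n_frames`` frames; the object-plane
    pixel area converts areal fluence to counts.
    """
    if total_fluence < 0:
        raise ValueError("fluence must be nonnegative")
    area_um2 = (effective_pixel * 1e6) ** 2
    return total_fluence / n_frames * area_um2


def simulate_hologram(
    phase: np.ndarray,
    absorption: np.ndarray,
    geom: BeamGeometry,
    *,
    illumination: np.ndarray | None = None,
    fluence: float | None = None,
    n_frames: int = 1,
    rng: np.random.Generator | int | None = None,
    source_blur_fwhm: float = 0.0,
) -> Hologram:
    """Simulate one empty-beam-uncorrected in-line hologram.

    The exit wave ``T = exp(-B + i*phi)`` (sampled on the effective-pixel
    grid of ``geom``) is multiplied by the illumination amplitude,
    propagated by the effective distance, and squared.  If ``fluence``
    (photons/um^2, scan total over ``n_frames`` frames) is given, Poisson
    noise is applied at the implied counts per pixel; the returned
    intensity stays in flat-field units (mean ~ illumination).

    ``source_blur_fwhm`` (metres, object plane) optionally applies a
    Gaussian blur emulating a finite source; the default is an ideal point
    source, appropriate for a nanoscale waveguide exit.
    """
    phase = np.asarray(phase, dtype=np.float64)
    absorption = np.asarray(absorption, dtype=np.float64)
    if phase.shape != absorption.shape:
        raise ValueError(
            f"phase {phase.shape} and absorption {absorption.shape} shapes differ"
        )
    if illumination is not None and illumination.shape != phase.shape:
        raise ValueError("illumination shape must match the maps")
    if fluence is not None and fluence < 0:
        raise ValueError("fluence must be nonnegative")

    exit_wave = np.exp(-absorption + 1j * phase)
    if illumination is not None:
        exit_wave = exit_wave * np.sqrt(np.asarray(illumination, dtype=np.float64))
    field = Wavefield(exit_wave, geom.effective_pixel, geom.wavelength)
    intensity = fresnel_propagate(field, geom.effective_distance).intensity

    if source_blur_fwhm > 0.0:
        sigma_px = source_blur_fwhm / 2.3548200450309493 / geom.effective_pixel
        intensity = ndimage.gaussian_filter(intensity, sigma_px)

    if fluence is not None and fluence > 0:
        n_ph = photons_per_pixel(fluence, n_frames, geom.effective_pixel)
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        intensity = gen.poisson(np.clip(intensity, 0, None) * n_ph) / n_ph

    return Hologram(
        intensity=intensity,
        geometry=geom,
        fresnel_number=geom.fresnel_number(),
        fluence=None if fluence is None else fluence / n_frames,
        empty_beam_corrected=illumination is None,
    )


def synth_illumination(
    shape: tuple[int, int],
    mode: str = "flat",
    seed: int | None = 0,
) -> np.ndarray:
    """Synthetic illumination (empty-beam) intensity pattern, mean 1.

    ``flat``
        Uniform ones.
    ``waveguide``
        Smooth low-order envelope only, emulating the mode-filtered,
        near-aberration-free exit wave of an x-ray waveguide.
    ``kb_artifacts``
        The same smooth envelope plus high-frequency stripe artefacts as
        produced by mirror figure errors of a KB focus.

    Deterministic in ``seed``; total power matched across modes.
    """
    ny, nx = shape
    if mode == "flat":
        return np.ones(shape)
    if mode not in ("waveguide", "kb_artifacts"):
        raise ValueError(f"unknown illumination mode: {mode!r}")
    rng = np.random.default_rng(seed)
    y = np.linspace(-1, 1, ny)[:, None]
    x = np.linspace(-1, 1, nx)[None, :]
    envelope = np.exp(-(y**2 + x**2) / 1.8) * (
        1.0 + 0.08 * y + 0.05 * x + 0.06 * y * x
    )
    if mode == "kb_artifacts":
        stripes = np.zeros(shape)
        for _ in range(12):
            fr = rng.uniform(8, 30)  # cycles across the field
            ph = rng.uniform(0, 2 * np.pi)
            stripes += rng.uniform(0.3, 1.0) * np.sin(np.pi * fr * y + ph)
        for _ in range(12):
            fr = rng.uniform(8, 30)
            ph = rng.uniform(0, 2 * np.pi)
            stripes += rng.uniform(0.3, 1.0) * np.sin(np.pi * fr * x + ph)
        stripes /= np.abs(stripes).max()
        envelope = envelope * (1.0 + 0.25 * stripes)
    envelope = np.clip(envelope, 1e-3, None)
    # match total power (mean intensity 1)
    return envelope / envelope.mean()


def empty_beam_correct(
    sample: Hologram | np.ndarray,
    empty: np.ndarray,
    *,
    floor_frac: float = 1e-6,
) -> Hologram:
    """Flat-field (empty-beam) correction: pixelwise ``I_sample/I_empty``.

    ``empty`` is floored at ``floor_frac * max(empty)`` so dead pixels
    cannot produce NaN/Inf.  Raises if the empty image carries no signal.
    """
    if isinstance(sample, Hologram):
        intensity, geom, fn, fl = (
            sample.intensity,
            sample.geometry,
            sample.fresnel_number,
            sample.fluence,
        )
    else:
        intensity = np.asarray(sample, dtype=np.float64)
        geom = fn = fl = None
    empty = np.asarray(empty, dtype=np.float64)
    if empty.shape != intensity.shape:
        raise ValueError("sample and empty images must share a shape")
    peak = empty.max()
    if not peak > 0:
        raise ValueError("empty-beam image is identically zero")
    corrected = intensity / np.clip(empty, floor_frac * peak, None)
    return Hologram(
        intensity=corrected,
        geometry=geom,
        fresnel_number=fn,
        fluence=fl,
        empty_beam_corrected=True,
    )
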
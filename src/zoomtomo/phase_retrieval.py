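"""Phase retrieval from empty-beam-corrected in-line holograms.

Weak-object contrast-transfer-function (CTF) theory linearizes the hologram
of an object with exit wave ``T = exp(-B + i*phi)``: in Fourier space the
flat-field contrast of distance ``d`` obeys

    FT(I_d - 1)(f) = 2 * s_d(f) * FT(phi)(f),
    s_d(f) = sin(chi_d) + (beta/delta) * cos(chi_d),
    chi_d(f) = pi * lambda * z_eff,d * |f|^2,

where the homogeneous-object ratio beta/delta couples absorption to phase
(0 for a pure phase object).  Inversion is the regularized least-squares
combination over all distances,

    phi_hat(f) = sum_d s_d * FT(I_d - 1) / (2 * sum_d s_d^2 + alpha(f)).

A single distance leaves blind rings at the zeros of s_d; several distances
with distinct effective propagation move the zeros apart so the summed
response stays bounded away from zero — the reason multi-distance scans are
acquired.  The transport-of-intensity (TIE) inversion implemented here is
the small-chi limit of the same expression, accurate only at low spatial
frequency, i.e. in the direct-contrast regime.

Regularization is two-level: a small alpha below the first zero crossing of
the shortest distance (where the data constrain phase well) and a larger
alpha above it.  The absolute phase offset is unobservable; the DC
convention sets the median phase over an object-free margin to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft

from zoomtomo.geometry import BeamGeometry
from zoomtomo.propagation import Hologram

__all__ = [
    "CTFModel",
    "PhaseMap",
    "ctf_factors",
    "ctf_retrieve",
    "tie_retrieve",
]

DEFAULT_ALPHA_LOW = 1e-4
DEFAULT_ALPHA_HIGH = 1e-1


@dataclass
class CTFModel:
    """Discrete transfer factors of a multi-distance CTF inversion.

    All spectral arrays are sampled on the padded FFT grid of the images to
    be inverted (``padded_shape``); ``shape`` is the unpadded image shape.
    """

    shape: tuple[int, int]
    padded_shape: tuple[int, int]
    pixel_size: float
    wavelength: float
    distances: tuple[float, ...]  # effective propagation distances (m)
    chi: list[np.ndarray] = field(repr=False, default_factory=list)
    s: list[np.ndarray] = field(repr=False, default_factory=list)
    alpha: np.ndarray | None = field(repr=False, default=None)
    delta_beta_ratio: float = np.inf  # delta/beta; inf => pure phase object

    @property
    def beta_delta(self) -> float:
        return 0.0 if np.isinf(self.delta_beta_ratio) else 1.0 / self.delta_beta_ratio


def _padded_shape(shape: tuple[int, int]) -> tuple[tuple[int, int], tuple[int, int]]:
    ny, nx = shape
    py, px = ny // 2, nx // 2
    return (ny + 2 * py, nx + 2 * px), (py, px)


def ctf_factors(
    geometries: list[BeamGeometry] | BeamGeometry,
    shape: tuple[int, int],
    effective_pixel: float | None = None,
    *,
    delta_beta_ratio: float = np.inf,
    alpha_low: float = DEFAULT_ALPHA_LOW,
    alpha_high: float = DEFAULT_ALPHA_HIGH,
) -> CTFModel:
    """Build the CTF transfer factors for a set of hologram geometries.

    All geometries must share the effective pixel of the reference grid
    (after resampling, see :mod:`zoomtomo.registration`); a mismatch above
    0.1% raises.  ``delta_beta_ratio`` is delta/beta of the homogeneous-object
    assumption (``inf`` = pure phase).
    """
    if isinstance(geometries, BeamGeometry):
        geometries = [geometries]
    if not geometries:
        raise ValueError("at least one geometry required")
    pixels = [g.effective_pixel for g in geometries]
    if effective_pixel is not None:
        # caller vouches that all holograms were resampled onto this grid
        ref_px = effective_pixel
    else:
        ref_px = pixels[0]
        for p in pixels:
            if abs(p - ref_px) > 1e-3 * ref_px:
                raise ValueError(
                    "geometries have inconsistent effective pixels "
                    f"({pixels}); resample holograms to a common grid first "
                    "and pass effective_pixel explicitly"
                )
    lam = geometries[0].wavelength
    pshape, _ = _padded_shape(tuple(shape))
    fy = sp_fft.fftfreq(pshape[0], d=ref_px)
    fx = sp_fft.fftfreq(pshape[1], d=ref_px)
    f2 = fy[:, None] ** 2 + fx[None, :] ** 2

    beta_delta = 0.0 if np.isinf(delta_beta_ratio) else 1.0 / delta_beta_ratio
    distances = tuple(g.effective_distance for g in geometries)
    chi = [np.pi * lam * d * f2 for d in distances]
    s = [np.sin(c) + beta_delta * np.cos(c) for c in chi]

    # two-level alpha split at the first zero of sin(chi) of the shortest
    # nonzero distance
    pos = [d for d in distances if d > 0]
    if pos:
        f_cross2 = 1.0 / (lam * min(pos))  # |f|^2 at chi = pi
        alpha = np.where(f2 < f_cross2, alpha_low, alpha_high)
    else:
        alpha = np.full(pshape, alpha_low)

    return CTFModel(
        shape=tuple(shape),
        padded_shape=pshape,
        pixel_size=ref_px,
        wavelength=lam,
        distances=distances,
        chi=chi,
        s=s,
        alpha=alpha,
        delta_beta_ratio=delta_beta_ratio,
    )


@dataclass
class PhaseMap:
    """Retrieved projection phase in radians (negative for delta > 0)."""

    values: np.ndarray
    pixel_size: float
    distances: tuple[float, ...] = ()
    method: str = "ctf"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("phase map contains non-finite values")


def _margin_mask(shape: tuple[int, int], margin: int) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    mask[:margin, :] = mask[-margin:, :] = True
    mask[:, :margin] = mask[:, -margin:] = True
    return mask


def _contrast_spectrum(intensity: np.ndarray, pad: tuple[int, int]) -> np.ndarray:
    py, px = pad
    padded = np.pad(intensity - 1.0, ((py, py), (px, px)), mode="reflect")
    return sp_fft.fft2(padded)


def _check_corrected(holo: Hologram | np.ndarray) -> np.ndarray:
    if isinstance(holo, Hologram):
        if not holo.empty_beam_corrected:
            raise ValueError(
                "hologram is not empty-beam corrected; run empty_beam_correct first"
            )
        return holo.intensity
    return np.asarray(holo, dtype=np.float64)


def ctf_retrieve(
    holograms: list[Hologram] | list[np.ndarray] | Hologram,
    model: CTFModel,
    *,
    margin: int | None = None,
    margin_mask: np.ndarray | None = None,
) -> PhaseMap:
    """Invert a set of aligned, corrected holograms to one phase map.

    The holograms must be on the common reference grid (same shape and
    effective pixel) the model was built for, one per model distance.
    ``margin`` is the width in pixels of the object-free border used for
    the DC (zero-median) convention; default ``max(4, N//16)``.  When the
    object touches some borders, pass ``margin_mask`` (boolean, True on
    object-free pixels) instead.
    """
    if isinstance(holograms, Hologram):
        holograms = [holograms]
    if len(holograms) != len(model.distances):
        raise ValueError(
            f"{len(holograms)} holograms for {len(model.distances)} model distances"
        )
    if len(holograms) == 1 and not np.any(model.alpha > 0):
        raise ValueError(
            "single-distance CTF inversion with zero regularization is singular"
        )
    pshape, pad = _padded_shape(model.shape)

    num = np.zeros(pshape, dtype=np.complex128)
    den = np.zeros(pshape, dtype=np.float64)
    for holo, s in zip(holograms, model.s):
        intensity = _check_corrected(holo)
        if intensity.shape != model.shape:
            raise ValueError(
                f"hologram shape {intensity.shape} != model shape {model.shape}"
            )
        num += s * _contrast_spectrum(intensity, pad)
        den += s**2
    phi_hat = num / (2.0 * den + model.alpha)
    phi_hat[0, 0] = 0.0
    phi = sp_fft.ifft2(phi_hat).real
    py, px = pad
    phi = phi[py : py + model.shape[0], px : px + model.shape[1]]

    if margin_mask is not None:
        phi = phi - np.median(phi[margin_mask])
    else:
        m = margin if margin is not None else max(4, min(model.shape) // 16)
        phi = phi - np.median(phi[_margin_mask(model.shape, m)])
    return PhaseMap(phi, model.pixel_size, model.distances, method="ctf")


def tie_retrieve(
    hologram: Hologram,
    *,
    delta_beta_ratio: float = np.inf,
    alpha: float = 1e-3,
    margin: int | None = None,
    margin_mask: np.ndarray | None = None,
) -> PhaseMap:
    """Single-distance TIE-type inversion (small-chi limit of the CTF).

        phi_hat(f) = FT(I - 1) / (2*chi(f) + 2*beta/delta + alpha)

    Valid at low spatial frequency; intended for the direct-contrast regime
    (a warning is emitted when the hologram's Fresnel number is below 0.5).
    """
    geom = hologram.geometry
    if geom is None:
        raise ValueError("hologram carries no geometry")
    if geom.effective_distance <= 0:
        raise ValueError("zero effective distance: nothing to invert")
    fresnel = hologram.fresnel_number or geom.fresnel_number()
    if fresnel < 0.5:
        warnings.warn(
            f"TIE inversion outside the direct-contrast regime (F = {fresnel:.3g}); "
            "high frequencies will be wrong — prefer CTF retrieval",
            RuntimeWarning,
            stacklevel=2,
        )
    intensity = _check_corrected(hologram)
    shape = intensity.shape
    pshape, pad = _padded_shape(shape)
    fy = sp_fft.fftfreq(pshape[0], d=geom.effective_pixel)
    fx = sp_fft.fftfreq(pshape[1], d=geom.effective_pixel)
    chi = np.pi * geom.wavelength * geom.effective_distance * (
        fy[:, None] ** 2 + fx[None, :] ** 2
    )
    beta_delta = 0.0 if np.isinf(delta_beta_ratio) else 1.0 / delta_beta_ratio
    denom = 2.0 * chi + 2.0 * beta_delta + alpha
    phi_hat = _contrast_spectrum(intensity, pad) / denom
    phi_hat[0, 0] = 0.0
    phi = sp_fft.ifft2(phi_hat).real
    py, px = pad
    phi = phi[py : py + shape[0], px : px + shape[1]]
    if margin_mask is not None:
        phi = phi - np.median(phi[margin_mask])
    else:
        m = margin if margin is not None else max(4, min(shape) // 16)
        phi = phi - np.median(phi[_margin_mask(shape, m)])
    return PhaseMap(
        phi, geom.effective_pixel, (geom.effective_distance,), method="tie"
    )
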
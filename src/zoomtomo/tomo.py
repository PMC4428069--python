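"""Filtered back-projection of per-projection phase maps.

Retrieved phases are line integrals of the refractive decrement:
``phi = -k * integral(delta ds)``, so ``-phi/k`` is a standard parallel-beam
sinogram of delta.  After magnification correction the residual cone angle
of the zoom geometries is a few milliradians, and reconstruction is plain
parallel-beam FBP (no cone-beam weighting), slice by detector row.

Angle convention: radians, counter-clockwise; angle 0 projects along the +y
axis of the (z, y, x) volume grid, matching
:func:`zoomtomo.phantom.project_volume`.  The rotation center is estimated
from opposed (theta, theta+pi) projections, which mirror onto each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation
from skimage.transform import iradon

__all__ = [
    "Sinogram",
    "ReconVolume",
    "CenterEstimate",
    "find_rotation_center",
    "fbp_reconstruct",
    "reconstruct_volume",
]

_FILTERS = {"ram-lak": "ramp", "ramp": "ramp", "shepp-logan": "shepp-logan", "hann": "hann"}


@dataclass
class Sinogram:
    """Line integrals of one slice: shape (n_angles, n_detector)."""

    values: np.ndarray
    angles: np.ndarray  # radians, strictly increasing
    center: float | None = None  # rotation axis position in detector pixels

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.angles = np.asarray(self.angles, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.angles):
            raise ValueError(
                f"sinogram shape {self.values.shape} inconsistent with "
                f"{len(self.angles)} angles"
            )
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("angles must be strictly increasing")


@dataclass
class ReconVolume:
    """Reconstructed 3D refractive-decrement map, voxel = effective pixel."""

    delta: np.ndarray  # (z, y, x)
    voxel_size: float  # m
    provenance: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.delta.shape


@dataclass
class CenterEstimate:
    center: float  # detector pixels
    degenerate: bool  # True when the sinogram cannot constrain the center


def find_rotation_center(sinogram: Sinogram) -> CenterEstimate:
    """Rotation-axis position from opposed projections.

    A parallel projection at ``theta + pi`` is the mirror image of the one
    at ``theta`` about the rotation axis; cross-correlating a projection
    with its mirrored opposite therefore measures twice the axis offset
    from the detector centre.  Requires angular coverage >= pi (within one
    angular step).  A featureless sinogram yields a degenerate estimate at
    the detector centre.
    """
    angles = sinogram.angles
    if len(angles) < 2:
        raise ValueError("need at least two projections")
    step = np.median(np.diff(angles))
    span = angles[-1] - angles[0] + step
    if span < np.pi - 1e-9:
        raise ValueError(
            f"angular coverage {span:.3f} rad < pi: cannot locate the rotation axis"
        )
    n = sinogram.values.shape[1]
    mid = (n - 1) / 2.0

    if np.ptp(sinogram.values) < 1e-12 * max(1.0, np.abs(sinogram.values).max()):
        return CenterEstimate(center=mid, degenerate=True)

    # pair each of a few probe projections with the one closest to +pi away
    offsets = []
    for i in np.linspace(0, len(angles) // 4, 5, dtype=int):
        target = angles[i] + np.pi
        j = int(np.argmin(np.abs(angles - target)))
        if abs(angles[j] - target) > 2 * step:
            continue
        a = sinogram.values[i]
        b = sinogram.values[j][::-1]
        shift, _, _ = phase_cross_correlation(
            a[None, :], b[None, :], upsample_factor=8, normalization=None
        )
        offsets.append(shift[1] / 2.0)
    if not offsets:
        # coverage is [0, pi): the mirrored last projection approximates
        # the opposite of the first
        a = sinogram.values[0]
        b = sinogram.values[-1][::-1]
        shift, _, _ = phase_cross_correlation(
            a[None, :], b[None, :], upsample_factor=8, normalization=None
        )
        offsets.append(shift[1] / 2.0)
    return CenterEstimate(center=mid + float(np.median(offsets)), degenerate=False)


def fbp_reconstruct(
    sinogram: Sinogram,
    *,
    filter_name: str = "ram-lak",
    voxel_size: float = 1.0,
    center: float | None = None,
) -> np.ndarray:
    """Filtered back-projection of one sinogram slice.

    ``values`` are line integrals with physical path length (metres); the
    output is the integrand per voxel (delta if the input is
    ``-phi/k``).  ``center`` overrides the sinogram's stored rotation axis
    (default: detector centre).
    """
    if filter_name not in _FILTERS:
        raise ValueError(f"unknown filter {filter_name!r}; use one of {list(_FILTERS)}")
    values = sinogram.values
    if np.isnan(values).any():
        raise ValueError("sinogram contains NaN")
    n = values.shape[1]
    c = center if center is not None else sinogram.center
    if c is None:
        c = (n - 1) / 2.0
    # iradon assumes the rotation axis at projection index n//2 and places
    # it at output pixel (n//2, n//2); shift the sinogram onto that
    # convention and shift the slice back so the axis ends up at (c, c)
    # of the output grid.
    if abs(c - n // 2) > 1e-9:
        values = ndimage.shift(
            values, (0.0, n // 2 - c), order=3, mode="nearest", prefilter=True
        )
    recon = iradon(
        values.T,
        theta=np.degrees(sinogram.angles),
        filter_name=_FILTERS[filter_name],
        circle=False,
        output_size=n,
    )
    if abs(c - n // 2) > 1e-9:
        recon = ndimage.shift(
            recon, (c - n // 2, c - n // 2), order=3, mode="nearest", prefilter=True
        )
    return recon / voxel_size


def reconstruct_volume(
    phase_stack: np.ndarray,
    angles: np.ndarray,
    *,
    wavelength: float,
    voxel_size: float,
    filter_name: str = "ram-lak",
    center: float | None = None,
) -> ReconVolume:
    """Slice-by-slice FBP of a stack of retrieved phase maps.

    Parameters
    ----------
    phase_stack : ndarray, shape (n_angles, n_z, n_x)
        One phase map per tomographic angle (radians).
    angles : ndarray
        Strictly increasing tomographic angles in radians; coverage must
        reach pi within one angular step (missing angles are reported).
    wavelength : float
        Photon wavelength in metres (sets k for the -phi/k conversion).
    voxel_size : float
        Effective pixel = voxel size in metres.
    center : float, optional
        Rotation axis in detector pixels; estimated from the central slice
        when omitted.
    """
    phase_stack = np.asarray(phase_stack, dtype=np.float64)
    angles = np.asarray(angles, dtype=np.float64)
    if phase_stack.ndim != 3 or phase_stack.shape[0] != len(angles):
        raise ValueError("phase stack must be (n_angles, n_z, n_x) matching angles")
    steps = np.diff(angles)
    if np.any(steps <= 0):
        raise ValueError("angles must be strictly increasing")
    step = np.median(steps)
    gaps = np.where(steps > 1.5 * step)[0]
    if len(gaps):
        missing = [
            f"({angles[i]:.4f}, {angles[i+1]:.4f})" for i in gaps
        ]
        raise ValueError(f"missing angular ranges (rad): {', '.join(missing)}")
    if angles[-1] - angles[0] + step < np.pi - 1e-9:
        raise ValueError("angular coverage < pi")

    k = 2.0 * np.pi / wavelength
    n_angles, nz, nx = phase_stack.shape
    line_integrals = -phase_stack / k  # metres * delta

    if center is None:
        mid_sino = Sinogram(line_integrals[:, nz // 2, :], angles)
        est = find_rotation_center(mid_sino)
        center = est.center

    volume = np.empty((nz, nx, nx), dtype=np.float64)
    for iz in range(nz):
        sino = Sinogram(line_integrals[:, iz, :], angles, center=center)
        volume[iz] = fbp_reconstruct(
            sino, filter_name=filter_name, voxel_size=voxel_size
        )
    return ReconVolume(
        delta=volume,
        voxel_size=voxel_size,
        provenance={
            "filter": filter_name,
            "center": float(center),
            "n_angles": int(n_angles),
            "angle_range": (float(angles[0]), float(angles[-1])),
        },
    )
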
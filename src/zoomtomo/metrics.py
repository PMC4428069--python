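"""Quantitative metrology: dose accounting, Fourier shell correlation,
Gaussian feature sizing.

Dose: a fluence Phi (photons per um^2) of energy E deposits, in the thin-
sample limit, ``D = Phi * E * (mu/rho)`` gray, with the mass attenuation
coefficient of the sample medium (water by default).  Two coefficient
conventions are shipped — total attenuation and energy absorption — which
bracket the physically deposited energy depending on how much of the
scattered/fluoresced energy escapes the sample; total attenuation is the
default.

Resolution: the Fourier shell correlation of two independent
reconstructions of the same object,

    FSC(r) = |sum_shell F_a F_b*| / sqrt(sum |F_a|^2 * sum |F_b|^2),

read against the half-bit information threshold
``T(n) = (0.2071 + 1.9102/sqrt(n)) / (1.2071 + 0.9102/sqrt(n))`` with n the
number of independent Fourier samples per shell; the first crossing below
the threshold is quoted as the resolution.  ``split_scan_fsc`` builds the
two half-datasets by interleaving (even/odd) tomographic angles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft
from scipy.interpolate import interp1d
from scipy.optimize import curve_fit

from zoomtomo.tomo import reconstruct_volume

__all__ = [
    "DoseReport",
    "FSCCurve",
    "FitError",
    "dose_from_fluence",
    "half_bit_threshold",
    "fsc",
    "split_scan_fsc",
    "fwhm_gaussian_fit",
]

KEV_TO_J = 1.602176634e-16

# Mass attenuation (total) and mass energy-absorption coefficients of
# water, cm^2/g, at 10, 15, 20, 30 keV (standard compilation values);
# interpolated log-log in energy.
_DOSE_ENERGIES = np.array([10.0, 15.0, 20.0, 30.0])
_WATER_MU = {
    "total_attenuation": np.array([5.329, 1.673, 0.8096, 0.3756]),
    "energy_absorption": np.array([4.944, 1.374, 0.5503, 0.1557]),
}


@dataclass
class DoseReport:
    """Fluence -> dose accounting of one tomographic scan."""

    fluence: float  # photons / um^2, scan total
    energy_kev: float
    material: str
    coefficient_source: str  # which mu/rho convention
    mu_over_rho: float  # m^2 / kg
    dose: float  # Gy
    n_projections: int | None = None
    dose_per_projection: float | None = None


def _mu_over_rho_water(energy_kev: float, source: str) -> float:
    if source not in _WATER_MU:
        raise ValueError(
            f"unknown coefficient source {source!r}; use one of {list(_WATER_MU)}"
        )
    if not 10.0 <= energy_kev <= 30.0:
        raise ValueError(
            f"energy {energy_kev} keV outside the packaged dose table (10-30 keV)"
        )
    f = interp1d(np.log(_DOSE_ENERGIES), np.log(_WATER_MU[source]))
    return math.exp(float(f(math.log(energy_kev)))) * 0.1  # cm^2/g -> m^2/kg


def dose_from_fluence(
    fluence: float,
    energy_kev: float,
    *,
    material: str = "water",
    coefficient_source: str = "total_attenuation",
    n_projections: int | None = None,
) -> DoseReport:
    """Surface dose in gray from a scan fluence in photons/um^2.

    D [Gy] = Phi * 1e12 [1/m^2] * E [J] * (mu/rho) [m^2/kg].  Only water
    is packaged as sample medium (hydrated tissue is water-equivalent at
    this accuracy).
    """
    if fluence < 0:
        raise ValueError("fluence must be nonnegative")
    if material != "water":
        raise ValueError(f"unsupported dose material {material!r} (packaged: water)")
    mu_rho = _mu_over_rho_water(energy_kev, coefficient_source)
    dose = fluence * 1e12 * energy_kev * KEV_TO_J * mu_rho
    return DoseReport(
        fluence=fluence,
        energy_kev=energy_kev,
        material=material,
        coefficient_source=coefficient_source,
        mu_over_rho=mu_rho,
        dose=dose,
        n_projections=n_projections,
        dose_per_projection=None if n_projections is None else dose / n_projections,
    )


def half_bit_threshold(n: np.ndarray | float) -> np.ndarray | float:
    """Half-bit information threshold for shells of n independent samples.

    Tends to (1/2)/(sqrt(2)+... ) = 0.2071/1.2071 ~ 0.1716 for large n.
    """
    rn = np.sqrt(np.asarray(n, dtype=np.float64))
    return (0.2071 + 1.9102 / rn) / (1.2071 + 0.9102 / rn)


@dataclass
class FSCCurve:
    """Shell-wise correlation of two volumes with half-bit threshold."""

    frequency: np.ndarray  # shell centers, 1/m (or 1/voxel if no voxel size)
    correlation: np.ndarray  # may contain NaN for zero-power shells
    n_voxels: np.ndarray  # Fourier samples per shell
    threshold: np.ndarray  # half-bit values
    resolution: float | None  # m (or voxels), None if no crossing
    voxel_size: float | None = None
    provenance: dict = field(default_factory=dict)


def fsc(
    volume_a: np.ndarray,
    volume_b: np.ndarray,
    *,
    shell_width: float = 1.0,
    voxel_size: float | None = None,
) -> FSCCurve:
    """Fourier shell correlation between two equally shaped volumes."""
    a = np.asarray(volume_a, dtype=np.float64)
    b = np.asarray(volume_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"volume shapes differ: {a.shape} vs {b.shape}")
    if shell_width < 1.0:
        raise ValueError("shell width must be >= 1 frequency bin")
    fa = sp_fft.fftn(a)
    fb = sp_fft.fftn(b)
    freqs = [sp_fft.fftfreq(s) for s in a.shape]  # cycles/voxel
    r = np.sqrt(
        sum(
            (f.reshape([-1 if i == j else 1 for i in range(a.ndim)])) ** 2
            for j, f in enumerate(freqs)
        )
    )
    # shell index in bins of the smallest axis resolution
    bin_width = shell_width / min(a.shape)
    shell = np.floor(r / bin_width).astype(np.int64)
    n_shells = int(shell.max()) + 1

    cross = np.bincount(shell.ravel(), weights=(fa * np.conj(fb)).real.ravel(), minlength=n_shells)
    cross_im = np.bincount(shell.ravel(), weights=(fa * np.conj(fb)).imag.ravel(), minlength=n_shells)
    pa = np.bincount(shell.ravel(), weights=np.abs(fa.ravel()) ** 2, minlength=n_shells)
    pb = np.bincount(shell.ravel(), weights=np.abs(fb.ravel()) ** 2, minlength=n_shells)
    counts = np.bincount(shell.ravel(), minlength=n_shells)

    # keep shells up to Nyquist of the smallest axis
    keep = np.arange(n_shells) * bin_width <= 0.5 + bin_width
    cross = np.hypot(cross, cross_im)[keep]
    pa, pb, counts = pa[keep], pb[keep], counts[keep]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where((pa > 0) & (pb > 0), cross / np.sqrt(pa * pb), np.nan)
    centers = (np.arange(len(corr)) + 0.5) * bin_width  # cycles/voxel
    thr = half_bit_threshold(np.maximum(counts, 1))

    # first crossing below the threshold (ignore the DC shell)
    resolution = None
    valid = ~np.isnan(corr)
    for i in range(1, len(corr)):
        if not valid[i]:
            continue
        if corr[i] < thr[i]:
            # linear interpolation between shells i-1 and i
            c0, c1 = corr[i - 1], corr[i]
            t0, t1 = thr[i - 1], thr[i]
            d0, d1 = c0 - t0, c1 - t1
            frac = d0 / (d0 - d1) if d0 != d1 else 0.0
            f_cross = centers[i - 1] + frac * (centers[i] - centers[i - 1])
            resolution = 1.0 / f_cross  # voxels
            if voxel_size is not None:
                resolution *= voxel_size
            break

    if voxel_size is not None:
        centers = centers / voxel_size
    return FSCCurve(
        frequency=centers,
        correlation=corr,
        n_voxels=counts,
        threshold=np.asarray(thr),
        resolution=resolution,
        voxel_size=voxel_size,
    )


def split_scan_fsc(
    phase_stack: np.ndarray,
    angles: np.ndarray,
    *,
    wavelength: float,
    voxel_size: float,
    filter_name: str = "ram-lak",
    split: str = "interleaved",
    shell_width: float = 1.0,
) -> FSCCurve:
    """FSC between reconstructions from two angle subsets of one scan.

    ``interleaved`` (default) assigns even/odd angles to the halves;
    ``halves`` uses the first and second half of the scan.
    """
    angles = np.asarray(angles)
    if len(angles) < 2:
        raise ValueError("need at least two projections to split")
    if split == "interleaved":
        ia, ib = np.arange(0, len(angles), 2), np.arange(1, len(angles), 2)
    elif split == "halves":
        half = len(angles) // 2
        ia, ib = np.arange(half), np.arange(half, len(angles))
    else:
        raise ValueError(f"unknown split {split!r}")
    va = reconstruct_volume(
        phase_stack[ia], angles[ia], wavelength=wavelength,
        voxel_size=voxel_size, filter_name=filter_name,
    )
    vb = reconstruct_volume(
        phase_stack[ib], angles[ib], wavelength=wavelength,
        voxel_size=voxel_size, filter_name=filter_name,
    )
    curve = fsc(va.delta, vb.delta, shell_width=shell_width, voxel_size=voxel_size)
    curve.provenance = {"split": split, "n_angles": len(angles)}
    return curve


class FitError(RuntimeError):
    """Gaussian fit did not converge or the profile has no peak."""


def fwhm_gaussian_fit(profile: np.ndarray, spacing: float = 1.0) -> float:
    """FWHM (in units of ``spacing``) of a single-peak profile.

    Least-squares fit of ``offset + amplitude * exp(-(x-mu)^2/(2 sigma^2))``;
    FWHM = 2*sqrt(2 ln 2) * sigma.  Works on dips as well (negative
    amplitude).  Raises :class:`FitError` for flat or non-peaked input.
    """
    y = np.asarray(profile, dtype=np.float64)
    if y.ndim != 1 or len(y) < 5:
        raise ValueError("profile must be 1D with at least 5 samples")
    x = np.arange(len(y), dtype=np.float64)
    span = np.ptp(y)
    if span <= 0 or span < 1e-12 * max(1.0, np.abs(y).max()):
        raise FitError("flat profile: no peak to fit")

    med = np.median(y)
    peak_up = y.max() - med >= med - y.min()
    amp0 = (y.max() - med) if peak_up else (y.min() - med)
    mu0 = float(np.argmax(y) if peak_up else np.argmin(y))
    sigma0 = max(1.0, len(y) / 10.0)

    def model(x, off, amp, mu, sigma):
        return off + amp * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))

    try:
        popt, _ = curve_fit(
            model, x, y, p0=[med, amp0, mu0, sigma0],
            maxfev=10_000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"Gaussian fit failed: {exc}") from exc
    off, amp, mu, sigma = popt
    sigma = abs(sigma)
    if abs(amp) < 1e-3 * span or sigma > 5 * len(y):
        raise FitError(
            f"degenerate fit (amplitude {amp:.3g}, sigma {sigma:.3g} px): "
            "profile has no dominant peak"
        )
    return 2.0 * math.sqrt(2.0 * math.log(2.0)) * sigma * spacing
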
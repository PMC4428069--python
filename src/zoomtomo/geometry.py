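"""Cone-beam imaging geometry and regime diagnostics.

A point source at distance ``z1`` upstream of the sample and a detector at
``z2`` downstream define a geometric magnification ``M = (z1 + z2)/z1``.
By the Fresnel scaling theorem the cone-beam hologram equals a plane-wave
hologram recorded at the *effective propagation distance*
``z_eff = z1*z2/(z1 + z2)`` on a grid with the *effective pixel* ``p/M``.
Moving the sample towards the source (smaller ``z1``) therefore zooms into
the object: magnification grows and the effective pixel shrinks.

The character of the contrast is set by a single dimensionless number, the
Fresnel number ``F = a**2 / (lambda * z_eff)`` of a typical feature size
``a`` (here, by convention, ten effective pixels).  ``F`` of order one gives
edge-enhanced *direct* contrast; ``F << 1`` gives the strongly oscillatory
*holographic* regime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "HC_KEV_M",
    "BeamGeometry",
    "RegimeDescriptor",
    "wavelength_from_energy",
    "magnification",
    "effective_distance",
    "fresnel_number",
    "classify_regime",
    "describe_regime",
]

#: Photon energy-wavelength conversion constant h*c, in keV * m
#: (1.239842 keV nm).
HC_KEV_M = 1.239842e-9

#: Fresnel-number cut separating the direct-contrast from the holographic
#: regime.  The physical transition is gradual (F ~ 1 vs F << 1); 0.5 is the
#: package's documented convention.
REGIME_THRESHOLD = 0.5


def wavelength_from_energy(energy_kev: float) -> float:
    """X-ray wavelength in metres for a photon energy in keV.

    Uses lambda = h*c / E with h*c = 1.239842 keV nm.

    >>> round(wavelength_from_energy(13.8) * 1e12, 3)
    89.843
    """
    if not energy_kev > 0:
        raise ValueError(f"photon energy must be positive, got {energy_kev}")
    return HC_KEV_M / energy_kev


@dataclass(frozen=True)
class BeamGeometry:
    """Cone-beam geometry of one hologram.

    Parameters
    ----------
    z1 : float
        Focus (source) to sample distance in metres.  ``math.inf`` is
        accepted and denotes plane-wave illumination.
    z2 : float
        Sample to detector distance in metres.
    energy_kev : float
        Photon energy in keV.
    detector_pixel : float
        Physical detector pixel size in metres.
    """

    z1: float
    z2: float
    energy_kev: float
    detector_pixel: float

    def __post_init__(self) -> None:
        if not self.z1 > 0:
            raise ValueError(f"z1 must be positive (or inf), got {self.z1}")
        if self.z2 < 0:
            raise ValueError(f"z2 must be nonnegative, got {self.z2}")
        if not self.energy_kev > 0:
            raise ValueError(f"energy must be positive, got {self.energy_kev}")
        if not self.detector_pixel > 0:
            raise ValueError(
                f"detector pixel must be positive, got {self.detector_pixel}"
            )

    @property
    def wavelength(self) -> float:
        """Photon wavelength in metres."""
        return wavelength_from_energy(self.energy_kev)

    @property
    def magnification(self) -> float:
        """Geometric magnification M = (z1 + z2)/z1 >= 1."""
        if math.isinf(self.z1):
            return 1.0
        return (self.z1 + self.z2) / self.z1

    @property
    def effective_distance(self) -> float:
        """Parallel-beam equivalent propagation distance z1*z2/(z1 + z2)."""
        if math.isinf(self.z1):
            return self.z2
        if self.z2 == 0.0:
            return 0.0
        return self.z1 * self.z2 / (self.z1 + self.z2)

    @property
    def effective_pixel(self) -> float:
        """Object-plane (demagnified) pixel size p/M in metres."""
        return self.detector_pixel / self.magnification

    def fresnel_number(self, feature_size: float | None = None) -> float:
        """Fresnel number of ``feature_size`` (default: 10 effective pixels)."""
        if feature_size is None:
            feature_size = 10.0 * self.effective_pixel
        return fresnel_number(feature_size, self.wavelength, self.effective_distance)


def magnification(geom: BeamGeometry) -> float:
    """Geometric magnification of a cone-beam geometry."""
    return geom.magnification


def effective_distance(geom: BeamGeometry) -> float:
    """Effective (parallel-equivalent) propagation distance in metres."""
    return geom.effective_distance


def fresnel_number(feature_size: float, wavelength: float, z_eff: float) -> float:
    """Fresnel number F = a^2 / (lambda * z_eff) of a feature of size ``a``.

    All arguments in metres; ``z_eff`` is the effective propagation
    distance.  F quantifies how far into the near field the feature is
    imaged: F >~ 1 means direct (edge) contrast, F << 1 holographic fringes.
    """
    if not (feature_size > 0 and wavelength > 0 and z_eff > 0):
        raise ValueError(
            "feature_size, wavelength and z_eff must all be positive, got "
            f"{feature_size}, {wavelength}, {z_eff}"
        )
    return feature_size**2 / (wavelength * z_eff)


def classify_regime(fresnel: float, threshold: float = REGIME_THRESHOLD) -> str:
    """Label a Fresnel number: ``direct_contrast`` if F >= threshold else
    ``holographic``."""
    if not fresnel > 0:
        raise ValueError(f"Fresnel number must be positive, got {fresnel}")
    return "direct_contrast" if fresnel >= threshold else "holographic"


@dataclass(frozen=True)
class RegimeDescriptor:
    """Dimensionless description of the imaging regime of one geometry."""

    fresnel_number: float
    feature_size: float
    wavelength: float
    wavenumber: float
    regime_label: str


def describe_regime(
    geom: BeamGeometry, feature_size: float | None = None
) -> RegimeDescriptor:
    """Regime diagnostics for a geometry at a given feature size.

    ``feature_size`` defaults to ten effective pixels, the package's
    convention for a "typical" feature.
    """
    if feature_size is None:
        feature_size = 10.0 * geom.effective_pixel
    lam = geom.wavelength
    f = fresnel_number(feature_size, lam, geom.effective_distance)
    return RegimeDescriptor(
        fresnel_number=f,
        feature_size=feature_size,
        wavelength=lam,
        wavenumber=2.0 * math.pi / lam,
        regime_label=classify_regime(f),
    )
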
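"""Optical constants of the phantom materials.

The complex x-ray refractive index is written n = 1 - delta + i*beta.  For
soft matter at 10-20 keV the refractive decrement delta exceeds the
absorption index beta by two to three orders of magnitude, which is the
whole point of phase-contrast imaging.

delta is computed from the electron density via

    delta = r_e * lambda**2 * rho_e / (2*pi),

with r_e the classical electron radius; beta from compiled mass-attenuation
coefficients via beta = mu * lambda / (4*pi), mu = (mu/rho) * rho.  The
packaged (mu/rho) support points are standard compilation values at 10, 15,
20 and 30 keV, interpolated log-log in energy; different compilations differ
at the few-percent level, which is the accuracy claimed here.  The barium
sulphate and lipid entries are element-weighted estimates of similar
accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "R_E",
    "Material",
    "OpticalConstants",
    "MaterialTable",
    "MATERIALS",
    "make_material_table",
]

#: Classical electron radius in metres.
R_E = 2.8179403e-15

#: Energies (keV) of the packaged mass-attenuation support points.
_MU_ENERGIES_KEV = np.array([10.0, 15.0, 20.0, 30.0])


@dataclass(frozen=True)
class Material:
    """Bulk properties from which optical constants are derived."""

    name: str
    density: float  # kg/m^3
    electron_density: float  # electrons / m^3
    mu_over_rho: tuple[float, float, float, float]  # cm^2/g at 10/15/20/30 keV


# Compiled constants.  Electron densities: rho * N_A * (Z/A).  mu/rho for
# water from the standard photon-attenuation compilation; tissue ~ water;
# adipose and BaSO4 are element-weighted estimates (BaSO4: mass fractions
# Ba 0.588, S 0.137, O 0.274; Ba dominates below its K edge at 37.4 keV).
MATERIALS: dict[str, Material] = {
    "water": Material("water", 1000.0, 3.340e29, (5.329, 1.673, 0.8096, 0.3756)),
    "tissue": Material("tissue", 1060.0, 3.520e29, (5.372, 1.693, 0.8205, 0.3783)),
    "lipid": Material("lipid", 920.0, 3.100e29, (3.268, 1.065, 0.5437, 0.2878)),
    "barium_sulfate": Material(
        "barium_sulfate", 4500.0, 1.208e30, (81.1, 27.0, 12.4, 4.15)
    ),
}

# Buffer (PBS) is optically water at this accuracy.
MATERIALS["buffer"] = Material(
    "buffer",
    MATERIALS["water"].density,
    MATERIALS["water"].electron_density,
    MATERIALS["water"].mu_over_rho,
)


@dataclass(frozen=True)
class OpticalConstants:
    """(delta, beta) of one material at one photon energy."""

    delta: float
    beta: float


class MaterialTable(dict):
    """Mapping material name -> :class:`OpticalConstants` at a fixed energy."""

    def __init__(self, energy_kev: float, entries: dict[str, OpticalConstants]):
        super().__init__(entries)
        self.energy_kev = energy_kev


def _interp_mu_over_rho(material: Material, energy_kev: float) -> float:
    """Mass attenuation coefficient in m^2/kg, log-log interpolated
    (linearly extrapolated in log-log space below the 10 keV support)."""
    from scipy.interpolate import interp1d

    f = interp1d(
        np.log(_MU_ENERGIES_KEV),
        np.log(np.asarray(material.mu_over_rho)),
        kind="linear",
        fill_value="extrapolate",
    )
    return math.exp(float(f(math.log(energy_kev)))) * 0.1  # cm^2/g -> m^2/kg


def delta_of(material: Material, energy_kev: float) -> float:
    """Refractive decrement from the electron-density formula."""
    from zoomtomo.geometry import wavelength_from_energy

    lam = wavelength_from_energy(energy_kev)
    return R_E * lam**2 * material.electron_density / (2.0 * math.pi)


def beta_of(material: Material, energy_kev: float) -> float:
    """Absorption index from the packaged mass-attenuation table."""
    from zoomtomo.geometry import wavelength_from_energy

    lam = wavelength_from_energy(energy_kev)
    mu = _interp_mu_over_rho(material, energy_kev) * material.density  # 1/m
    return mu * lam / (4.0 * math.pi)


def make_material_table(energy_kev: float) -> MaterialTable:
    """Optical constants (delta, beta) of all packaged materials.

    Parameters
    ----------
    energy_kev : float
        Photon energy; supported band 5-30 keV (the mass-attenuation table
        is extrapolated log-log below its 10 keV support point).

    Raises
    ------
    ValueError
        If the energy lies outside the supported 5-30 keV band.
    """
    if not 5.0 <= energy_kev <= 30.0:
        raise ValueError(
            f"unsupported energy {energy_kev} keV (supported band: 5-30 keV)"
        )
    return MaterialTable(
        energy_kev,
        {
            name: OpticalConstants(delta_of(m, energy_kev), beta_of(m, energy_kev))
            for name, m in MATERIALS.items()
        },
    )
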
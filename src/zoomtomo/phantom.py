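"""Seeded 3D lung-slice phantom and parallel-ray projection.

The phantom is a stylized, miniaturized hydrated lung-tissue slice: a block
of soft-tissue parenchyma immersed in buffer, perforated by buffer-filled
alveoli, traversed by one bronchial tube and one blood vessel (both hollow
cylinders with walls of distinct thickness), sprinkled with a few lipid
droplets, and carrying micron-scale barium-sulphate clusters grouped into
macrophage-like "cells".  Cluster centroids, radii and the anatomical
compartment they were seeded into (alveolar lumen or bronchial wall) are
recorded as ground truth so that downstream imaging, reconstruction and
segmentation can be scored against the phantom.

Structure radii are specified in voxels (fractions of the grid), so the
phantom is a topologically faithful miniature at any grid size; physical
dimensions follow from the voxel size.

Projections use parallel rays: the object is thin compared with the
focus-to-sample distance, so the cone angle across the object is negligible
and the cone beam enters only through the Fresnel scaling theorem
downstream (see :mod:`zoomtomo.propagation`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from zoomtomo.geometry import wavelength_from_energy
from zoomtomo.materials import make_material_table

__all__ = [
    "PhantomSpec",
    "PhantomVolume",
    "ClusterTruth",
    "PlacementError",
    "generate_lung_phantom",
    "project_volume",
]

# Material label codes of the label grid.
LABEL_EXTERIOR = 255  # outside the sample plug: vacuum/air, delta = beta = 0
LABEL_BUFFER = 0
LABEL_TISSUE = 1
LABEL_BRONCHIAL_WALL = 2
LABEL_VESSEL_WALL = 3
LABEL_LIPID = 4
LABEL_BARIUM = 5

LABEL_MATERIALS = {
    LABEL_BUFFER: "buffer",
    LABEL_TISSUE: "tissue",
    LABEL_BRONCHIAL_WALL: "tissue",
    LABEL_VESSEL_WALL: "tissue",
    LABEL_LIPID: "lipid",
    LABEL_BARIUM: "barium_sulfate",
}


class PlacementError(RuntimeError):
    """Raised when a structure cannot be placed by rejection sampling."""


@dataclass(frozen=True)
class ClusterTruth:
    """Ground truth of one seeded barium cluster."""

    centroid: tuple[float, float, float]  # voxel coordinates (z, y, x)
    radius: float  # voxels
    compartment: str  # "alveolar" or "bronchial_wall"
    cell_id: int


@dataclass
class PhantomSpec:
    """Parameters of the synthetic lung slice.

    All radii/thicknesses are in voxels.  Defaults give a 64^3 miniature
    with 20 alveolar and 5 bronchial-wall barium clusters, matching the
    conditions used throughout the test suite and demos.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: float = 245e-9  # m
    energy_kev: float = 13.8
    n_alveoli: int = 12
    alveolus_radius: tuple[float, float] = (6.0, 9.5)
    alveolus_wall: float = 1.5
    include_parenchyma: bool = True
    include_bronchus: bool = True
    bronchus_radius: float = 11.0
    bronchus_wall: float = 4.0
    include_vessel: bool = True
    vessel_radius: float = 7.0
    vessel_wall: float = 1.5
    n_lipid: int = 3
    lipid_radius: tuple[float, float] = (2.0, 3.5)
    n_clusters_alveolar: int = 20
    n_clusters_bronchial: int = 5
    cluster_radius: tuple[float, float] = (1.6, 2.4)
    clusters_per_cell: tuple[int, int] = (2, 4)
    cell_envelope_radius: float = 8.0
    # minimum surface-to-surface spacing between clusters, voxels; must
    # exceed the imaging point-spread so clusters stay resolvable
    cluster_min_gap: float = 4.0
    background: str = "buffer"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 8 for s in self.shape):
            raise ValueError(f"volume too small: {self.shape}")
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive")
        for name in ("alveolus_radius", "cluster_radius", "lipid_radius"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        if self.bronchus_radius >= min(self.shape) / 2:
            raise ValueError("bronchial tube does not fit inside the volume")


@dataclass
class PhantomVolume:
    """delta/beta voxel grids plus material labels and cluster ground truth.

    ``anatomy`` is the material-label grid *before* barium placement, i.e.
    the anatomical-compartment mask against which cluster locations are
    scored.
    """

    delta: np.ndarray  # 3D, refractive decrement
    beta: np.ndarray  # 3D, absorption index
    label: np.ndarray  # 3D, integer material codes
    voxel_size: float  # m
    energy_kev: float
    clusters: list[ClusterTruth] = field(default_factory=list)
    anatomy: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, ...]:
        return self.delta.shape


def _ball_mask(shape, center, radius):
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (
        xx - center[2]
    ) ** 2 <= radius**2


def _cylinder_mask(shape, axis, center2, radius):
    """Cylinder along ``axis`` with 2D center in the remaining axes."""
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    other = [i for i in range(3) if i != axis]
    mask = (grids[other[0]] - center2[0]) ** 2 + (
        grids[other[1]] - center2[1]
    ) ** 2 <= radius**2
    return np.broadcast_to(mask, shape)


def generate_lung_phantom(spec: PhantomSpec) -> PhantomVolume:
    """Build the phantom deterministically from ``spec`` (including seed).

    Raises :class:`PlacementError` if a structure cannot be placed without
    forbidden overlap within 10,000 rejection-sampling attempts.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    label = np.full(spec.shape, LABEL_EXTERIOR, dtype=np.uint8)

    # Sample plug: a buffer-filled cylinder along the rotation (z) axis,
    # compactly supported inside the grid (radially and axially) so that
    # rotated projections never clip the sample and hologram margins stay
    # object-free at every magnification.
    plug_radius = 0.42 * min(ny, nx)
    mz = max(3, int(round(0.08 * nz)))
    plug = _cylinder_mask(
        spec.shape, 0, ((ny - 1) / 2.0, (nx - 1) / 2.0), plug_radius
    ).copy()
    plug[:mz] = plug[nz - mz :] = False
    label[plug] = LABEL_BUFFER

    # Parenchyma block: tissue filling the central 85% of y/x over the
    # plug's axial extent (the slice is cut normal to z), clipped to the
    # plug.
    my, mx = int(round(0.075 * ny)), int(round(0.075 * nx))
    block = np.zeros(spec.shape, dtype=bool)
    block[:, my : ny - my, mx : nx - mx] = True
    if spec.include_parenchyma:
        label[block & plug] = LABEL_TISSUE
    parenchyma = label == LABEL_TISSUE

    # Bronchial tube along z, off-center; hollow with a thick wall.
    bron_outer = np.zeros(spec.shape, dtype=bool)
    if spec.include_bronchus:
        bc = (0.32 * ny, 0.60 * nx)
        bron_outer = _cylinder_mask(spec.shape, 0, bc, spec.bronchus_radius)
        bron_lumen = _cylinder_mask(
            spec.shape, 0, bc, spec.bronchus_radius - spec.bronchus_wall
        )
        label[bron_outer & parenchyma] = LABEL_BRONCHIAL_WALL
        label[bron_lumen & parenchyma] = LABEL_BUFFER

    # Blood vessel along y with a thin wall; must not intersect the bronchus.
    vessel_outer = np.zeros(spec.shape, dtype=bool)
    if spec.include_vessel:
        for attempt in range(10_000):
            vc = (
                rng.uniform(0.2, 0.8) * nz,
                rng.uniform(0.15, 0.85) * nx,
            )
            vessel_outer = _cylinder_mask(spec.shape, 1, vc, spec.vessel_radius)
            if not (vessel_outer & bron_outer).any():
                break
        else:
            raise PlacementError("blood vessel: no non-overlapping position found")
        vessel_lumen = _cylinder_mask(
            spec.shape, 1, vc, spec.vessel_radius - spec.vessel_wall
        )
        label[vessel_outer & parenchyma] = LABEL_VESSEL_WALL
        label[vessel_lumen & parenchyma] = LABEL_BUFFER

    # Alveoli: buffer-filled spheres carved into the parenchyma.  Overlap
    # among alveoli is allowed (walls merge); tubes are kept clear.
    forbidden = bron_outer | vessel_outer
    alveoli_mask = np.zeros(spec.shape, dtype=bool)
    alveoli_centers = []
    for i in range(spec.n_alveoli):
        for attempt in range(10_000):
            r = rng.uniform(*spec.alveolus_radius)
            c = (
                rng.uniform(r, nz - r),
                rng.uniform(my + r, ny - my - r),
                rng.uniform(mx + r, nx - mx - r),
            )
            ball = _ball_mask(spec.shape, c, r)
            if not (ball & forbidden).any():
                alveoli_mask |= ball
                alveoli_centers.append((c, r))
                break
        else:
            raise PlacementError(f"alveolus {i}: no position found")
    label[alveoli_mask & (label == LABEL_TISSUE)] = LABEL_BUFFER

    # Lipid droplets in the tissue walls.
    for i in range(spec.n_lipid):
        for attempt in range(10_000):
            r = rng.uniform(*spec.lipid_radius)
            c = tuple(rng.uniform(r, s - r) for s in spec.shape)
            ball = _ball_mask(spec.shape, c, r)
            if (label[ball] == LABEL_TISSUE).all():
                label[ball] = LABEL_LIPID
                break
        else:
            raise PlacementError(f"lipid droplet {i}: no position found")

    # Barium clusters grouped into macrophage-like cells.  Alveolar cells sit
    # in alveolar lumina; bronchial cells inside the bronchial wall.  Cluster
    # spheres within one cell stay inside its envelope; clusters of distinct
    # cells must not touch (ground-truth centroids must stay resolvable).
    clusters: list[ClusterTruth] = []
    # (center, radius) of all accepted clusters; spheres are kept >= 2 voxels
    # apart (surface to surface) so labelled components stay separable
    accepted: list[tuple[np.ndarray, float]] = []
    anatomy = label.copy()
    alveolar_lumen = alveoli_mask & (label == LABEL_BUFFER)
    bronchial_wall = label == LABEL_BRONCHIAL_WALL
    MIN_GAP = spec.cluster_min_gap

    def place_cell(cell_id, n_left, compartment, host_mask, inset=1):
        n_in_cell = min(int(rng.integers(*spec.clusters_per_cell)), n_left)
        env = spec.cell_envelope_radius
        # keep centres inside the compartment so the (rounded) centroid
        # voxel stays in it even after reconstruction errors
        host_mask = ndimage.binary_erosion(host_mask, iterations=inset)

        # candidate cell centers: host voxels with an envelope-wide margin
        margin = np.zeros(spec.shape, dtype=bool)
        e = int(math.ceil(env))
        margin[e:-e, e:-e, e:-e] = True
        candidates = np.argwhere(host_mask & margin)
        if len(candidates) == 0:
            raise PlacementError(
                f"barium cell {cell_id} ({compartment}): host compartment empty"
            )

        def in_host(c):
            v = tuple(
                min(max(int(round(c[k])), 0), spec.shape[k] - 1) for k in range(3)
            )
            return bool(host_mask[v])

        def separated(c, r):
            return all(
                np.linalg.norm(c - cj) > r + rj + MIN_GAP for cj, rj in accepted
            )

        for attempt in range(10_000):
            cc = candidates[rng.integers(len(candidates))].astype(float)
            cc += rng.uniform(-0.5, 0.5, size=3)
            placed: list[tuple[np.ndarray, float]] = []

            def sep_local(c, r):
                return separated(c, r) and all(
                    np.linalg.norm(c - cj) > r + rj + MIN_GAP for cj, rj in placed
                )

            for _ in range(n_in_cell):
                for _ in range(200):
                    r = rng.uniform(*spec.cluster_radius)
                    off = rng.normal(size=3)
                    off *= rng.uniform(0, env - r) / (np.linalg.norm(off) + 1e-12)
                    c = cc + off
                    if any(
                        c[k] < r + 1 or c[k] > spec.shape[k] - r - 1 for k in range(3)
                    ):
                        continue
                    if not in_host(c) or not sep_local(c, r):
                        continue
                    placed.append((c, r))
                    break
                else:
                    break
            if len(placed) == n_in_cell:
                for c, r in placed:
                    label[_ball_mask(spec.shape, c, r)] = LABEL_BARIUM
                    accepted.append((c, r))
                    clusters.append(ClusterTruth(tuple(c), r, compartment, cell_id))
                return n_in_cell
        raise PlacementError(f"barium cell {cell_id} ({compartment}): no position found")

    cell_id = 0
    remaining = spec.n_clusters_alveolar
    while remaining > 0:
        remaining -= place_cell(cell_id, remaining, "alveolar", alveolar_lumen,
                                inset=2)
        cell_id += 1
    remaining = spec.n_clusters_bronchial
    while remaining > 0:
        remaining -= place_cell(cell_id, remaining, "bronchial_wall", bronchial_wall)
        cell_id += 1

    table = make_material_table(spec.energy_kev)
    delta = np.zeros(spec.shape, dtype=np.float64)
    beta = np.zeros(spec.shape, dtype=np.float64)
    for code, mat in LABEL_MATERIALS.items():
        mask = label == code
        if code == LABEL_BUFFER:
            mat = spec.background
        if mat in ("vacuum", "none", "empty"):
            continue  # exterior optical constants: delta = beta = 0
        delta[mask] = table[mat].delta
        beta[mask] = table[mat].beta

    return PhantomVolume(
        delta, beta, label, spec.voxel_size, spec.energy_kev, clusters, anatomy
    )


def project_volume(
    vol: PhantomVolume | np.ndarray,
    angle: float,
    *,
    beta: np.ndarray | None = None,
    voxel_size: float | None = None,
    energy_kev: float | None = None,
    order: int = 1,
):
    """Parallel-ray phase and absorption projection at a tomographic angle.

    Rays run in the (y, x) plane; the volume is rotated by ``-angle`` about
    the z axis and summed along y, matching the projection convention of the
    tomography module.  Returns ``(phi, B)`` with

        phi(z, x) = -k * integral(delta ds),   B(z, x) = k * integral(beta ds)

    so that the exit wave is ``T = exp(-B + i*phi)``.  phi is negative for
    matter with delta > 0.

    Parameters
    ----------
    vol : PhantomVolume or ndarray
        Phantom, or a raw delta grid (then supply ``beta``, ``voxel_size``
        and ``energy_kev`` explicitly; ``beta`` defaults to zero).
    angle : float
        Tomographic angle in radians, in [0, pi) by convention.
    """
    if isinstance(vol, PhantomVolume):
        delta_grid = vol.delta
        beta_grid = vol.beta
        voxel_size = vol.voxel_size
        energy_kev = vol.energy_kev
    else:
        delta_grid = np.asarray(vol)
        beta_grid = beta if beta is not None else np.zeros_like(delta_grid)
        if voxel_size is None or energy_kev is None:
            raise ValueError("voxel_size and energy_kev required for raw grids")
    if not np.isfinite(angle):
        raise ValueError(f"angle must be finite, got {angle}")

    k = 2.0 * math.pi / wavelength_from_energy(energy_kev)
    deg = math.degrees(angle)
    if abs(deg) % 360.0 < 1e-12:
        d_rot, b_rot = delta_grid, beta_grid
    else:
        d_rot = ndimage.rotate(
            delta_grid, -deg, axes=(1, 2), reshape=False, order=order, mode="constant"
        )
        b_rot = ndimage.rotate(
            beta_grid, -deg, axes=(1, 2), reshape=False, order=order, mode="constant"
        )
    phi = -k * d_rot.sum(axis=1) * voxel_size
    absorb = k * b_rot.sum(axis=1) * voxel_size
    return phi, absorb
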
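"""Voxelized phantoms: the contrast-depth cylinder and a procedural mouse.

The contrast-depth phantom is a 32-mm soft-tissue cylinder (long axis = beam
axis) carrying 4-mm gold spheres at six weight fractions, repeated at four
beam depths.  The six spheres of each depth plane sit on two concentric rings
whose slots rotate from plane to plane, so all 24 transverse footprints are
pairwise disjoint: a pencil beam along the long axis crosses soft tissue only
before reaching any sphere.

The mouse phantom is a procedural stand-in for a licensed whole-body rodent
phantom: ellipsoidal organs in ICRP tissues with the study's gold loadings
(kidneys 4 wt%; spleen, lung, heart and a hind-leg tumor 0.75 wt%; liver
0.12 wt%).  It reproduces the organ-level imaging task, not rodent anatomy.

Axes: ``(x, y, z)`` with z the beam axis; the beam enters at z = 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .materials import MATERIALS, Material

GOLD_DENSITY = 19.32


class GeometryError(ValueError):
    """Raised when a requested layout cannot be voxelized."""


@dataclass(frozen=True)
class SphereInsert:
    """A spherical gold insert in the contrast-depth phantom."""

    center: tuple[float, float, float]  # mm
    diameter: float                     # mm
    gold_fraction: float                # mass fraction
    depth: float                        # beam depth to sphere center, mm


@dataclass(frozen=True)
class ROISpec:
    """A circular or square region of interest in the transverse plane."""

    shape: str                          # 'circle' | 'square'
    center: tuple[float, float]         # (x, y) mm
    size: float                         # diameter or side, mm
    role: str                           # 'gold' | 'background'
    label: str = ""
    axial_mm: float | None = None       # beam depth of the slice, if tied to one

    def mask(self, shape_xy: tuple[int, int], pitch: float,
             origin: tuple[float, float]) -> np.ndarray:
        """Boolean mask of voxel centers inside the ROI on an (nx, ny) grid."""
        nx, ny = shape_xy
        x = origin[0] + (np.arange(nx) + 0.5) * pitch
        y = origin[1] + (np.arange(ny) + 0.5) * pitch
        xx, yy = np.meshgrid(x, y, indexing="ij")
        dx, dy = xx - self.center[0], yy - self.center[1]
        if self.shape == "circle":
            m = dx ** 2 + dy ** 2 <= (self.size / 2) ** 2
        elif self.shape == "square":
            m = (np.abs(dx) <= self.size / 2) & (np.abs(dy) <= self.size / 2)
        else:
            raise ValueError(f"unknown ROI shape {self.shape!r}")
        if not m.any():
            raise GeometryError(f"ROI {self.label!r} covers no voxel centers")
        return m


@dataclass
class VoxelPhantom:
    """Material-ID grid plus a gold weight-fraction grid on a common lattice."""

    material_ids: np.ndarray            # (nx, ny, nz) small ints
    gold_fraction: np.ndarray           # (nx, ny, nz) mass fractions
    pitch: tuple[float, float, float]   # mm
    origin: tuple[float, float, float]  # mm, corner of voxel (0, 0, 0)
    material_names: list[str]           # index -> registry name

    def __post_init__(self):
        if self.material_ids.shape != self.gold_fraction.shape:
            raise ValueError("material and gold grids must be congruent")
        if any(p <= 0 for p in self.pitch):
            raise ValueError("voxel pitch must be positive")

    # -- coordinate helpers -------------------------------------------------
    @property
    def shape(self):
        return self.material_ids.shape

    def centers(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.pitch[axis]

    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.pitch)) / 1000.0

    @property
    def materials(self) -> list[Material]:
        return [MATERIALS[n] for n in self.material_names]

    # -- derived physical maps ---------------------------------------------
    def mixture_density(self) -> np.ndarray:
        """Per-voxel density of the gold-loaded mixture (g/cm^3)."""
        host_rho = np.array([m.density for m in self.materials])[self.material_ids]
        w = self.gold_fraction
        return 1.0 / ((1.0 - w) / host_rho + w / GOLD_DENSITY)

    def partial_densities(self) -> tuple[list[str], np.ndarray]:
        """Basis decomposition: per-material host partial density plus gold.

        Returns ``(names + ['gold'], dens)`` with ``dens`` of shape
        ``(n_basis, nx, ny, nz)`` in g/cm^3; attenuation at any energy is
        ``sum_b dens_b * (mu/rho)_b(E)``.
        """
        rho_mix = self.mixture_density()
        w = self.gold_fraction
        host_part = rho_mix * (1.0 - w)
        out = np.empty((len(self.material_names) + 1,) + self.shape,
                       dtype=np.float32)
        for i in range(len(self.material_names)):
            out[i] = np.where(self.material_ids == i, host_part, 0.0)
        out[-1] = rho_mix * w
        return self.material_names + ["gold"], out

    def mu_map(self, energy_keV: float) -> np.ndarray:
        """Per-voxel linear attenuation (1/mm) at one energy."""
        names, dens = self.partial_densities()
        out = np.zeros(self.shape, dtype=np.float64)
        for name, d in zip(names, dens):
            out += d.astype(np.float64) * MATERIALS[name].mu_over_rho(energy_keV)
        return out / 10.0

    def electron_density_map(self) -> np.ndarray:
        """Electrons per cm^3 per voxel."""
        names, dens = self.partial_densities()
        out = np.zeros(self.shape, dtype=np.float64)
        for name, d in zip(names, dens):
            out += d.astype(np.float64) * MATERIALS[name].electrons_per_gram()
        return out

    def gold_partial_density(self) -> np.ndarray:
        """Gold mass per unit volume (g/cm^3) per voxel."""
        return self.mixture_density() * self.gold_fraction

    def total_gold_mass_g(self) -> float:
        return float(self.gold_partial_density().sum() * self.voxel_volume_cm3())

    def mass_g(self) -> float:
        """Total phantom mass, excluding surrounding air."""
        air = self.material_names.index("air") if "air" in self.material_names else -1
        rho = self.mixture_density()
        body = self.material_ids != air
        return float(rho[body].sum() * self.voxel_volume_cm3())


# ---------------------------------------------------------------------------
# contrast-depth phantom
# ---------------------------------------------------------------------------

CONCENTRATIONS = (0.04, 0.02, 0.015, 0.01, 0.005, 0.0005)
DEPTHS_MM = (3.25, 28.75, 54.25, 79.75)
_OUTER_RING_MM = 13.0
_INNER_RING_MM = 8.5
_N_OUTER_SLOTS = 16
_N_INNER_SLOTS = 8


def _insert_layout(diameter_mm: float) -> list[SphereInsert]:
    inserts = []
    for d_idx, depth in enumerate(DEPTHS_MM):
        # four highest loadings on the outer ring, two lowest on the inner;
        # slots interleave across depth planes so footprints never overlap
        slots = [(d_idx + 4 * k) % _N_OUTER_SLOTS for k in range(4)]
        for conc, slot in zip(CONCENTRATIONS[:4], slots):
            ang = 2 * np.pi * slot / _N_OUTER_SLOTS
            inserts.append(SphereInsert(
                center=(_OUTER_RING_MM * np.cos(ang),
                        _OUTER_RING_MM * np.sin(ang), depth),
                diameter=diameter_mm, gold_fraction=conc, depth=depth))
        slots = [(d_idx + 4 * k) % _N_INNER_SLOTS for k in range(2)]
        for conc, slot in zip(CONCENTRATIONS[4:], slots):
            ang = 2 * np.pi * slot / _N_INNER_SLOTS + np.pi / _N_INNER_SLOTS
            inserts.append(SphereInsert(
                center=(_INNER_RING_MM * np.cos(ang),
                        _INNER_RING_MM * np.sin(ang), depth),
                diameter=diameter_mm, gold_fraction=conc, depth=depth))
    return inserts


def build_contrast_depth_phantom(
        pitch: float = 0.5, *, diameter: float = 32.0, length: float = 90.0,
        insert_diameter: float = 4.0, gold_roi_scale: float = 1.0,
        background_roi_scale: float = 3.0,
) -> tuple[VoxelPhantom, list[SphereInsert], list[ROISpec]]:
    """Build the contrast-depth cylinder, its inserts and its ROI protocol.

    Gold ROIs are circles matching each insert's transverse footprint; the
    background ROI is a larger circle at the gold-free center of the cylinder.
    """
    if pitch > 0.5 + 1e-12:
        raise GeometryError("pitch must be <= 0.5 mm to resolve 4-mm inserts")
    radius = diameter / 2.0
    nxy = int(round(diameter / pitch))
    nz = int(round(length / pitch))
    origin = (-radius, -radius, 0.0)

    x = origin[0] + (np.arange(nxy) + 0.5) * pitch
    z = origin[2] + (np.arange(nz) + 0.5) * pitch
    xx, yy = np.meshgrid(x, x, indexing="ij")
    inside = xx ** 2 + yy ** 2 <= radius ** 2

    material_names = ["air", "soft_tissue"]
    ids = np.zeros((nxy, nxy, nz), dtype=np.int8)
    ids[inside, :] = 1
    gold = np.zeros((nxy, nxy, nz), dtype=np.float32)

    inserts = _insert_layout(insert_diameter)
    r_ins = insert_diameter / 2.0
    for ins in inserts:
        cx, cy, cz = ins.center
        if np.hypot(cx, cy) + r_ins > radius or not r_ins <= cz <= length - r_ins:
            raise GeometryError("insert extends outside the cylinder")
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        near = d2 <= r_ins ** 2
        dz2 = (z - cz) ** 2
        zmask = dz2 <= r_ins ** 2
        sphere = near[:, :, None] & (d2[:, :, None] + dz2[None, None, :] <= r_ins ** 2)
        sphere &= zmask[None, None, :]
        gold[sphere] = ins.gold_fraction

    rois = [ROISpec("circle", (ins.center[0], ins.center[1]),
                    insert_diameter * gold_roi_scale, "gold",
                    label=f"Au{ins.gold_fraction * 100:g}pct@{ins.depth:g}mm",
                    axial_mm=ins.depth)
            for ins in inserts]
    rois.append(ROISpec("circle", (0.0, 0.0),
                        insert_diameter * background_roi_scale, "background",
                        label="background"))

    phantom = VoxelPhantom(ids, gold, (pitch, pitch, pitch), origin,
                           material_names)
    return phantom, inserts, rois


# ---------------------------------------------------------------------------
# procedural mouse phantom
# ---------------------------------------------------------------------------

def _ellipsoid(xx, yy, zz, center, radii):
    return ((xx - center[0]) / radii[0]) ** 2 + \
           ((yy - center[1]) / radii[1]) ** 2 + \
           ((zz - center[2]) / radii[2]) ** 2 <= 1.0


# organ -> (center, radii, tissue, gold fraction)
_MOUSE_ORGANS = {
    "brain":        ((0.0, 0.0, 7.0), (5.5, 5.5, 7.0), "brain", 0.0),
    "lung_left":    ((-6.0, -1.0, 30.0), (3.0, 4.0, 8.0), "lung", 0.0075),
    "lung_right":   ((6.0, -1.0, 30.0), (3.0, 4.0, 8.0), "lung", 0.0075),
    "heart":        ((0.0, 2.0, 28.0), (2.8, 3.0, 4.0), "muscle", 0.0075),
    "liver":        ((0.0, -3.0, 44.0), (7.0, 4.5, 5.0), "soft_tissue", 0.0012),
    "spleen":       ((-7.0, -4.0, 54.0), (2.5, 2.5, 4.5), "soft_tissue", 0.0075),
    "kidney_left":  ((-5.5, 2.0, 56.0), (2.5, 2.2, 4.0), "soft_tissue", 0.04),
    "kidney_right": ((5.5, 2.0, 56.0), (2.5, 2.2, 4.0), "soft_tissue", 0.04),
    "tumor":        ((8.0, 4.0, 72.0), (2.0, 2.0, 2.0), "soft_tissue", 0.0075),
}

_TORSO = dict(ax=13.0, ay=11.0, z0=12.0, z1=72.0, fat_shell_mm=1.5)
_LEG = dict(center=(8.0, 4.0, 72.0), radii=(5.0, 5.0, 7.0))
_SPINE = dict(center_xy=(0.0, 7.0), radius=1.2, z0=16.0, z1=70.0)


def build_mouse_phantom(pitch: float = 0.5) -> tuple[VoxelPhantom, list[ROISpec]]:
    """Build the mouse-like phantom and its square-ROI protocol.

    ROIs sit over each kidney and the hind-leg tumor, with a background ROI
    in gold-free abdominal tissue on the kidney slice.
    """
    if pitch > 1.0 + 1e-12:
        raise GeometryError("pitch must be <= 1 mm")
    extent_xy, length = 32.0, 80.0
    nxy, nz = int(round(extent_xy / pitch)), int(round(length / pitch))
    origin = (-extent_xy / 2, -extent_xy / 2, 0.0)
    x = origin[0] + (np.arange(nxy) + 0.5) * pitch
    z = origin[2] + (np.arange(nz) + 0.5) * pitch
    xx, yy, zz = np.meshgrid(x, x, z, indexing="ij")

    material_names = ["air", "soft_tissue", "adipose", "muscle", "brain",
                      "lung", "cortical_bone"]
    mat_idx = {n: i for i, n in enumerate(material_names)}
    ids = np.zeros((nxy, nxy, nz), dtype=np.int8)
    gold = np.zeros((nxy, nxy, nz), dtype=np.float32)

    t = _TORSO
    ell = (xx / t["ax"]) ** 2 + (yy / t["ay"]) ** 2
    torso = (ell <= 1.0) & (zz >= t["z0"]) & (zz <= t["z1"])
    head = _ellipsoid(xx, yy, zz, (0.0, 0.0, 8.0), (8.0, 8.0, 10.0))
    leg = _ellipsoid(xx, yy, zz, _LEG["center"], _LEG["radii"])
    ids[torso | head] = mat_idx["soft_tissue"]
    ids[leg] = mat_idx["muscle"]
    shell = torso & (ell > (1.0 - t["fat_shell_mm"] / min(t["ax"], t["ay"])) ** 2)
    ids[shell] = mat_idx["adipose"]

    s = _SPINE
    spine = ((xx - s["center_xy"][0]) ** 2 + (yy - s["center_xy"][1]) ** 2
             <= s["radius"] ** 2) & (zz >= s["z0"]) & (zz <= s["z1"])
    ids[spine] = mat_idx["cortical_bone"]

    for organ, (center, radii, tissue, frac) in _MOUSE_ORGANS.items():
        mask = _ellipsoid(xx, yy, zz, center, radii)
        ids[mask] = mat_idx[tissue]
        if frac > 0:
            gold[mask] = frac

    rois = [
        ROISpec("square", (-5.5, 2.0), 5.0, "gold", "kidney_left", 56.0),
        ROISpec("square", (5.5, 2.0), 5.0, "gold", "kidney_right", 56.0),
        ROISpec("square", (8.0, 4.0), 4.0, "gold", "tumor", 72.0),
        ROISpec("square", (0.0, -5.0), 8.0, "background", "background", 56.0),
    ]
    phantom = VoxelPhantom(ids, gold, (pitch, pitch, pitch), origin,
                           material_names)
    return phantom, rois


def mouse_organ_masks(phantom: VoxelPhantom) -> dict[str, np.ndarray]:
    """Re-derive the analytic organ masks on the phantom's grid (for QA)."""
    x = phantom.centers(0)
    z = phantom.centers(2)
    xx, yy, zz = np.meshgrid(x, x, z, indexing="ij")
    return {name: _ellipsoid(xx, yy, zz, c, r)
            for name, (c, r, _, _) in _MOUSE_ORGANS.items()}


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_phantom(path, phantom: VoxelPhantom,
                 inserts: list[SphereInsert] | None = None,
                 rois: list[ROISpec] | None = None) -> None:
    """Write grids to ``<path>.npz`` and metadata to ``<path>.json``."""
    path = str(path)
    np.savez_compressed(path + ".npz", material_ids=phantom.material_ids,
                        gold_fraction=phantom.gold_fraction)
    meta = {
        "pitch": list(phantom.pitch), "origin": list(phantom.origin),
        "material_names": phantom.material_names,
        "attenuation_tables": "packaged NIST-grid elemental mu/rho tables",
        "inserts": [vars(i) | {"center": list(i.center)} for i in inserts or []],
        "rois": [vars(r) | {"center": list(r.center)} for r in rois or []],
    }
    with open(path + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)


def load_phantom(path) -> VoxelPhantom:
    path = str(path)
    arrays = np.load(path + ".npz")
    with open(path + ".json") as fh:
        meta = json.load(fh)
    return VoxelPhantom(arrays["material_ids"], arrays["gold_fraction"],
                        tuple(meta["pitch"]), tuple(meta["origin"]),
                        list(meta["material_names"]))


def rois_to_csv(path, rois: list[ROISpec]) -> None:
    pd.DataFrame([vars(r) | {"x_mm": r.center[0], "y_mm": r.center[1]}
                  for r in rois]).drop(columns=["center"]).to_csv(path, index=False)
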
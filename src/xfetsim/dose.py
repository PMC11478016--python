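"""Dose matching between XFET raster scans and fan-beam CT.

A raster scan delivers ``Ib`` photons to each beam position of cross-section
``A0``, i.e. an areal fluence N = Ib / A0.  CT is approximately dose-matched
by delivering, summed over all projection views, the same areal fluence to a
detector-channel footprint at the isocenter:

    N     = Ib / A0
    w_iso = gamma_fan * SID / N_channels      (channel width at isocenter)
    Iproj = N * h * w_iso / N_proj            (photons per channel per view)

with ``h`` the channel height (= phantom slice width).  A simple
primary-beam collision-kerma tally estimates the mean phantom dose of the
raster scan; it omits scattered-photon redeposition and carries a stated
factor-of-two fidelity caveat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .materials import mu_en_water
from .phantoms import VoxelPhantom
from .spectrum import Spectrum
from .xfet import RasterPlan

KEV_TO_J = 1.602176634e-16


@dataclass(frozen=True)
class DoseMatchParams:
    """Inputs and derived quantities of the dose-matching chain."""

    ib: float                   # photons per beam position
    a0_mm2: float               # beam-position cross-section
    h_mm: float                 # channel height = phantom slice width
    fan_angle_deg: float
    sid_mm: float
    sdd_mm: float
    n_channels: int
    n_proj: int

    def __post_init__(self):
        for name in ("ib", "a0_mm2", "h_mm", "fan_angle_deg", "sid_mm",
                     "sdd_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_channels <= 0 or self.n_proj <= 0:
            raise ValueError("channel and view counts must be positive")

    @property
    def areal_fluence_per_mm2(self) -> float:
        return self.ib / self.a0_mm2

    @property
    def w_fan_mm(self) -> float:
        return np.deg2rad(self.fan_angle_deg) * self.sdd_mm

    @property
    def w_mm(self) -> float:
        return self.w_fan_mm / self.n_channels

    @property
    def w_iso_mm(self) -> float:
        return self.w_mm * self.sid_mm / self.sdd_mm

    @property
    def iproj(self) -> float:
        return self.areal_fluence_per_mm2 * self.h_mm * self.w_iso_mm / self.n_proj

    @property
    def iproj_nearest(self) -> int:
        return int(round(self.iproj))


def compute_iproj(ib: float, a0_mm2: float, h_mm: float,
                  fan_angle_deg: float = 19.37, sid_mm: float = 100.0,
                  n_channels: int = 1024, n_proj: int = 438,
                  sdd_mm: float = 200.0) -> DoseMatchParams:
    """Per-view per-channel photon count that dose-matches CT to a raster scan.

    Returns the full parameter chain; ``.iproj`` is the exact real value and
    ``.iproj_nearest`` a rounded convenience.
    """
    return DoseMatchParams(ib, a0_mm2, h_mm, fan_angle_deg, sid_mm, sdd_mm,
                           n_channels, n_proj)


def fold_increase(histories_partial: float, histories_full: float) -> int:
    """Local-dose fold factor of a partial-FOV scan, nearest integer."""
    if histories_full <= 0:
        raise ZeroDivisionError("full-scan histories must be positive")
    return int(round(histories_partial / histories_full))


def local_dose_cGy(full_fov_dose_mGy: float, fold: float) -> float:
    """Local dose of a partial-FOV scan in cGy (mGy * fold / 10)."""
    return full_fov_dose_mGy * fold / 10.0


def estimate_dose(phantom: VoxelPhantom, spectrum: Spectrum,
                  plan: RasterPlan, warn_truncated: bool = True) -> dict:
    """Mean phantom dose (mGy) of a raster scan, primary-beam kerma tally.

    Per beam position the deposited energy is
    ``sum_E sum_z Phi(E, z) * E * mu_en(E) * dz`` along the attenuated beam
    path, summed over positions and divided by the phantom mass.  Requires
    the complete (non-truncated) spectrum; fidelity is a factor of ~2
    (scattered-photon redeposition is not transported).
    """
    if spectrum.cutoff > 0 and warn_truncated:
        import warnings
        warnings.warn("dose tally called with a truncated spectrum; supply "
                      "the full spectrum for a meaningful dose")
    if plan.histories == 0:
        return {"mean_dose_mGy": 0.0, "deposited_J": 0.0,
                "mass_g": phantom.mass_g(), "n_positions": 0}
    from .materials import MATERIALS
    from .xfet import _active_mask

    spec = spectrum.scaled(plan.histories / spectrum.equivalent_histories)
    keep = spec.fluence > 0
    energies = spec.centers[keep]
    flu0 = spec.fluence[keep]
    names, dens = phantom.partial_densities()
    mu_rho = np.stack([MATERIALS[n].mu_over_rho(energies) for n in names])
    rho_mix = phantom.mixture_density()
    mu_en = mu_en_water(energies)
    dz = phantom.pitch[2]
    active, ix_all, iy_all = _active_mask(phantom, plan)
    act = np.argwhere(active)
    deposited = 0.0
    for s in range(0, len(act), 512):
        sel = act[s:s + 512]
        ix = ix_all[sel[:, 0]]
        iy = iy_all[sel[:, 1]]
        cols = dens[:, ix, iy, :].astype(np.float64)             # (b, p, z)
        mu = np.einsum("bpz,be->pze", cols, mu_rho / 10.0)
        optical = np.cumsum(mu * dz, axis=1) - 0.5 * mu * dz
        fluence = flu0 * np.exp(-optical)                        # (p, z, E)
        rho = rho_mix[ix, iy, :]                                 # (p, z)
        deposited += np.einsum("pze,e,pz->", fluence, energies * mu_en,
                               rho) * (dz / 10.0) * KEV_TO_J
    n_positions = len(act)
    mass_kg = phantom.mass_g() / 1000.0
    return {"mean_dose_mGy": 1000.0 * deposited / mass_kg,
            "deposited_J": deposited, "mass_g": phantom.mass_g() * 1.0,
            "n_positions": n_positions}
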
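"""Material compositions and photon attenuation data.

Elemental mass attenuation coefficients are packaged as a curated grid
(``data/mass_attenuation.csv``) and interpolated log-log, the standard
practice between absorption edges.  Materials are elemental mixtures with a
mass-fraction composition; mixture attenuation follows the mixture rule

    mu/rho (E) = sum_i w_i (mu/rho)_i (E)

and gold-loaded tissues are built with :func:`with_gold`, which perturbs both
the composition and the mass density of the host.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

# Avogadro constant (1/mol)
N_A = 6.02214076e23

#: Z and atomic mass (g/mol) for the elements covered by the packaged tables.
ELEMENTS: dict[str, tuple[int, float]] = {
    "H": (1, 1.008), "C": (6, 12.011), "N": (7, 14.007), "O": (8, 15.999),
    "Na": (11, 22.990), "Mg": (12, 24.305), "Al": (13, 26.982),
    "P": (15, 30.974), "S": (16, 32.06), "Cl": (17, 35.45),
    "K": (19, 39.098), "Ca": (20, 40.078), "Au": (79, 196.967),
    "Pb": (82, 207.2),
}

ENERGY_RANGE_KEV = (1.0, 150.0)


class UnknownElementError(KeyError):
    """Raised when a composition references an element without packaged data."""


def _load_element_tables() -> dict[str, tuple[np.ndarray, np.ndarray]]:
    tables: dict[str, list[tuple[float, float]]] = {}
    path = resources.files("xfetsim.data").joinpath("mass_attenuation.csv")
    with path.open() as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    for el, e, mu in rows[1:]:
        tables.setdefault(el, []).append((float(e), float(mu)))
    out = {}
    for el, pts in tables.items():
        pts.sort()
        e = np.array([p[0] for p in pts])
        mu = np.array([p[1] for p in pts])
        out[el] = (np.log(e), np.log(mu))
    return out


_ELEMENT_TABLES = _load_element_tables()


def _loglog_interp(energy_keV, log_e: np.ndarray, log_y: np.ndarray):
    e = np.asarray(energy_keV, dtype=float)
    if np.any(e < ENERGY_RANGE_KEV[0]) or np.any(e > ENERGY_RANGE_KEV[1]):
        raise ValueError(f"energy outside supported range {ENERGY_RANGE_KEV} keV")
    x = np.log(e)
    # linear extrapolation in log-log space below the lowest tabulated point
    slope_lo = (log_y[1] - log_y[0]) / (log_e[1] - log_e[0])
    slope_hi = (log_y[-1] - log_y[-2]) / (log_e[-1] - log_e[-2])
    y = np.interp(x, log_e, log_y)
    y = np.where(x < log_e[0], log_y[0] + slope_lo * (x - log_e[0]), y)
    y = np.where(x > log_e[-1], log_y[-1] + slope_hi * (x - log_e[-1]), y)
    return np.exp(y) if np.ndim(energy_keV) else float(np.exp(y))


def mass_attenuation(element: str, energy_keV):
    """Elemental mu/rho in cm^2/g at the given energies (1-150 keV)."""
    try:
        log_e, log_mu = _ELEMENT_TABLES[element]
    except KeyError:
        raise UnknownElementError(element) from None
    return _loglog_interp(energy_keV, log_e, log_mu)


@dataclass(frozen=True)
class Material:
    """An elemental mixture with a mass density.

    ``composition`` maps element symbols to mass fractions; fractions must sum
    to 1 within 1e-9 and the density must be positive.
    """

    name: str
    composition: dict[str, float] = field(default_factory=dict)
    density: float = 1.0  # g/cm^3

    def __post_init__(self):
        if self.density <= 0:
            raise ValueError(f"{self.name}: density must be positive")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: mass fractions sum to {total}, not 1")
        for el in self.composition:
            if el not in ELEMENTS:
                raise UnknownElementError(el)

    def mu_over_rho(self, energy_keV):
        """Mixture mu/rho (cm^2/g) via the mass-weighted mixture rule."""
        out = 0.0
        for el, w in self.composition.items():
            out = out + w * mass_attenuation(el, energy_keV)
        return out

    def electrons_per_gram(self) -> float:
        return sum(w * N_A * ELEMENTS[el][0] / ELEMENTS[el][1]
                   for el, w in self.composition.items())


def linear_attenuation(material: Material, energy_keV):
    """Linear attenuation coefficient in 1/mm (density * mu/rho / 10)."""
    return material.density * material.mu_over_rho(energy_keV) / 10.0


def electron_density(material: Material) -> float:
    """Electrons per cm^3."""
    return material.density * material.electrons_per_gram()


def with_gold(host: Material, gold_fraction: float) -> Material:
    """Host material loaded with gold at the given mass fraction.

    The mixture density follows the inverse-mass-fraction rule
    1/rho = (1-w)/rho_host + w/rho_Au, and the elemental composition is the
    mass-weighted blend, so both production and attenuation see the admixture.
    """
    if not 0.0 <= gold_fraction < 1.0:
        raise ValueError("gold mass fraction must be in [0, 1)")
    if gold_fraction == 0.0:
        return host
    rho_au = 19.32
    comp = {el: w * (1.0 - gold_fraction) for el, w in host.composition.items()}
    comp["Au"] = comp.get("Au", 0.0) + gold_fraction
    density = 1.0 / ((1.0 - gold_fraction) / host.density + gold_fraction / rho_au)
    name = f"{host.name}+Au{gold_fraction:g}"
    return Material(name, comp, density)


def _load_registry() -> dict[str, Material]:
    path = resources.files("xfetsim.data").joinpath("materials.yaml")
    with path.open() as fh:
        raw = yaml.safe_load(fh)
    out = {}
    for name, spec in raw.items():
        comp = {el: float(w) for el, w in spec["composition"].items()}
        total = sum(comp.values())
        comp = {el: w / total for el, w in comp.items()}
        out[name] = Material(name, comp, float(spec["density"]))
    return out


MATERIALS: dict[str, Material] = _load_registry()


def _load_mu_en() -> tuple[np.ndarray, np.ndarray]:
    path = resources.files("xfetsim.data").joinpath("mu_en_water.csv")
    with path.open() as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    pts = sorted((float(e), float(m)) for e, m in rows[1:])
    return (np.log(np.array([p[0] for p in pts])),
            np.log(np.array([p[1] for p in pts])))


_MU_EN_TABLE = _load_mu_en()


def mu_en_water(energy_keV):
    """Mass energy-absorption coefficient of water (cm^2/g), for dose tallies."""
    return _loglog_interp(energy_keV, *_MU_EN_TABLE)
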
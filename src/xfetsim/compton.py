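"""Compton scatter kinematics and the Klein-Nishina cross section.

The single-scatter background in the fluorescence energy window is built from
the Klein-Nishina differential cross section per electron times the material
electron density, with the scattered photon energy fixed by Compton
kinematics.  Electrons are treated as free and at rest (no Doppler
broadening, no binding corrections), matching the idealized detector model.
"""

from __future__ import annotations

import numpy as np

from .materials import Material, electron_density

ELECTRON_REST_KEV = 510.99895
R_E_CM = 2.8179403262e-13  # classical electron radius


def scattered_energy(energy_keV, theta_rad):
    """Compton-scattered photon energy (keV) at scattering angle theta."""
    e = np.asarray(energy_keV, dtype=float)
    return e / (1.0 + (e / ELECTRON_REST_KEV) * (1.0 - np.cos(theta_rad)))


def klein_nishina(energy_keV, theta_rad):
    """Klein-Nishina d(sigma)/d(Omega) per electron (cm^2/sr)."""
    e = np.asarray(energy_keV, dtype=float)
    if np.any(e <= 0):
        raise ValueError("energy must be positive")
    ratio = scattered_energy(e, theta_rad) / e
    sin2 = np.sin(theta_rad) ** 2
    return 0.5 * R_E_CM ** 2 * ratio ** 2 * (ratio + 1.0 / ratio - sin2)


def klein_nishina_total(energy_keV):
    """Total Klein-Nishina cross section per electron (cm^2), closed form."""
    k = np.asarray(energy_keV, dtype=float) / ELECTRON_REST_KEV
    t1 = (1 + k) / k ** 2 * (2 * (1 + k) / (1 + 2 * k) - np.log(1 + 2 * k) / k)
    t2 = np.log(1 + 2 * k) / (2 * k)
    t3 = -(1 + 3 * k) / (1 + 2 * k) ** 2
    return 2 * np.pi * R_E_CM ** 2 * (t1 + t2 + t3)


def compton_scatter_rate(material: Material, energy_keV, theta_rad):
    """Differential scatter probability per unit solid angle per mm.

    Returns ``(rate_per_sr_per_mm, scattered_energy_keV)``; the rate is the
    Klein-Nishina cross section times the material electron density.
    """
    theta = np.asarray(theta_rad, dtype=float)
    if np.any(theta < 0) or np.any(theta > np.pi):
        raise ValueError("scatter angle must be in [0, pi]")
    n_e = electron_density(material)  # electrons / cm^3
    rate_per_cm = n_e * klein_nishina(energy_keV, theta)
    return rate_per_cm / 10.0, scattered_energy(energy_keV, theta)
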
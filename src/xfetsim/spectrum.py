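"""Tungsten-anode tube spectrum model.

The beam is a 120-kVp polychromatic pencil beam.  Bremsstrahlung follows the
Kramers law (number fluence per unit energy proportional to (kVp - E)/E),
hardened by a configurable aluminium filtration; tungsten K characteristic
lines are added for tube potentials above the W K edge.  The absolute scale is
set by a requested photon-history count.  A low-energy cutoff (the fraction of
the spectrum that can contribute to gold fluorescence and its scatter
neighborhood) zeroes all fluence below the cutoff, scaling the partially
covered bin by its covered fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .materials import Material, linear_attenuation

# Tungsten K lines (keV) and relative intensities.
_W_LINES = ((59.32, 1.00), (57.98, 0.57), (67.24, 0.23), (69.10, 0.08))
_W_K_EDGE = 69.525
# Characteristic share of total filtered fluence at 120 kVp (model choice).
_W_LINE_FRACTION = 0.06

_AL = Material("Al_filter", {"Al": 1.0}, 2.699)


class EmptySpectrumError(ValueError):
    """Raised when the cutoff removes the entire spectrum."""


@dataclass(frozen=True)
class Spectrum:
    """Photon fluence tabulated in uniform 1-keV bins.

    ``fluence[i]`` is the photon count (per beam position) in
    ``[edges[i], edges[i+1])``.
    """

    edges: np.ndarray          # keV, uniform 1-keV bins
    fluence: np.ndarray        # photons per bin
    kvp: float                 # keV
    cutoff: float = 0.0        # keV
    #: full-spectrum history count this (possibly truncated) fluence stands
    #: for; a cutoff spectrum of N histories carries only the above-cutoff
    #: share of N as actual fluence
    histories_equivalent: float | None = None

    def __post_init__(self):
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.fluence < 0):
            raise ValueError("fluence must be non-negative")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def total(self) -> float:
        return float(self.fluence.sum())

    @property
    def equivalent_histories(self) -> float:
        return self.histories_equivalent \
            if self.histories_equivalent is not None else self.total

    def scaled(self, factor: float) -> "Spectrum":
        return replace(self, fluence=self.fluence * factor,
                       histories_equivalent=self.equivalent_histories * factor)

    def mean_energy(self) -> float:
        if self.total == 0:
            raise EmptySpectrumError("spectrum has zero fluence")
        return float(np.sum(self.centers * self.fluence) / self.total)


def generate_spectrum(kvp: float = 120.0, histories: float = 1.0,
                      cutoff: float = 0.0,
                      filtration_mm_al: float = 2.5) -> Spectrum:
    """Model tube spectrum in 1-keV bins, normalized to ``histories`` photons.

    Parameters
    ----------
    kvp:
        Tube potential (keV); fluence is zero at and above ``kvp``.
    histories:
        Total photon count after filtration and cutoff truncation.
    cutoff:
        Low-energy cutoff (keV); bins fully below it are zeroed, the bin
        containing it is scaled by its covered fraction.
    filtration_mm_al:
        Aluminium filtration thickness (mm).
    """
    if cutoff >= kvp:
        raise EmptySpectrumError(f"cutoff {cutoff} >= kVp {kvp}")
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    n_bins = int(np.ceil(kvp))
    edges = np.arange(n_bins + 1, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])

    with np.errstate(divide="ignore"):
        brems = np.clip(kvp - centers, 0.0, None) / centers
    # energies below 1 keV never survive filtration; avoid the 1/E pole
    brems[centers < 1.0] = 0.0
    transmission = np.exp(-linear_attenuation(_AL, np.clip(centers, 1.0, 150.0))
                          * filtration_mm_al)
    transmission[centers < 1.0] = 0.0
    fluence = brems * transmission

    if kvp > _W_K_EDGE and fluence.sum() > 0:
        lines = np.zeros_like(fluence)
        for e_line, rel in _W_LINES:
            if e_line < kvp:
                i = int(e_line)
                lines[i] += rel * np.exp(
                    -linear_attenuation(_AL, e_line) * filtration_mm_al)
        if lines.sum() > 0:
            lines *= _W_LINE_FRACTION / (1 - _W_LINE_FRACTION) \
                * fluence.sum() / lines.sum()
            fluence = fluence + lines

    # apply the low-energy cutoff with partial-bin coverage
    full_below = edges[1:] <= cutoff
    fluence[full_below] = 0.0
    i_cut = np.searchsorted(edges, cutoff, side="right") - 1
    if 0 <= i_cut < n_bins and edges[i_cut] < cutoff:
        fluence[i_cut] *= (edges[i_cut + 1] - cutoff) / (edges[i_cut + 1] - edges[i_cut])

    total = fluence.sum()
    if total == 0 and histories > 0:
        raise EmptySpectrumError("no fluence survives filtration and cutoff")
    if histories == 0:
        fluence = np.zeros_like(fluence)
    else:
        fluence = fluence * (histories / total)
    return Spectrum(edges=edges, fluence=fluence, kvp=float(kvp),
                    cutoff=float(cutoff))


def fraction_above(kvp: float, cutoff: float,
                   filtration_mm_al: float = 2.5) -> float:
    """Fraction of the full model spectrum's fluence above ``cutoff``.

    Spectrum-model dependent; reported descriptively alongside results.
    """
    full = generate_spectrum(kvp, 1.0, 0.0, filtration_mm_al)
    widths = np.diff(full.edges)
    covered = np.clip((full.edges[1:] - cutoff) / widths, 0.0, 1.0)
    return float((full.fluence * covered).sum() / full.fluence.sum())


def truncated_beam(kvp: float, full_histories: float, cutoff: float,
                   filtration_mm_al: float = 2.5) -> Spectrum:
    """Low-energy-truncated beam representing a full-spectrum history count.

    Only the portion above ``cutoff`` is carried as fluence (the part that
    can produce metal fluorescence and its scatter neighborhood), but the
    spectrum remembers that it stands for ``full_histories`` photons of the
    complete tube output - the count that enters dose bookkeeping.
    """
    frac = fraction_above(kvp, cutoff, filtration_mm_al)
    spec = generate_spectrum(kvp, full_histories * frac, cutoff,
                             filtration_mm_al)
    return replace(spec, histories_equivalent=full_histories)
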
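"""Direct XFET image formation.

XFET needs no tomographic reconstruction: the raw image for an energy bin is
simply the detected counts per (beam x, beam y, axial position).  The
fluorescence bin (68-69 keV) is contaminated by Compton scatter at the same
energy; the correction estimates the scatter field as the average of the two
neighboring 1-keV bins, smooths it across the object plane with a Gaussian
kernel (sigma = 1 pixel, reflective boundaries so constants are preserved)
and subtracts it.  Axial rebinning trades axial resolution for contrast by
summing adjacent slices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .xfet import CountVolume

FLUOR_BIN = (68.0, 69.0)
LOWER_BIN = (67.0, 68.0)
UPPER_BIN = (69.0, 70.0)


@dataclass
class XFETImage:
    """A directly formed 3D metal image (beam x, beam y, axial)."""

    values: np.ndarray
    axial_pitch_mm: float
    x_mm: np.ndarray = field(default_factory=lambda: np.array([]))
    y_mm: np.ndarray = field(default_factory=lambda: np.array([]))
    energy_window: tuple[float, float] = FLUOR_BIN
    background_subtracted: bool = False

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image values must be finite")
        if not self.background_subtracted and np.any(self.values < 0):
            raise ValueError("raw images cannot be negative")

    def axial_slice(self, z_mm: float, axial_origin_mm: float = 0.0) -> np.ndarray:
        """The (x, y) slice whose axial bin contains ``z_mm``."""
        i = int((z_mm - axial_origin_mm) / self.axial_pitch_mm)
        if not 0 <= i < self.values.shape[2]:
            raise IndexError(f"axial position {z_mm} mm outside the image")
        return self.values[:, :, i]


def form_raw_images(counts: CountVolume) -> dict[tuple[float, float], XFETImage]:
    """One image per 1-keV bin in the 67-70 keV fluorescence neighborhood.

    Counts are already summed over detector rows and planes per object voxel;
    this selects the three named energy bins.
    """
    out = {}
    for window in (LOWER_BIN, FLUOR_BIN, UPPER_BIN):
        try:
            i = counts.energy_bin_index(window[0])
        except KeyError:
            raise ValueError(f"count volume does not cover {window} keV") from None
        out[window] = XFETImage(counts.counts[:, :, :, i].astype(np.float64),
                                counts.axial_pitch_mm, counts.x_mm,
                                counts.y_mm, window)
    return out


def subtract_background(fluor: XFETImage, lower: XFETImage, upper: XFETImage,
                        sigma_pixels: float = 1.0) -> XFETImage:
    """Compton-corrected image: fluor - smooth((lower + upper)/2).

    Smoothing acts on each object plane (x, y) independently with reflective
    padding, so a spatially constant scatter field cancels exactly.  Negative
    output values are kept for unbiased ROI statistics.
    """
    if fluor.values.shape != lower.values.shape or \
            fluor.values.shape != upper.values.shape:
        raise ValueError("images must be congruent")
    scatter = 0.5 * (lower.values + upper.values)
    smoothed = gaussian_filter(scatter, sigma=(sigma_pixels, sigma_pixels, 0),
                               mode="reflect")
    return XFETImage(fluor.values - smoothed, fluor.axial_pitch_mm,
                     fluor.x_mm, fluor.y_mm, fluor.energy_window,
                     background_subtracted=True)


def rebin_axial(image: XFETImage, factor: int) -> XFETImage:
    """Sum adjacent axial bins; total counts are conserved."""
    if factor < 1 or int(factor) != factor:
        raise ValueError("rebin factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return image
    vals = image.values
    n = vals.shape[2]
    if n % factor:
        pad = factor - n % factor
        warnings.warn(f"axial length {n} not divisible by {factor}; "
                      f"padding {pad} empty slices")
        vals = np.concatenate([vals, np.zeros(vals.shape[:2] + (pad,))], axis=2)
    vals = vals.reshape(vals.shape[0], vals.shape[1], -1, factor).sum(axis=3)
    return XFETImage(vals, image.axial_pitch_mm * factor, image.x_mm,
                     image.y_mm, image.energy_window,
                     image.background_subtracted)


def save_tiff(path, image: XFETImage) -> None:
    """Write the axial stack as a multi-page 32-bit TIFF."""
    import tifffile
    tifffile.imwrite(str(path), np.moveaxis(image.values, 2, 0)
                     .astype(np.float32), photometric="minisblack")
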
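"""Emission spectra and intensiometric response arithmetic.

A near-infrared plate reader records one emission spectrum per well per
read.  The sensor response is intensiometric: the relative change
dF/F = (F - F0)/F0 of the integrated emission, where F0 is the baseline
read taken before analyte addition.  Responses can be computed either
from the full spectrum or restricted to a single chirality's emission
window (here the (9,4) species).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EmissionSpectrum",
    "integrate_spectrum",
    "subtract_blank",
    "compute_dff",
    "extract_peak_response",
]


@dataclass(frozen=True)
class EmissionSpectrum:
    """Wavelength/intensity pairs from one well read.

    Parameters
    ----------
    wavelength : array-like
        Emission wavelengths in nm, strictly increasing, >= 2 points.
    intensity : array-like
        Fluorescence intensity in arbitrary units, same length.
        Negative values are allowed (blank subtraction is not clipped).
    """

    wavelength: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength, dtype=float)
        it = np.asarray(self.intensity, dtype=float)
        if wl.ndim != 1 or it.ndim != 1:
            raise ValueError("wavelength and intensity must be 1-D")
        if wl.size < 2:
            raise ValueError("spectrum needs at least 2 points")
        if wl.size != it.size:
            raise ValueError(
                f"length mismatch: {wl.size} wavelengths vs {it.size} intensities"
            )
        if not (np.isfinite(wl).all() and np.isfinite(it).all()):
            raise ValueError("spectrum contains non-finite values")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelength", wl)
        object.__setattr__(self, "intensity", it)

    def __add__(self, other: "EmissionSpectrum") -> "EmissionSpectrum":
        _check_same_grid(self, other)
        return EmissionSpectrum(self.wavelength, self.intensity + other.intensity)

    def scaled(self, factor: float) -> "EmissionSpectrum":
        return EmissionSpectrum(self.wavelength, self.intensity * factor)


def _check_same_grid(a: EmissionSpectrum, b: EmissionSpectrum) -> None:
    if a.wavelength.size != b.wavelength.size or not np.array_equal(
        a.wavelength, b.wavelength
    ):
        n = min(a.wavelength.size, b.wavelength.size)
        diff = np.nonzero(a.wavelength[:n] != b.wavelength[:n])[0]
        if diff.size:
            where = f"first differing wavelength at index {diff[0]}: " \
                    f"{a.wavelength[diff[0]]} vs {b.wavelength[diff[0]]}"
        else:
            where = f"grids have different lengths ({a.wavelength.size} vs {b.wavelength.size})"
        raise ValueError(f"wavelength grid mismatch: {where}")


def integrate_spectrum(
    spectrum: EmissionSpectrum,
    window: tuple[float, float] | None = None,
) -> float:
    """Trapezoidal integral of intensity over wavelength.

    If ``window=(lo, hi)`` is given, the integral is restricted to grid
    points inside the closed interval; otherwise the full range is used.
    """
    wl, it = spectrum.wavelength, spectrum.intensity
    if window is not None:
        lo, hi = float(window[0]), float(window[1])
        if lo > hi:
            lo, hi = hi, lo
        mask = (wl >= lo) & (wl <= hi)
        if mask.sum() < 2:
            raise ValueError(
                f"window ({lo}, {hi}) nm overlaps fewer than 2 grid points "
                f"of [{wl[0]}, {wl[-1]}] nm"
            )
        wl, it = wl[mask], it[mask]
    return float(np.trapezoid(it, wl))


def subtract_blank(sample: EmissionSpectrum, blank: EmissionSpectrum) -> EmissionSpectrum:
    """Pointwise blank subtraction on an identical wavelength grid.

    Negative intensities are kept: clipping would bias integrals.
    """
    _check_same_grid(sample, blank)
    return EmissionSpectrum(sample.wavelength, sample.intensity - blank.intensity)


def compute_dff(F0: float, F: float) -> float:
    """Relative fluorescence change (F - F0)/F0."""
    if not np.isfinite(F0) or not np.isfinite(F):
        raise ValueError("F0 and F must be finite")
    if F0 <= 0:
        raise ValueError(f"degenerate baseline: F0 = {F0} must be > 0")
    return (F - F0) / F0


def extract_peak_response(
    F0_spec: EmissionSpectrum,
    F_spec: EmissionSpectrum,
    chirality_window: tuple[float, float],
) -> float:
    """dF/F restricted to a single chirality's emission window."""
    _check_same_grid(F0_spec, F_spec)
    F0 = integrate_spectrum(F0_spec, chirality_window)
    F = integrate_spectrum(F_spec, chirality_window)
    return compute_dff(F0, F)
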
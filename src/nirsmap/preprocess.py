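"""Calibration and conditioning of raw reflectance spectra.

Raw spectra are divided by the measurement of a 99% diffuse reflectance
standard (removing lamp shape and system response), scaled by a phantom-
derived factor, truncated to 600-1000 nm, resampled to a uniform 1 nm
grid, lowpass filtered (zero-phase, cutoff 0.05 pi rad/sample), and
renormalized to the value at 600 nm.  The result is the relative
reflectance Rrel on which all optical indices are defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .types import GRID, DerivativeSpectrum, RawSpectrum, RelativeSpectrum, ValidationError

#: Normalized lowpass cutoff along wavelength, rad/sample on the 1 nm grid.
CUTOFF = 0.05
FILTER_ORDER = 4

#: Largest wavelength step (nm) tolerated inside the 600-1000 nm band
#: before the input is considered to have a coverage gap.
MAX_GAP_NM = 5.0


class CalibrationError(ValueError):
    pass


@dataclass
class CalibrationPair:
    """Reflectance-standard spectrum plus phantom-derived scale factor."""

    standard: RawSpectrum
    phantom_factor: float

    def __post_init__(self) -> None:
        if self.phantom_factor <= 0:
            raise ValidationError("phantom_factor must be > 0")
        wl, c = self.standard.wavelengths, self.standard.counts
        band = (wl >= 600) & (wl <= 1000)
        if band.any() and np.any(c[band] <= 0):
            raise ValidationError("standard counts must be > 0 over 600-1000 nm")


def calibrate(raw: RawSpectrum, cal: CalibrationPair) -> tuple[np.ndarray, np.ndarray]:
    """Divide by the reflectance standard and apply the phantom scale.

    Returns ``(wavelengths, relative_reflectance)`` on ``raw``'s grid.
    """
    if not np.array_equal(raw.wavelengths, cal.standard.wavelengths):
        raise CalibrationError(
            "raw and standard spectra are on different wavelength grids; "
            "resample to a common grid before calibrating"
        )
    wl = raw.wavelengths
    band = (wl >= 600) & (wl <= 1000)
    std = cal.standard.counts
    if np.any(std[band] <= 0):
        raise CalibrationError("standard reflectance <= 0 inside 600-1000 nm")
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = cal.phantom_factor * raw.counts / std
    return wl, rel


def _design_filter() -> tuple[np.ndarray, np.ndarray]:
    # butter() takes the cutoff as a fraction of Nyquist (= pi rad/sample)
    return butter(FILTER_ORDER, CUTOFF)


def condition_batch(wavelengths: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Condition many spectra at once; rows of ``values`` are spectra.

    Returns an (n, 401) array of conditioned Rrel rows.  See
    :func:`condition` for the per-spectrum contract.
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if wavelengths[0] > 600.0 or wavelengths[-1] < 1000.0:
        raise ValidationError(
            f"input covers {wavelengths[0]:g}-{wavelengths[-1]:g} nm; "
            "600-1000 nm required"
        )
    inside = (wavelengths >= 600.0 - MAX_GAP_NM) & (wavelengths <= 1000.0 + MAX_GAP_NM)
    if np.any(np.diff(wavelengths[inside]) > MAX_GAP_NM):
        raise ValidationError("coverage gap inside 600-1000 nm")
    if not np.all(np.isfinite(values)):
        raise ValidationError("non-finite reflectance values")

    # linear resample onto the uniform 1 nm grid
    j = np.searchsorted(wavelengths, GRID, side="right") - 1
    j = np.clip(j, 0, len(wavelengths) - 2)
    w1 = (GRID - wavelengths[j]) / (wavelengths[j + 1] - wavelengths[j])
    resampled = values[:, j] * (1 - w1) + values[:, j + 1] * w1

    b, a = _design_filter()
    filtered = filtfilt(b, a, resampled, axis=1)
    ref = filtered[:, 0]
    if np.any(ref <= 0):
        raise ValidationError("post-filter value at 600 nm <= 0; cannot normalize")
    out = filtered / ref[:, None]
    # lowpass ringing can graze zero on pathological inputs; Rrel must stay > 0
    if np.any(out <= 0):
        raise ValidationError("conditioned spectrum not strictly positive")
    return out


def condition(wavelengths: np.ndarray, values: np.ndarray) -> RelativeSpectrum:
    """Truncate, resample, zero-phase lowpass, and normalize at 600 nm."""
    return RelativeSpectrum(condition_batch(wavelengths, values)[0])


def differentiate(s: RelativeSpectrum) -> DerivativeSpectrum:
    """Per-nm first derivative: central differences, one-sided at ends."""
    return DerivativeSpectrum(np.gradient(s.rrel, 1.0))


def differentiate_batch(rrel: np.ndarray) -> np.ndarray:
    return np.gradient(np.atleast_2d(rrel), 1.0, axis=1)


def preprocess_raw(
    raw: RawSpectrum, cal: CalibrationPair
) -> tuple[RelativeSpectrum, DerivativeSpectrum]:
    """calibrate -> condition -> differentiate, in one call."""
    wl, rel = calibrate(raw, cal)
    s = condition(wl, rel)
    return s, differentiate(s)
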
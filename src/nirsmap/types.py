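"""Shared domain types for the NIRS lesion-mapping pipeline.

The pipeline operates on near-infrared reflectance spectra acquired by a
tracked ablation catheter.  Each acquisition couples a spectrum with a
six-degree-of-freedom tracker pose and (after registration) a pixel
location on a reference photograph of the tissue.  Spectra move through
three representations: raw detector counts (:class:`RawSpectrum`),
calibrated and conditioned relative reflectance on a fixed 600-1000 nm
grid (:class:`RelativeSpectrum`), and its first derivative
(:class:`DerivativeSpectrum`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

#: Uniform 1 nm wavelength grid, 600-1000 nm inclusive (401 samples).
#: All optical-index lookups address exact points of this grid.
GRID = np.arange(600.0, 1001.0, 1.0)
N_GRID = 401

MEDIA = ("PBS", "blood")
LABELS = ("lesion", "nonlesion", "unknown")


class ValidationError(ValueError):
    """An object violates one of its declared invariants."""


@dataclass
class RawSpectrum:
    """Uncalibrated detector intensities on the spectrometer's native grid."""

    wavelengths: np.ndarray  # nm, strictly increasing
    counts: np.ndarray  # nonnegative, arbitrary units
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.wavelengths.ndim != 1 or self.counts.ndim != 1:
            raise ValidationError("wavelengths and counts must be 1-D")
        if len(self.wavelengths) != len(self.counts) or len(self.counts) < 2:
            raise ValidationError(
                "wavelengths and counts must have equal length >= 2"
            )
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValidationError("wavelengths must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be nonnegative")


@dataclass
class RelativeSpectrum:
    """Calibrated, conditioned relative reflectance Rrel on the standard grid.

    Conditioning normalizes at 600 nm, so for conditioned spectra
    ``rrel[0] == 1`` exactly; the type itself only requires positivity.
    """

    rrel: np.ndarray

    def __post_init__(self) -> None:
        self.rrel = np.asarray(self.rrel, dtype=float)
        if self.rrel.shape != (N_GRID,):
            raise ValidationError(
                f"rrel must have exactly {N_GRID} samples on the 600-1000 nm grid"
            )
        if not np.all(np.isfinite(self.rrel)) or np.any(self.rrel <= 0):
            raise ValidationError("rrel values must be finite and > 0")

    @property
    def grid(self) -> np.ndarray:
        return GRID

    def at(self, nm: float) -> float:
        """Value at an exact grid wavelength (no interpolation)."""
        return float(self.rrel[_grid_index(nm)])


@dataclass
class DerivativeSpectrum:
    """First derivative Rrel'(lambda), per nm, on the standard grid."""

    drrel: np.ndarray

    def __post_init__(self) -> None:
        self.drrel = np.asarray(self.drrel, dtype=float)
        if self.drrel.shape != (N_GRID,):
            raise ValidationError(f"drrel must have exactly {N_GRID} samples")
        if not np.all(np.isfinite(self.drrel)):
            raise ValidationError("drrel values must be finite")

    @property
    def grid(self) -> np.ndarray:
        return GRID

    def at(self, nm: float) -> float:
        return float(self.drrel[_grid_index(nm)])


def _grid_index(nm: float) -> int:
    idx = nm - 600.0
    if idx != int(idx) or not (0 <= idx <= 400):
        raise ValidationError(
            f"{nm} nm is not a point of the 600-1000 nm 1 nm grid"
        )
    return int(idx)


@dataclass
class TrackerPose:
    """Six-degree-of-freedom electromagnetic tracker reading."""

    x: float  # mm
    y: float  # mm
    z: float  # mm
    pitch: float  # deg
    yaw: float  # deg
    roll: float  # deg
    time: float = 0.0  # s

    def __post_init__(self) -> None:
        vals = (self.x, self.y, self.z, self.pitch, self.yaw, self.roll, self.time)
        if not all(np.isfinite(v) for v in vals):
            raise ValidationError("pose fields must be finite")
        for name in ("pitch", "yaw", "roll"):
            a = getattr(self, name)
            if not -180.0 <= a <= 180.0:
                raise ValidationError(f"{name} = {a} deg outside [-180, 180]")


@dataclass
class MappedSample:
    """One acquisition: spectrum + pose + registration + study metadata."""

    sample_id: str
    heart_id: str
    medium: str  # "PBS" | "blood"
    pose: TrackerPose
    spectrum: RawSpectrum | RelativeSpectrum
    label: str = "unknown"  # "lesion" | "nonlesion" | "unknown"
    pixel: tuple[float, float] | None = None  # (u=column, v=row), 0-based
    contact: bool | None = None  # None = undetermined

    def __post_init__(self) -> None:
        if self.medium not in MEDIA:
            raise ValidationError(f"medium must be one of {MEDIA}")
        if self.label not in LABELS:
            raise ValidationError(f"label must be one of {LABELS}")


@dataclass
class OpticalIndexVector:
    """The six named optical indices plus optional extra ratio indices.

    coi: contact optical index Rrel(764)/Rrel(730) -- low values flag
    poor catheter-tissue contact.  loi* (lesion optical indices) and
    soi* (substrate optical indices) separate ablated from untreated
    tissue.
    """

    coi: float
    loi0: float
    loi8: float
    soi1: float
    soi3: float
    soi4: float
    extras: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = (self.coi, self.loi0, self.loi8, self.soi1, self.soi3, self.soi4)
        if not all(np.isfinite(v) for v in vals):
            raise ValidationError("optical indices must be finite")

    def as_dict(self) -> dict[str, float]:
        d = {
            "coi": self.coi,
            "loi0": self.loi0,
            "loi8": self.loi8,
            "soi1": self.soi1,
            "soi3": self.soi3,
            "soi4": self.soi4,
        }
        d.update(self.extras)
        return d


@dataclass
class Homography:
    """3x3 projective transform, normalized so H[2, 2] == 1."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3):
            raise ValidationError("homography must be 3x3")
        if not np.all(np.isfinite(self.matrix)):
            raise ValidationError("homography entries must be finite")
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValidationError("homography must be invertible")
        if self.matrix[2, 2] == 0:
            raise ValidationError("bottom-right entry must be nonzero")
        self.matrix = self.matrix / self.matrix[2, 2]

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (n, 2) points through the projective transform."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        h = np.column_stack([pts, np.ones(len(pts))]) @ self.matrix.T
        return h[:, :2] / h[:, 2:3]

    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.matrix))


@dataclass
class ProbabilityMap:
    """Masked uniform 2-D grid of lesion probabilities.

    ``values[i, j]`` corresponds to physical location
    ``(x0 + j * spacing, y0 + i * spacing)``; undefined cells hold NaN
    and are False in ``mask``.
    """

    origin: tuple[float, float]  # (x0, y0) mm
    spacing: float  # mm per cell
    values: np.ndarray  # 2-D, NaN where undefined
    mask: np.ndarray  # 2-D bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2 or self.values.shape != self.mask.shape:
            raise ValidationError("values and mask must be equal-shape 2-D grids")
        if self.spacing <= 0:
            raise ValidationError("spacing must be positive")
        defined = self.values[self.mask]
        if not np.all(np.isfinite(defined)):
            raise ValidationError("masked-in cells must be finite")
        if np.any((defined < 0) | (defined > 1)):
            raise ValidationError("probabilities must lie in [0, 1]")
        if np.any(np.isfinite(self.values[~self.mask])):
            raise ValidationError("masked-out cells must be NaN")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (x, y) coordinate arrays of the grid columns/rows."""
        ny, nx = self.values.shape
        xs = self.origin[0] + self.spacing * np.arange(nx)
        ys = self.origin[1] + self.spacing * np.arange(ny)
        return xs, ys


@dataclass
class BinaryMap:
    """Thresholded lesion prediction on the same grid as its source map."""

    origin: tuple[float, float]
    spacing: float
    prediction: np.ndarray  # 2-D bool; True only where mask is True
    mask: np.ndarray  # 2-D bool

    def __post_init__(self) -> None:
        self.prediction = np.asarray(self.prediction, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.prediction.shape != self.mask.shape:
            raise ValidationError("prediction and mask shapes must match")
        if np.any(self.prediction & ~self.mask):
            raise ValidationError("prediction must be False outside the mask")


@dataclass
class ComparisonReport:
    """Similarity metrics between two probability maps on a shared mask."""

    ssim: float
    inner_product: float | None  # None when a map is identically zero
    rms_diff: float
    dice: dict[float, float | None]
    n_valid_cells: int

    def __post_init__(self) -> None:
        for name in ("ssim", "inner_product", "rms_diff"):
            v = getattr(self, name)
            if name == "inner_product" and v is None:
                continue
            if not np.isfinite(v):
                raise ValidationError(f"{name} must be finite")
        if self.ssim > 1 + 1e-12:
            raise ValidationError("ssim must be <= 1")
        if self.rms_diff < 0:
            raise ValidationError("rms_diff must be >= 0")
        for t, d in self.dice.items():
            if d is not None and not (0 - 1e-12 <= d <= 1 + 1e-12):
                raise ValidationError(f"dice at threshold {t} outside [0, 1]")

    def as_dict(self) -> dict[str, Any]:
        return {
            "ssim": self.ssim,
            "inner_product": self.inner_product,
            "rms_diff": self.rms_diff,
            "dice": {f"{t:g}": d for t, d in self.dice.items()},
            "n_valid_cells": self.n_valid_cells,
        }
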
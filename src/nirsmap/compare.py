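"""Masked comparison of probability maps (PBS vs. blood equivalence).

Four metrics quantify agreement between two maps on a shared mask:
windowed SSIM (Gaussian 11x11 window, sigma 1.5, K1 = 0.01, K2 = 0.03,
dynamic range 1.0, averaged over windows fully inside the mask), the
Frobenius normalized inner product sum(ab)/sqrt(sum(a^2) sum(b^2)), the
RMS difference, and the Dice coefficient between thresholded binary
predictions.  Cohort summaries average per-heart metrics; the Dice mean
divides the sum of *defined* per-heart values by the number of hearts,
so a heart where both maps predict no lesion at a threshold contributes
zero to the numerator but stays in the divisor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import correlate, minimum_filter

from .types import BinaryMap, ComparisonReport, ProbabilityMap, ValidationError

SSIM_WINDOW = 11
SSIM_SIGMA = 1.5
SSIM_K1 = 0.01
SSIM_K2 = 0.03
SSIM_DYNAMIC_RANGE = 1.0

DEFAULT_DICE_THRESHOLDS = (0.3, 0.5, 0.7)


def _check_aligned(a: ProbabilityMap | BinaryMap, b: ProbabilityMap | BinaryMap):
    if a.mask.shape != b.mask.shape or not np.array_equal(a.mask, b.mask):
        raise ValidationError("maps must share grid shape and mask")
    if a.origin != b.origin or a.spacing != b.spacing:
        raise ValidationError("maps must share origin and spacing")


def intersect_masks(a: ProbabilityMap, b: ProbabilityMap) -> tuple[ProbabilityMap, ProbabilityMap]:
    """Restrict two same-grid maps to their common defined region."""
    if a.values.shape != b.values.shape or a.origin != b.origin or a.spacing != b.spacing:
        raise ValidationError("maps are on different grids")
    m = a.mask & b.mask
    return (
        ProbabilityMap(a.origin, a.spacing, np.where(m, a.values, np.nan), m),
        ProbabilityMap(b.origin, b.spacing, np.where(m, b.values, np.nan), m),
    )


def _gaussian_kernel(size: int, sigma: float) -> np.ndarray:
    r = np.arange(size) - (size - 1) / 2
    k = np.exp(-0.5 * (r / sigma) ** 2)
    k2 = np.outer(k, k)
    return k2 / k2.sum()


def masked_ssim(a: ProbabilityMap, b: ProbabilityMap) -> float:
    """SSIM averaged over windows lying fully inside the mask."""
    _check_aligned(a, b)
    kernel = _gaussian_kernel(SSIM_WINDOW, SSIM_SIGMA)
    # valid window centers: every cell of the window is masked-in and
    # the window does not cross the array edge
    valid = minimum_filter(
        a.mask.astype(np.uint8), size=SSIM_WINDOW, mode="constant", cval=0
    ).astype(bool)
    if not valid.any():
        raise ValidationError("mask contains no full SSIM window")
    x = np.where(a.mask, a.values, 0.0)
    y = np.where(b.mask, b.values, 0.0)

    def smooth(z):
        return correlate(z, kernel, mode="constant", cval=0.0)

    mu_x, mu_y = smooth(x), smooth(y)
    sxx = smooth(x * x) - mu_x**2
    syy = smooth(y * y) - mu_y**2
    sxy = smooth(x * y) - mu_x * mu_y
    c1 = (SSIM_K1 * SSIM_DYNAMIC_RANGE) ** 2
    c2 = (SSIM_K2 * SSIM_DYNAMIC_RANGE) ** 2
    ssim_map = ((2 * mu_x * mu_y + c1) * (2 * sxy + c2)) / (
        (mu_x**2 + mu_y**2 + c1) * (sxx + syy + c2)
    )
    return float(ssim_map[valid].mean())


def masked_inner_product(a: ProbabilityMap, b: ProbabilityMap) -> float | None:
    """Frobenius normalized inner product over the mask; None if a map
    is identically zero there."""
    _check_aligned(a, b)
    av = a.values[a.mask]
    bv = b.values[b.mask]
    na, nb = np.sum(av**2), np.sum(bv**2)
    if na == 0 or nb == 0:
        return None
    return float(np.sum(av * bv) / np.sqrt(na * nb))


def masked_rms(a: ProbabilityMap, b: ProbabilityMap) -> float:
    """Root-mean-squared difference over the mask."""
    _check_aligned(a, b)
    if not a.mask.any():
        raise ValidationError("empty mask")
    d = a.values[a.mask] - b.values[b.mask]
    return float(np.sqrt(np.mean(d**2)))


def dice(a: BinaryMap, b: BinaryMap) -> float | None:
    """Dice coefficient 2|A∩B|/(|A|+|B|); None when both sets are empty."""
    _check_aligned(a, b)
    na = int(a.prediction.sum())
    nb = int(b.prediction.sum())
    if na + nb == 0:
        return None
    inter = int(np.sum(a.prediction & b.prediction))
    return 2.0 * inter / (na + nb)


def compare_maps(
    a: ProbabilityMap,
    b: ProbabilityMap,
    thresholds: tuple[float, ...] = DEFAULT_DICE_THRESHOLDS,
) -> ComparisonReport:
    """All four metrics between two maps on a shared mask."""
    from . import mapping

    ip = masked_inner_product(a, b)
    dices = {
        float(t): dice(mapping.threshold_map(a, t), mapping.threshold_map(b, t))
        for t in thresholds
    }
    return ComparisonReport(
        ssim=masked_ssim(a, b),
        inner_product=ip,
        rms_diff=masked_rms(a, b),
        dice=dices,
        n_valid_cells=int(a.mask.sum()),
    )


@dataclass
class CohortComparison:
    """Per-heart reports plus cohort means under both Dice conventions."""

    reports: dict[str, ComparisonReport]
    mean_ssim: float
    mean_inner_product: float
    mean_rms: float
    mean_dice: dict[float, float]  # sum of defined values / n_hearts
    mean_dice_defined_only: dict[float, float | None]
    n_hearts: int
    dice_convention: str = "sum_defined_over_n_hearts"

    def as_dict(self) -> dict:
        return {
            "mean_ssim": self.mean_ssim,
            "mean_inner_product": self.mean_inner_product,
            "mean_rms": self.mean_rms,
            "mean_dice": {f"{t:g}": v for t, v in self.mean_dice.items()},
            "mean_dice_defined_only": {
                f"{t:g}": v for t, v in self.mean_dice_defined_only.items()
            },
            "n_hearts": self.n_hearts,
            "dice_convention": self.dice_convention,
            "per_heart": {k: r.as_dict() for k, r in self.reports.items()},
        }


def summarize_cohort(
    reports: dict[str, ComparisonReport],
    thresholds: tuple[float, ...] = DEFAULT_DICE_THRESHOLDS,
    n_hearts: int | None = None,
) -> CohortComparison:
    """Cohort means of per-heart comparison reports.

    SSIM / inner product / RMS means are plain arithmetic means over
    hearts.  The primary Dice mean at each threshold divides the sum of
    defined per-heart values by ``n_hearts`` (undefined entries count
    zero in the numerator but remain in the divisor); a defined-only
    mean is also reported.
    """
    if not reports:
        raise ValidationError("need >= 1 report")
    if n_hearts is None:
        n_hearts = len(reports)
    if n_hearts < len(reports):
        raise ValidationError("n_hearts smaller than the number of reports")
    rs = list(reports.values())
    mean_dice: dict[float, float] = {}
    mean_dice_def: dict[float, float | None] = {}
    for t in thresholds:
        vals = [r.dice.get(float(t)) for r in rs]
        defined = [v for v in vals if v is not None]
        mean_dice[float(t)] = sum(defined) / n_hearts
        mean_dice_def[float(t)] = (
            sum(defined) / len(defined) if defined else None
        )
    return CohortComparison(
        reports=reports,
        mean_ssim=float(np.mean([r.ssim for r in rs])),
        mean_inner_product=float(
            np.mean([r.inner_product for r in rs if r.inner_product is not None])
        ),
        mean_rms=float(np.mean([r.rms_diff for r in rs])),
        mean_dice=mean_dice,
        mean_dice_defined_only=mean_dice_def,
        n_hearts=n_hearts,
    )
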
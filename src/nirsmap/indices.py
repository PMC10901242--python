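"""Optical indices, contact filtering, and the ratio-index search.

Six scalar indices summarize each conditioned spectrum:

* ``COI  = Rrel(764) / Rrel(730)`` — contact optical index; values below
  a threshold (default 0.93) indicate poor catheter-tissue contact.
* ``LOI0 = sum_{660..690} |Rrel'(l) - Rrel'(952)|`` — lesion optical index.
* ``LOI8 = Rrel'(601) - Rrel'(609)``
* ``SOI1 = sum_{600..1000} |Rrel'(l) - Rrel'(661)|`` — substrate index.
* ``SOI3 = Rrel(650) / Rrel(930)``
* ``SOI4 = Rrel(630) / Rrel(600)`` — found by exhaustive search over all
  ordered pairs of integer wavelengths, ranked by single-feature ROC AUC.

Sums run over the uniform 1 nm grid, endpoints inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .types import (
    DerivativeSpectrum,
    MappedSample,
    OpticalIndexVector,
    RelativeSpectrum,
    ValidationError,
)
from . import preprocess


class IndexError_(ValueError):
    """An optical index is undefined for this spectrum."""


@dataclass
class ContactFilterConfig:
    coi_threshold: float = 0.93

    def __post_init__(self) -> None:
        if self.coi_threshold <= 0:
            raise ValidationError("coi_threshold must be > 0")


@dataclass
class RatioIndexCandidate:
    numerator_nm: int
    denominator_nm: int
    auc: float

    def __post_init__(self) -> None:
        if self.numerator_nm == self.denominator_nm:
            raise ValidationError("numerator and denominator must differ")


def _i(nm: int) -> int:
    return nm - 600


def compute_index_vector(
    s: RelativeSpectrum, d: DerivativeSpectrum | None = None
) -> OpticalIndexVector:
    """Evaluate the six optical indices for one conditioned spectrum."""
    if d is None:
        d = preprocess.differentiate(s)
    r, dr = s.rrel, d.drrel
    for den_nm in (730, 930, 600):
        if r[_i(den_nm)] <= 0:
            raise IndexError_(f"reflectance at {den_nm} nm is <= 0")
    return OpticalIndexVector(
        coi=r[_i(764)] / r[_i(730)],
        loi0=float(np.sum(np.abs(dr[_i(660) : _i(690) + 1] - dr[_i(952)]))),
        loi8=float(dr[_i(601)] - dr[_i(609)]),
        soi1=float(np.sum(np.abs(dr - dr[_i(661)]))),
        soi3=r[_i(650)] / r[_i(930)],
        soi4=r[_i(630)] / r[_i(600)],
    )


def index_matrix(rrel: np.ndarray) -> pd.DataFrame:
    """Vectorized indices for an (n, 401) matrix of conditioned spectra."""
    rrel = np.atleast_2d(np.asarray(rrel, dtype=float))
    dr = preprocess.differentiate_batch(rrel)
    return pd.DataFrame(
        {
            "coi": rrel[:, _i(764)] / rrel[:, _i(730)],
            "loi0": np.sum(
                np.abs(dr[:, _i(660) : _i(690) + 1] - dr[:, [_i(952)]]), axis=1
            ),
            "loi8": dr[:, _i(601)] - dr[:, _i(609)],
            "soi1": np.sum(np.abs(dr - dr[:, [_i(661)]]), axis=1),
            "soi3": rrel[:, _i(650)] / rrel[:, _i(930)],
            "soi4": rrel[:, _i(630)] / rrel[:, _i(600)],
        }
    )


def compute_ratio_index(s: RelativeSpectrum, num_nm: int, den_nm: int) -> float:
    """Generic ratiometric index Rrel(num)/Rrel(den); no interpolation."""
    den = s.rrel[_i(den_nm)]
    if den <= 0:
        raise IndexError_(f"reflectance at {den_nm} nm is <= 0")
    return float(s.rrel[_i(num_nm)] / den)


def filter_contact(
    samples: list[MappedSample], cfg: ContactFilterConfig | None = None
) -> tuple[list[MappedSample], list[MappedSample], float | None]:
    """Partition samples by catheter-tissue contact quality.

    A sample is kept iff its COI >= threshold.  Returns (kept, rejected,
    rejection_fraction); the fraction is None for empty input.  Order is
    preserved and each sample's ``contact`` flag is set.
    """
    cfg = cfg or ContactFilterConfig()
    kept: list[MappedSample] = []
    rejected: list[MappedSample] = []
    for s in samples:
        if not isinstance(s.spectrum, RelativeSpectrum):
            raise ValidationError("contact filtering requires conditioned spectra")
        coi = s.spectrum.at(764) / s.spectrum.at(730)
        s.contact = coi >= cfg.coi_threshold
        (kept if s.contact else rejected).append(s)
    if not samples:
        return kept, rejected, None
    return kept, rejected, len(rejected) / len(samples)


def _auc_columns(scores: np.ndarray, positive: np.ndarray) -> np.ndarray:
    """Tie-corrected Mann-Whitney AUC for each column of ``scores``."""
    ranks = rankdata(scores, axis=0)
    n1 = int(positive.sum())
    n0 = len(positive) - n1
    u = ranks[positive].sum(axis=0) - n1 * (n1 + 1) / 2
    return u / (n1 * n0)


def search_ratio_indices(
    rrel: np.ndarray,
    labels: np.ndarray,
    chunk: int = 8000,
) -> pd.DataFrame:
    """Exhaustive ratio-index search over ordered integer-wavelength pairs.

    For every ordered pair (num, den) of distinct wavelengths in
    600..1000 nm, scores Rrel(num)/Rrel(den) as a single-feature
    classifier by ROC AUC (lesion positive) and returns all 401*400
    candidates ranked by descending AUC.

    ``labels`` is boolean (True = lesion); both classes must be present
    with at least two samples each.
    """
    rrel = np.atleast_2d(np.asarray(rrel, dtype=float))
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any() or min(labels.sum(), (~labels).sum()) < 2:
        raise ValidationError("need >= 2 samples in each class")

    n_wl = rrel.shape[1]
    num_idx, den_idx = np.meshgrid(np.arange(n_wl), np.arange(n_wl), indexing="ij")
    keep = num_idx != den_idx
    num_idx, den_idx = num_idx[keep], den_idx[keep]

    aucs = np.empty(len(num_idx))
    for start in range(0, len(num_idx), chunk):
        sl = slice(start, start + chunk)
        ratios = rrel[:, num_idx[sl]] / rrel[:, den_idx[sl]]
        aucs[sl] = _auc_columns(ratios, labels)

    df = pd.DataFrame(
        {
            "numerator_nm": 600 + num_idx,
            "denominator_nm": 600 + den_idx,
            "auc": aucs,
        }
    )
    df = df.sort_values("auc", ascending=False, kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def index_table(samples: list[MappedSample]) -> pd.DataFrame:
    """Per-sample table of metadata plus the six optical indices."""
    rows = []
    rrel = []
    for s in samples:
        if not isinstance(s.spectrum, RelativeSpectrum):
            raise ValidationError("index table requires conditioned spectra")
        rrel.append(s.spectrum.rrel)
        rows.append(
            {
                "sample_id": s.sample_id,
                "heart_id": s.heart_id,
                "medium": s.medium,
                "label": s.label,
                "kept": s.contact,
            }
        )
    meta = pd.DataFrame(rows)
    idx = index_matrix(np.asarray(rrel))
    return pd.concat([meta, idx], axis=1)
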
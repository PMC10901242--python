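"""Readers and writers for session tables, pose logs, images, and reports.

A mapping session is stored as two delimited files: ``spectra.csv``
(``sample_id`` plus one column per wavelength, headers ``w<nm>``) and
``meta.csv`` (``sample_id`` plus typed metadata and pose columns).  The
wavelength header is the single source of grid truth; no re-gridding
happens at I/O time.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .types import (
    GRID,
    ComparisonReport,
    MappedSample,
    RawSpectrum,
    RelativeSpectrum,
    TrackerPose,
    ValidationError,
)

POSE_COLUMNS = ("time_s", "x_mm", "y_mm", "z_mm", "pitch_deg", "yaw_deg", "roll_deg")


class FormatError(ValueError):
    """A file does not conform to its declared schema."""


def _parse_wavelength_header(columns: Sequence[str]) -> np.ndarray:
    wl = []
    for c in columns:
        if not c.startswith("w"):
            raise FormatError(f"spectra column {c!r} does not match 'w<nm>'")
        try:
            wl.append(float(c[1:]))
        except ValueError as e:
            raise FormatError(f"unparseable wavelength column {c!r}") from e
    wl = np.asarray(wl)
    if not np.all(np.diff(wl) > 0):
        raise FormatError("wavelength header is not strictly increasing")
    return wl


def read_session(
    spectra_path: str | Path,
    meta_path: str | Path,
    stage: str = "auto",
) -> list[MappedSample]:
    """Read a session's spectra + metadata tables into MappedSamples.

    ``stage`` declares whether spectra rows are raw counts or conditioned
    relative reflectance; ``"auto"`` infers "relative" when the wavelength
    header is exactly the standard 600-1000 nm grid, else "raw".
    """
    if stage not in ("auto", "raw", "relative"):
        raise ValueError("stage must be 'auto', 'raw', or 'relative'")
    spectra = pd.read_csv(spectra_path, dtype={"sample_id": str})
    meta = pd.read_csv(meta_path, dtype={"sample_id": str, "heart_id": str})
    if "sample_id" not in spectra.columns or "sample_id" not in meta.columns:
        raise FormatError("both files need a sample_id column")

    wl = _parse_wavelength_header([c for c in spectra.columns if c != "sample_id"])
    if stage == "auto":
        stage = (
            "relative"
            if len(wl) == len(GRID) and np.array_equal(wl, GRID)
            else "raw"
        )

    spec_ids = set(spectra["sample_id"])
    meta_ids = set(meta["sample_id"])
    if spec_ids != meta_ids:
        missing = sorted(spec_ids ^ meta_ids)
        raise FormatError(
            f"sample_id mismatch between spectra and meta: {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    if len(spec_ids) != len(spectra) or len(meta_ids) != len(meta):
        raise FormatError("duplicate sample_id")

    spectra = spectra.set_index("sample_id")
    wl_cols = list(spectra.columns)

    samples: list[MappedSample] = []
    for row in meta.itertuples(index=False):
        vals = spectra.loc[row.sample_id, wl_cols].to_numpy(dtype=float)
        if stage == "relative":
            spectrum: RawSpectrum | RelativeSpectrum = RelativeSpectrum(vals)
        else:
            spectrum = RawSpectrum(wl, vals)
        pose = TrackerPose(
            x=row.x_mm, y=row.y_mm, z=row.z_mm,
            pitch=row.pitch_deg, yaw=row.yaw_deg, roll=row.roll_deg,
            time=getattr(row, "time_s", 0.0),
        )
        u = getattr(row, "u", math.nan)
        v = getattr(row, "v", math.nan)
        pixel = None if (pd.isna(u) or pd.isna(v)) else (float(u), float(v))
        contact_raw = getattr(row, "contact", None)
        contact = None if contact_raw is None or pd.isna(contact_raw) else bool(contact_raw)
        samples.append(
            MappedSample(
                sample_id=row.sample_id,
                heart_id=str(row.heart_id),
                medium=row.medium,
                pose=pose,
                spectrum=spectrum,
                label=row.label,
                pixel=pixel,
                contact=contact,
            )
        )
    return samples


def write_session(
    samples: Iterable[MappedSample],
    spectra_path: str | Path,
    meta_path: str | Path,
) -> None:
    """Write samples to the spectra.csv / meta.csv pair.

    All spectra must share one wavelength grid (raw) or all be conditioned
    (relative); mixing stages is an error.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("no samples to write")
    first = samples[0].spectrum
    if isinstance(first, RelativeSpectrum):
        wl = GRID
        get = lambda s: s.rrel  # noqa: E731
        kinds = (RelativeSpectrum,)
    else:
        wl = first.wavelengths
        get = lambda s: s.counts  # noqa: E731
        kinds = (RawSpectrum,)
    rows, meta_rows = [], []
    for s in samples:
        if not isinstance(s.spectrum, kinds):
            raise ValueError("cannot mix raw and relative spectra in one session")
        if isinstance(s.spectrum, RawSpectrum) and not np.array_equal(
            s.spectrum.wavelengths, wl
        ):
            raise ValueError("raw spectra must share one wavelength grid")
        rows.append(get(s.spectrum))
        meta_rows.append(
            {
                "sample_id": s.sample_id,
                "heart_id": s.heart_id,
                "medium": s.medium,
                "label": s.label,
                "time_s": s.pose.time,
                "x_mm": s.pose.x,
                "y_mm": s.pose.y,
                "z_mm": s.pose.z,
                "pitch_deg": s.pose.pitch,
                "yaw_deg": s.pose.yaw,
                "roll_deg": s.pose.roll,
                "u": math.nan if s.pixel is None else s.pixel[0],
                "v": math.nan if s.pixel is None else s.pixel[1],
                "contact": math.nan if s.contact is None else bool(s.contact),
            }
        )
    spec_df = pd.DataFrame(
        np.asarray(rows), columns=[f"w{w:g}" for w in wl]
    )
    spec_df.insert(0, "sample_id", [s.sample_id for s in samples])
    spec_df.to_csv(spectra_path, index=False)
    pd.DataFrame(meta_rows).to_csv(meta_path, index=False)


def read_pose_log(path: str | Path) -> list[TrackerPose]:
    """Read a pose log CSV into TrackerPoses, in file order."""
    df = pd.read_csv(path)
    missing = [c for c in POSE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"pose log missing columns: {missing}")
    for col in POSE_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise FormatError(
                f"non-numeric value {df[col][row]!r} in column {col}, data row {row}"
            )
        if coerced.isna().any():
            row = int(coerced.isna().idxmax())
            raise FormatError(f"missing value in column {col}, data row {row}")
        df[col] = coerced
    return [
        TrackerPose(
            x=r.x_mm, y=r.y_mm, z=r.z_mm,
            pitch=r.pitch_deg, yaw=r.yaw_deg, roll=r.roll_deg, time=r.time_s,
        )
        for r in df.itertuples(index=False)
    ]


def write_pose_log(poses: Iterable[TrackerPose], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "time_s": p.time, "x_mm": p.x, "y_mm": p.y, "z_mm": p.z,
                "pitch_deg": p.pitch, "yaw_deg": p.yaw, "roll_deg": p.roll,
            }
            for p in poses
        ],
        columns=list(POSE_COLUMNS),
    ).to_csv(path, index=False)


def read_reference_image(path: str | Path) -> tuple[np.ndarray, tuple[int, int]]:
    """Read a reference photograph as an array with 0-based (row, col) indexing.

    Returns the pixel grid and its (height, width).
    """
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except (OSError, SyntaxError) as e:
        raise IOError(f"cannot read image {path}: {e}") from e
    return arr, (arr.shape[0], arr.shape[1])


def write_report(report: ComparisonReport | dict, path: str | Path) -> None:
    """Serialize a report to JSON; undefined Dice entries become null."""
    if isinstance(report, ComparisonReport):
        payload = report.as_dict()
    else:
        payload = report
    _check_finite(payload, "report")
    Path(path).write_text(json.dumps(payload, indent=2, allow_nan=False))


def _check_finite(obj, where: str) -> None:
    if isinstance(obj, dict):
        for k, v in obj.items():
            _check_finite(v, f"{where}.{k}")
    elif isinstance(obj, (list, tuple)):
        for i, v in enumerate(obj):
            _check_finite(v, f"{where}[{i}]")
    elif isinstance(obj, float) and not math.isfinite(obj):
        raise ValidationError(f"non-finite value at {where}")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
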
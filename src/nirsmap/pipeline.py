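"""End-to-end orchestration: simulate -> preprocess -> indices/filter ->
classify -> map -> compare, under a single seeded configuration."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, compare, indices, mapping, preprocess, stats, synthetic
from .preprocess import CalibrationPair
from .types import MappedSample, RelativeSpectrum, ValidationError

log = logging.getLogger("nirsmap")


@dataclass
class PipelineConfig:
    """All stage parameters plus the seed, in one reproducible object."""

    seed: int = 0
    contact_threshold: float = 0.93
    probability_threshold: float = 0.5
    dice_thresholds: tuple[float, ...] = (0.3, 0.5, 0.7)
    grid_spacing_mm: float = mapping.DEFAULT_SPACING_MM
    map_cutoff: float = mapping.CUTOFF_2D
    model_kind: str = "random_forest"
    feature_names: tuple[str, ...] = classify.DEFAULT_FEATURES
    n_test_hearts: int = 4
    build_maps: bool = True
    session: synthetic.SessionConfig = field(default_factory=synthetic.SessionConfig)

    def __post_init__(self) -> None:
        if not 0.0 < self.contact_threshold <= 1.0:
            raise ValidationError("contact_threshold must lie in (0, 1]")
        if not 0.0 <= self.probability_threshold <= 1.0:
            raise ValidationError("probability_threshold must lie in [0, 1]")
        for t in self.dice_thresholds:
            if not 0.0 <= t <= 1.0:
                raise ValidationError("dice thresholds must lie in [0, 1]")
        if self.model_kind not in classify.MODEL_KINDS:
            raise ValidationError(f"unknown model kind {self.model_kind!r}")
        self.session = (
            self.session
            if isinstance(self.session, synthetic.SessionConfig)
            else synthetic.SessionConfig(**self.session)
        )
        self.session.seed = self.seed

    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _jsonable(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__}
    if isinstance(obj, (tuple, list)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def preprocess_samples(
    samples: list[MappedSample], cal: CalibrationPair
) -> list[MappedSample]:
    """Calibrate + condition every raw spectrum, in place, vectorized."""
    raw = [s for s in samples if not isinstance(s.spectrum, RelativeSpectrum)]
    if not raw:
        return samples
    wl = raw[0].spectrum.wavelengths
    counts = np.stack([s.spectrum.counts for s in raw])
    if not np.array_equal(wl, cal.standard.wavelengths):
        raise ValidationError("sample and standard wavelength grids differ")
    band = (wl >= 600) & (wl <= 1000)
    if np.any(cal.standard.counts[band] <= 0):
        raise ValidationError("standard reflectance <= 0 inside 600-1000 nm")
    rel = cal.phantom_factor * counts / cal.standard.counts[None, :]
    rrel = preprocess.condition_batch(wl, rel)
    for s, row in zip(raw, rrel):
        s.spectrum = RelativeSpectrum(row)
    return samples


@dataclass
class HeartMaps:
    heart_id: str
    maps: dict[str, "mapping.ProbabilityMap"]  # per medium
    truth_map: "mapping.ProbabilityMap"
    report: "compare.ComparisonReport"  # PBS vs blood
    dice_pred_truth: dict[str, float | None]  # per medium, at p threshold


@dataclass
class PipelineResult:
    config: PipelineConfig
    config_hash: str
    n_spectra: int
    n_kept: int
    n_rejected: int
    rejection_fraction: float
    index_table: pd.DataFrame
    evaluation: classify.Evaluation
    train_hearts: list[str]
    test_hearts: list[str]
    heart_maps: dict[str, HeartMaps]
    cohort: "compare.CohortComparison | None"

    def summary(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.config.seed,
            "n_spectra": self.n_spectra,
            "n_kept": self.n_kept,
            "n_rejected": self.n_rejected,
            "rejection_fraction": self.rejection_fraction,
            "train_hearts": self.train_hearts,
            "test_hearts": self.test_hearts,
            "evaluation": self.evaluation.as_dict(),
            "cohort": self.cohort.as_dict() if self.cohort is not None else None,
            "dice_pred_truth": {
                h: m.dice_pred_truth for h, m in self.heart_maps.items()
            },
        }


def split_hearts(heart_ids: list[str], n_test: int) -> tuple[list[str], list[str]]:
    """Deterministic heart-wise split: the last n_test hearts (sorted) test."""
    hearts = sorted(set(heart_ids))
    if n_test >= len(hearts):
        raise ValidationError("n_test_hearts must be smaller than the cohort")
    return hearts[: len(hearts) - n_test], hearts[len(hearts) - n_test :]


def _maps_for_heart(
    heart: synthetic.HeartTruth,
    table: pd.DataFrame,
    probs: np.ndarray,
    xy: np.ndarray,
    cfg: PipelineConfig,
) -> HeartMaps:
    sel = table["heart_id"] == heart.heart_id
    media = sorted(table.loc[sel, "medium"].unique())
    pooled = xy[sel.to_numpy()]
    maps = {}
    for medium in media:
        m = (sel & (table["medium"] == medium)).to_numpy()
        maps[medium] = mapping.build_probability_map(
            xy[m],
            probs[m],
            boundary_points=pooled,
            spacing=cfg.grid_spacing_mm,
            cutoff=cfg.map_cutoff,
        )
    truth_vals = heart.truth_probability(pooled[:, 0], pooled[:, 1])
    truth_map = mapping.build_probability_map(
        pooled,
        truth_vals,
        boundary_points=pooled,
        spacing=cfg.grid_spacing_mm,
        cutoff=cfg.map_cutoff,
    )
    a, b = compare.intersect_masks(maps[media[0]], maps[media[-1]])
    report = compare.compare_maps(a, b, thresholds=cfg.dice_thresholds)
    dice_pt = {}
    p = cfg.probability_threshold
    for medium in media:
        pm, tm = compare.intersect_masks(maps[medium], truth_map)
        dice_pt[medium] = compare.dice(
            mapping.threshold_map(pm, p), mapping.threshold_map(tm, p)
        )
    return HeartMaps(heart.heart_id, maps, truth_map, report, dice_pt)


def run_pipeline(
    cfg: PipelineConfig, session: synthetic.SessionData | None = None
) -> PipelineResult:
    """Execute the full analysis on a (possibly pre-built) session."""
    if session is None:
        log.info("simulating session (seed=%d)", cfg.seed)
        session = synthetic.simulate_session(cfg.session)

    log.info("preprocessing %d spectra", len(session.samples))
    preprocess_samples(session.samples, session.calibration)

    kept, rejected, frac = indices.filter_contact(
        session.samples, indices.ContactFilterConfig(cfg.contact_threshold)
    )
    assert len(kept) + len(rejected) == len(session.samples)
    log.info(
        "contact filter: kept %d, rejected %d (%.1f%%)",
        len(kept), len(rejected), 100 * (frac or 0.0),
    )

    table = indices.index_table(kept)
    train_hearts, test_hearts = split_hearts(list(table["heart_id"]), cfg.n_test_hearts)
    is_test = table["heart_id"].isin(test_hearts).to_numpy()

    X, y, hearts_arr, counts = classify.build_dataset(table, cfg.feature_names)
    log.info("dataset: %s", counts)
    clf = classify.train_classifier(
        X[~is_test], y[~is_test], hearts_arr[~is_test],
        kind=cfg.model_kind, seed=cfg.seed, feature_names=cfg.feature_names,
    )
    evaluation = classify.evaluate(
        clf, X[is_test], y[is_test], threshold=cfg.probability_threshold
    )
    log.info("test evaluation: %s", evaluation.as_dict())

    heart_maps: dict[str, HeartMaps] = {}
    cohort = None
    if cfg.build_maps:
        probs = clf.predict_proba(X)
        xy = np.array([[s.pose.x, s.pose.y] for s in kept])
        for h in test_hearts:
            heart_maps[h] = _maps_for_heart(session.hearts[h], table, probs, xy, cfg)
        cohort = compare.summarize_cohort(
            {h: m.report for h, m in heart_maps.items()},
            thresholds=cfg.dice_thresholds,
            n_hearts=len(test_hearts),
        )

    return PipelineResult(
        config=cfg,
        config_hash=cfg.config_hash(),
        n_spectra=len(session.samples),
        n_kept=len(kept),
        n_rejected=len(rejected),
        rejection_fraction=frac if frac is not None else float("nan"),
        index_table=table,
        evaluation=evaluation,
        train_hearts=train_hearts,
        test_hearts=test_hearts,
        heart_maps=heart_maps,
        cohort=cohort,
    )


def write_artifacts(result: PipelineResult, out_dir: str | Path) -> Path:
    """Persist index table, evaluation, and comparison reports."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.index_table.to_csv(out / "index_table.csv", index=False)
    (out / "summary.json").write_text(json.dumps(result.summary(), indent=2))
    return out
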
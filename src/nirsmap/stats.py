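"""Statistical characterization of optical indices.

Covers the pooled lesion-vs-nonlesion t-tests, ROC/AUC evaluation of
single indices, per-heart medium-equivalence summaries (PBS vs. blood),
Pearson-correlation feature selection, and the kernel-weighted
angle-sensitivity curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.transform import Rotation
from scipy.stats import rankdata

from .types import TrackerPose, ValidationError


def pooled_t_test(
    a: np.ndarray, b: np.ndarray, equal_var: bool = True
) -> tuple[float, float]:
    """Two-sample two-tailed t-test (pooled variance by default).

    Returns ``(t, p)``.  With zero variance in both groups and equal
    means, returns ``(0.0, 1.0)`` by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs n >= 2")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return np.inf if np.mean(a) > np.mean(b) else -np.inf, 0.0
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def roc_auc(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Tie-corrected rank-statistic AUC plus the ROC curve points.

    ``labels`` is boolean (True = positive).  Returns
    ``(auc, fpr, tpr)``; the curve runs monotonically from (0, 0) to
    (1, 1) and its trapezoidal area equals the rank AUC.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValidationError("both classes must be present")
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    ranks = rankdata(scores)
    auc = (ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)

    order = np.argsort(-scores, kind="mergesort")
    sorted_scores = scores[order]
    sorted_pos = labels[order]
    # one ROC point per distinct threshold
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    tps = np.cumsum(sorted_pos)[distinct]
    fps = np.cumsum(~sorted_pos)[distinct]
    tpr = np.r_[0.0, tps / n1]
    fpr = np.r_[0.0, fps / n0]
    return float(auc), fpr, tpr


@dataclass
class MediumComparison:
    """PBS-vs-blood t-test on per-heart means, for one tissue class."""

    label: str
    t: float
    p: float
    n_pbs: int
    n_blood: int


def per_heart_summary(
    table: pd.DataFrame, index_name: str, paired: bool = False
) -> tuple[pd.DataFrame, list[MediumComparison]]:
    """Per-(heart, medium, class) means of an index + medium t-tests.

    ``table`` needs columns heart_id, medium, label and the index.  With
    a full cohort of 22 hearts this yields 88 summary rows (22 hearts x
    2 media x 2 classes).  For each class, per-heart PBS means are then
    tested against per-heart blood means (unpaired by default; ``paired``
    uses only hearts present in both media).
    """
    required = {"heart_id", "medium", "label", index_name}
    if not required <= set(table.columns):
        raise ValidationError(f"table missing columns: {required - set(table.columns)}")
    data = table[table["label"].isin(["lesion", "nonlesion"])]
    grouped = (
        data.groupby(["heart_id", "medium", "label"], observed=True)[index_name]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_value", "count": "n"})
    )
    grouped["index"] = index_name

    comparisons = []
    for label in ("nonlesion", "lesion"):
        sub = grouped[grouped["label"] == label]
        pbs = sub[sub["medium"] == "PBS"].set_index("heart_id")["mean_value"]
        blood = sub[sub["medium"] == "blood"].set_index("heart_id")["mean_value"]
        if len(pbs) < 2 or len(blood) < 2:
            continue
        if paired:
            common = pbs.index.intersection(blood.index)
            t, p = sps.ttest_rel(pbs[common], blood[common])
            t, p = float(t), float(p)
            n_pbs = n_blood = len(common)
        else:
            t, p = pooled_t_test(pbs.to_numpy(), blood.to_numpy())
            n_pbs, n_blood = len(pbs), len(blood)
        comparisons.append(MediumComparison(label, t, p, n_pbs, n_blood))
    return grouped, comparisons


def select_features(
    features: pd.DataFrame,
    n_select: int = 5,
    seed_features: tuple[str, ...] = ("loi0", "soi1"),
) -> tuple[list[str], pd.DataFrame]:
    """Greedy selection of weakly correlated features.

    Computes the full Pearson correlation matrix, then starts from the
    seed features and repeatedly adds the feature minimizing the maximum
    absolute correlation with the chosen set, until ``n_select`` are
    chosen.  Constant features are excluded with a warning.
    """
    if features.shape[1] < 2 or features.shape[0] < 3:
        raise ValidationError("need >= 2 features and >= 3 samples")
    constant = [c for c in features.columns if features[c].nunique() <= 1]
    if constant:
        warnings.warn(f"excluding constant features: {constant}")
        features = features.drop(columns=constant)
    corr = features.corr(method="pearson")
    chosen = [f for f in seed_features if f in corr.columns]
    candidates = [c for c in corr.columns if c not in chosen]
    while len(chosen) < n_select and candidates:
        worst = {
            c: corr.loc[c, chosen].abs().max() if chosen else 0.0 for c in candidates
        }
        # a perfectly correlated duplicate is never addable alongside its twin
        addable = {c: w for c, w in worst.items() if w < 1.0 - 1e-12}
        if not addable:
            break
        best = min(addable, key=lambda c: (addable[c], c))
        chosen.append(best)
        candidates.remove(best)
    return chosen, corr


def kernel_sliding_stats(
    x: np.ndarray,
    y: np.ndarray,
    bandwidth: float = 5.0,
    grid: np.ndarray | None = None,
    n_grid: int = 100,
) -> pd.DataFrame:
    """Gaussian-kernel weighted sliding mean and SD of y against x.

    Used for the contact-angle sensitivity curves: x holds angles in
    degrees, y index values.  Returns a frame with columns
    ``angle_deg, mean, sd, n_eff``; grid points further than several
    bandwidths from all data get NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(x) != len(y):
        raise ValidationError("need >= 2 (x, y) points")
    if bandwidth <= 0:
        raise ValidationError("bandwidth must be > 0")
    if grid is None:
        grid = np.linspace(x.min(), x.max(), n_grid)
    w = np.exp(-0.5 * ((grid[:, None] - x[None, :]) / bandwidth) ** 2)
    wsum = w.sum(axis=1)
    valid = wsum > 1e-12
    mean = np.full(len(grid), np.nan)
    sd = np.full(len(grid), np.nan)
    n_eff = np.zeros(len(grid))
    mean[valid] = (w[valid] @ y) / wsum[valid]
    var = (w[valid] * (y[None, :] - mean[valid, None]) ** 2).sum(axis=1) / wsum[valid]
    sd[valid] = np.sqrt(var)
    n_eff[valid] = wsum[valid] ** 2 / (w[valid] ** 2).sum(axis=1)
    return pd.DataFrame({"angle_deg": grid, "mean": mean, "sd": sd, "n_eff": n_eff})


def catheter_axis(pose: TrackerPose) -> np.ndarray:
    """Unit vector along the catheter's long axis in tracker coordinates.

    Orientation convention: yaw about the fixed z-axis, then pitch about
    the rotated y-axis, then roll about the catheter's own axis (which
    leaves the axis unchanged).  At zero pitch/yaw the catheter points
    along +z, i.e. along the bath's surface normal.
    """
    rot = Rotation.from_euler("ZYZ", [pose.yaw, pose.pitch, pose.roll], degrees=True)
    return rot.apply([0.0, 0.0, 1.0])


def contact_angle(
    pose: TrackerPose, surface_normal: np.ndarray = (0.0, 0.0, 1.0)
) -> float:
    """Angle (deg, in [0, 90]) between the catheter axis and the surface normal.

    The flat-sample default takes the bath's vertical axis as the normal;
    0 deg is perpendicular contact.
    """
    n = np.asarray(surface_normal, dtype=float)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise ValidationError("surface normal has zero length")
    axis = catheter_axis(pose)
    cos = abs(float(axis @ n) / norm)
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))
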
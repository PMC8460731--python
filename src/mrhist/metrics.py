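"""Evaluation suite: target registration error, volumetric overlap
metrics, Hausdorff distance, and the two-sample significance tests.

Landmarks only evaluate registration here -- they never drive it.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .geometry import GeometryError, LabelVolume, LandmarkSet

__all__ = [
    "target_registration_error",
    "cumulative_error",
    "precision_recall_dice",
    "hausdorff_distance",
    "two_sample_test",
    "label_table",
]


def target_registration_error(deformed: LandmarkSet, target: LandmarkSet
                              ) -> tuple[np.ndarray, float, float]:
    """Per-landmark Euclidean distances (paired by label) + mean, sd in mm."""
    if set(deformed.labels) != set(target.labels):
        raise GeometryError("landmark labels do not correspond")
    order = {lab: i for i, lab in enumerate(target.labels)}
    idx = [order[lab] for lab in deformed.labels]
    d = np.linalg.norm(deformed.points - target.points[idx], axis=1)
    return d, float(d.mean()), float(d.std(ddof=0))


def cumulative_error(stage_means) -> float:
    """Upper bound on the pipeline error: sum of the per-stage mean TREs."""
    stage_means = list(stage_means)
    if not stage_means:
        raise GeometryError("need at least one stage error")
    return float(np.sum(stage_means))


def _require_same_grid(a: LabelVolume, b: LabelVolume) -> None:
    if a.shape != b.shape or not np.allclose(a.spacing, b.spacing) or \
            not np.allclose(a.origin, b.origin):
        raise GeometryError("labels must share one grid")


def precision_recall_dice(test: LabelVolume, reference: LabelVolume
                          ) -> tuple[float, float, float]:
    """Voxel-count precision, recall and DICE of ``test`` vs ``reference``."""
    _require_same_grid(test, reference)
    t = test.values > 0.5
    r = reference.values > 0.5
    if not r.any():
        raise GeometryError("empty reference label: recall undefined")
    if not t.any():
        raise GeometryError("empty test label: precision undefined")
    tp = float(np.sum(t & r))
    fp = float(np.sum(t & ~r))
    fn = float(np.sum(~t & r))
    return (tp / (tp + fp), tp / (tp + fn), 2 * tp / (2 * tp + fp + fn))


def _boundary_points(label: LabelVolume) -> np.ndarray:
    from scipy.ndimage import binary_erosion

    mask = label.values > 0.5
    boundary = mask & ~binary_erosion(mask)
    idx = np.argwhere(boundary)
    return label.voxel_to_world(idx.astype(float))


def hausdorff_distance(A: LabelVolume, B: LabelVolume) -> float:
    """Symmetric Hausdorff distance between label boundaries, world mm."""
    if not (A.values > 0.5).any() or not (B.values > 0.5).any():
        raise GeometryError("empty label volume")
    pa = _boundary_points(A)
    pb = _boundary_points(B)
    d_ab = cKDTree(pb).query(pa)[0].max()
    d_ba = cKDTree(pa).query(pb)[0].max()
    return float(max(d_ab, d_ba))


def two_sample_test(a, b, design: str = "independent") -> tuple[float, float]:
    """Two-sided t-test: ``independent`` (equal variance) or ``related``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise GeometryError("need at least two observations per sample")
    if design == "independent":
        t, p = stats.ttest_ind(a, b, equal_var=True)
    elif design == "related":
        if len(a) != len(b):
            raise GeometryError("related design requires equal lengths")
        if np.allclose(a - b, 0.0):
            return 0.0, 1.0  # identical pairs: no difference at all
        t, p = stats.ttest_rel(a, b)
    else:
        raise ValueError(f"unknown design {design!r}")
    return float(t), float(p)


def label_table(labels: dict[str, LabelVolume], reference: LabelVolume
                ) -> pd.DataFrame:
    """Biomarker evaluation table: volumes and spatial metrics vs reference.

    One row per label with columns volume_mm3, precision, recall, dice,
    hausdorff_mm (mirrors the per-subject biomarker comparison layout).
    """
    rows = []
    for name, lab in labels.items():
        p, r, d = precision_recall_dice(lab, reference)
        rows.append({
            "label": name,
            "volume_mm3": lab.volume_mm3,
            "precision": p,
            "recall": r,
            "dice": d,
            "hausdorff_mm": hausdorff_distance(lab, reference),
        })
    df = pd.DataFrame(rows)
    df.insert(1, "reference_volume_mm3", reference.volume_mm3)
    return df
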
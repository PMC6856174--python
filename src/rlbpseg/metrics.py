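"""Segmentation evaluation metrics.

Conventions follow common volumetric-segmentation practice: ``A`` is the
manual (reference) segmentation and ``B`` the automated one.  Volumes are
voxel counts times the voxel volume; overlap metrics are unitless, the
volume difference dVol is reported in cm^3 and the mean distance MD in mm.

MD is deliberately one-sided: the mean over boundary voxels of A of the
minimum Euclidean distance (between voxel centers, spacing-aware) to the
boundary of B.  Boundary voxels are foreground voxels with at least one
background face-neighbor (6-connectivity); voxels on the array edge count
as boundary.

Metrics that would be undefined (empty reference or prediction) raise
:class:`UndefinedMetricError` rather than returning a fabricated number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .volume_io import LabelMap

__all__ = [
    "UndefinedMetricError",
    "SegmentationScores",
    "overlap_scores",
    "boundary_mask",
    "mean_distance",
    "volume_pearson",
    "evaluate",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric has no defined value for the given inputs."""


@dataclass
class SegmentationScores:
    dice: float
    jaccard: float
    precision: float
    recall: float
    dvol_cm3: float
    md_mm: float | None = None

    def as_dict(self) -> dict[str, float]:
        d = {
            "dice": self.dice,
            "jaccard": self.jaccard,
            "precision": self.precision,
            "recall": self.recall,
            "dvol_cm3": self.dvol_cm3,
        }
        if self.md_mm is not None:
            d["md_mm"] = self.md_mm
        return d


def _as_bool(x) -> np.ndarray:
    arr = x.data if isinstance(x, LabelMap) else np.asarray(x)
    return arr.astype(bool)


def overlap_scores(A, B, spacing=(1.0, 1.0, 1.0)) -> SegmentationScores:
    """Dice, Jaccard, Precision, Recall and absolute volume difference.

    Precision is the overlap fraction of the automated volume B, Recall of
    the manual volume A.  dVol = |V(A) - V(B)| in cm^3.
    """
    a = _as_bool(A)
    b = _as_bool(B)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    va = int(a.sum())
    vb = int(b.sum())
    if va == 0:
        raise UndefinedMetricError("reference segmentation A is empty; recall undefined")
    if vb == 0:
        raise UndefinedMetricError("automated segmentation B is empty; precision undefined")
    inter = int(np.count_nonzero(a & b))
    union = va + vb - inter
    vox_cm3 = float(np.prod(spacing)) / 1000.0
    return SegmentationScores(
        dice=2.0 * inter / (va + vb),
        jaccard=inter / union,
        precision=inter / vb,
        recall=inter / va,
        dvol_cm3=abs(va - vb) * vox_cm3,
    )


def boundary_mask(mask) -> np.ndarray:
    """Foreground voxels with at least one background 6-neighbor."""
    m = _as_bool(mask)
    struct = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(m, structure=struct, border_value=0)
    return m & ~interior


def mean_distance(A, B, spacing=(1.0, 1.0, 1.0)) -> float:
    """One-sided mean boundary distance from A to B, in mm.

    mean over e in boundary(A) of min over f in boundary(B) of d(e, f),
    with d the Euclidean distance between voxel centers.  Not symmetric.
    Computed with an exact Euclidean distance transform of boundary(B).
    """
    ba = boundary_mask(A)
    bb = boundary_mask(B)
    if not ba.any():
        raise UndefinedMetricError("reference segmentation A has an empty boundary")
    if not bb.any():
        raise UndefinedMetricError("automated segmentation B has an empty boundary")
    dist_to_bb = ndimage.distance_transform_edt(~bb, sampling=spacing)
    return float(dist_to_bb[ba].mean())


def volume_pearson(v_manual, v_auto) -> float:
    """Pearson correlation between manual and automated volume series."""
    vm = np.asarray(v_manual, dtype=np.float64)
    va = np.asarray(v_auto, dtype=np.float64)
    if vm.shape != va.shape or vm.ndim != 1:
        raise ValueError("volume series must be 1D and equal length")
    if vm.size < 3:
        raise ValueError(f"need at least 3 subjects, got {vm.size}")
    if np.std(vm) == 0 or np.std(va) == 0:
        raise UndefinedMetricError("volume series has zero variance")
    return float(stats.pearsonr(vm, va).statistic)


def evaluate(truth, pred, spacing=(1.0, 1.0, 1.0)) -> SegmentationScores:
    """All six metrics of a predicted label map against the manual truth."""
    scores = overlap_scores(truth, pred, spacing)
    scores.md_mm = mean_distance(truth, pred, spacing)
    return scores
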
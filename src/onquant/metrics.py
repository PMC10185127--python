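"""Segmentation evaluation: DSC, tolerance-DSC, precision/recall, HD95, ASD
and the two-way mixed-effects absolute-agreement single-rater ICC.

Conventions: surface voxels are mask voxels with at least one face-adjacent
background neighbour; surface distances are voxel-center to voxel-center in
world mm; the directed 95th percentile uses linear interpolation of the
empirical distribution. Degenerate cases: DSC of two empty masks is 1.0,
of one empty mask 0.0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .grid import BinaryMask


def _check_same_grid(a: BinaryMask, b: BinaryMask) -> None:
    if not a.same_grid(b):
        raise ValueError("masks are not on the same grid")


def dsc(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient 2|A n B| / (|A| + |B|)."""
    _check_same_grid(a, b)
    na, nb = int(a.voxels.sum()), int(b.voxels.sum())
    if na == 0 and nb == 0:
        return 1.0
    inter = int(np.logical_and(a.voxels, b.voxels).sum())
    return 2.0 * inter / (na + nb)


def surface_voxels(mask: BinaryMask) -> np.ndarray:
    """Indices (n, 3) of mask voxels with >= 1 face-adjacent background
    neighbour (volume faces count as background)."""
    m = mask.voxels.astype(bool)
    eroded = ndimage.binary_erosion(m, structure=ndimage.generate_binary_structure(3, 1),
                                    border_value=0)
    return np.argwhere(m & ~eroded)


def _surface_world(mask: BinaryMask) -> np.ndarray:
    idx = surface_voxels(mask)
    if idx.size == 0:
        raise ValueError("mask is empty")
    pts = mask.voxel_to_world(idx.astype(float))
    return np.atleast_2d(pts)


def dsc_tolerance(a: BinaryMask, b: BinaryMask, tol_voxels: float = 1.0) -> float:
    """DSC with a border tolerance: disagreeing voxels within
    ``tol_voxels * max(spacing)`` of the other mask's surface count as
    agreeing. Reduces exactly to :func:`dsc` at tol 0.
    """
    _check_same_grid(a, b)
    na, nb = int(a.voxels.sum()), int(b.voxels.sum())
    if na == 0 and nb == 0:
        return 1.0
    inter = int(np.logical_and(a.voxels, b.voxels).sum())
    if tol_voxels <= 0 or na == 0 or nb == 0:
        return 2.0 * inter / (na + nb)
    tol_mm = tol_voxels * float(np.max(a.spacing)) + 1e-9
    n_tol = 0
    for x, y in ((a, b), (b, a)):
        only = np.argwhere(np.logical_and(x.voxels, np.logical_not(y.voxels)))
        if only.size:
            tree = cKDTree(_surface_world(y))
            d, _ = tree.query(np.atleast_2d(x.voxel_to_world(only.astype(float))))
            n_tol += int((d <= tol_mm).sum())
    return (2.0 * inter + n_tol) / (na + nb)


def precision_recall(truth: BinaryMask, pred: BinaryMask):
    """(precision, recall) of a prediction against the truth mask.

    Precision is NaN (flagged undefined) for an empty prediction.
    """
    _check_same_grid(truth, pred)
    nt, np_ = int(truth.voxels.sum()), int(pred.voxels.sum())
    inter = int(np.logical_and(truth.voxels, pred.voxels).sum())
    precision = inter / np_ if np_ else float("nan")
    recall = inter / nt if nt else float("nan")
    return precision, recall


def _directed_distances(a: BinaryMask, b: BinaryMask) -> np.ndarray:
    """Distances (mm) from each surface voxel of a to the nearest surface
    voxel of b."""
    pa, pb = _surface_world(a), _surface_world(b)
    d, _ = cKDTree(pb).query(pa)
    return d


def hd95(a: BinaryMask, b: BinaryMask) -> float:
    """Symmetric 95th-percentile Hausdorff surface distance, world mm."""
    _check_same_grid(a, b)
    dab = _directed_distances(a, b)
    dba = _directed_distances(b, a)
    return float(max(np.percentile(dab, 95), np.percentile(dba, 95)))


def asd(a: BinaryMask, b: BinaryMask) -> float:
    """Average symmetric surface distance, world mm."""
    _check_same_grid(a, b)
    dab = _directed_distances(a, b)
    dba = _directed_distances(b, a)
    return float((dab.sum() + dba.sum()) / (dab.size + dba.size))


# --------------------------------------------------------------------------- #
# ICC
# --------------------------------------------------------------------------- #

@dataclass
class PairedMeasurements:
    rater1: np.ndarray
    rater2: np.ndarray

    def __post_init__(self) -> None:
        self.rater1 = np.asarray(self.rater1, dtype=float)
        self.rater2 = np.asarray(self.rater2, dtype=float)
        if self.rater1.shape != self.rater2.shape or self.rater1.ndim != 1:
            raise ValueError("rater vectors must be equal-length 1D")
        if self.rater1.size < 3:
            raise ValueError("need at least 3 paired measurements")
        if np.any(~np.isfinite(self.rater1)) or np.any(~np.isfinite(self.rater2)):
            raise ValueError("missing values are not allowed")


def icc_a1(pairs: PairedMeasurements) -> float:
    """ICC(A,1): two-way mixed-effects, absolute-agreement, single rater.

    McGraw & Wong's ICC(A,1) from the two-way ANOVA decomposition with n
    subjects and k=2 raters:

        ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    """
    if not isinstance(pairs, PairedMeasurements):
        pairs = PairedMeasurements(*pairs)
    data = np.column_stack([pairs.rater1, pairs.rater2])
    n, k = data.shape
    grand = data.mean()
    if np.allclose(data, grand):
        raise ValueError("zero total variance")
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))


# --------------------------------------------------------------------------- #
# Reporting
# --------------------------------------------------------------------------- #

def evaluate_pair(truth: BinaryMask, pred: BinaryMask) -> dict:
    """All spatial and distance metrics for one (truth, prediction) pair."""
    p, r = precision_recall(truth, pred)
    row = {"dsc": dsc(truth, pred), "dsc_tol1": dsc_tolerance(truth, pred, 1.0),
           "precision": p, "recall": r}
    if truth.voxels.any() and pred.voxels.any():
        row["hd95_mm"] = hd95(truth, pred)
        row["asd_mm"] = asd(truth, pred)
    else:
        row["hd95_mm"] = float("nan")
        row["asd_mm"] = float("nan")
    return row


def aggregate_report(rows: list) -> dict:
    """Mean+-SD for spatial metrics, median [IQR] for distance metrics."""
    out = {}
    for key in ("dsc", "dsc_tol1", "precision", "recall"):
        vals = np.array([r[key] for r in rows], dtype=float)
        out[key] = {"mean": float(np.nanmean(vals)), "sd": float(np.nanstd(vals))}
    for key in ("hd95_mm", "asd_mm"):
        vals = np.array([r[key] for r in rows], dtype=float)
        q1, med, q3 = np.nanpercentile(vals, [25, 50, 75])
        out[key] = {"median": float(med), "iqr": [float(q1), float(q3)]}
    return out
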
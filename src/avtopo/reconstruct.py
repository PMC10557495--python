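"""Voxel reconstruction of artery/vein labels and evaluation metrics.

Particle labels are painted back into the vessel mask through each particle's
scale region (a ball of radius scale x dilation factor); voxels no ball
covers take the label of the nearest covered voxel geodesically within the
mask, so the painted volume always partitions the mask.  Evaluation follows
the artery-positive convention: accuracy, sensitivity, specificity from the
particle confusion counts, plus the Dice similarity coefficient on voxels.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

ARTERY, VEIN = 1, 2

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class ConfusionCounts:
    """Artery = positive class: TP/FN count arteries, TN/FP count veins."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def paint_labels(
    positions: np.ndarray,
    scales: np.ndarray,
    labels: np.ndarray,
    mask: np.ndarray,
    dilation_factor: float = 1.25,
) -> np.ndarray:
    """Paint per-particle classes into the mask via scale balls.

    Each mask voxel takes the label of the nearest particle whose dilated
    scale ball covers it; uncovered voxels inherit from the nearest covered
    voxel by iterative 26-neighbor propagation inside the mask (geodesic).
    """
    mask = np.asarray(mask, bool)
    out = np.zeros(mask.shape, dtype=np.uint8)
    if len(positions) == 0:
        warnings.warn("no labeled particles; painted volume is empty")
        return out
    positions = np.asarray(positions, float)
    scales = np.asarray(scales, float)
    labels = np.asarray(labels)
    vox = np.argwhere(mask)
    tree = cKDTree(positions)
    radii = scales * dilation_factor
    rmax = float(radii.max())
    k = min(8, len(positions))
    dd, ii = tree.query(vox.astype(float), k=k)
    if k == 1:
        dd, ii = dd[:, None], ii[:, None]
    covered = dd <= radii[ii]
    any_cov = covered.any(axis=1)
    first = np.argmax(covered, axis=1)
    lab = np.zeros(len(vox), dtype=np.uint8)
    lab[any_cov] = labels[ii[np.arange(len(vox)), first]][any_cov]
    # fall back to the overall nearest particle for voxels far from any ball
    out[tuple(vox[any_cov].T)] = lab[any_cov]
    # geodesic fill of uncovered voxels within the mask
    remaining = mask & (out == 0)
    it = 0
    while remaining.any() and it < int(np.sum(mask.shape)):
        grown = ndimage.grey_dilation(out, footprint=_STRUCT26)
        newly = remaining & (grown > 0)
        if not newly.any():
            # disconnected pocket with no covered voxel: use nearest particle
            pocket = np.argwhere(remaining)
            _, jj = tree.query(pocket.astype(float))
            out[tuple(pocket.T)] = labels[jj]
            break
        out[newly] = grown[newly]
        remaining = mask & (out == 0)
        it += 1
    return out


def fuse_hilum(av: np.ndarray, hilum: np.ndarray, spacing=None, hilum_spacing=None) -> np.ndarray:
    """Voxelwise union of the painted labels and the hilum label volume.

    Hilum labels win on overlap: vessels near the hilum are abnormally large
    and non-tubular, so their dedicated labels are higher-trust there.
    """
    av = np.asarray(av)
    hilum = np.asarray(hilum)
    if av.shape != hilum.shape:
        raise ValueError(f"shape mismatch: {av.shape} vs {hilum.shape}")
    if spacing is not None and hilum_spacing is not None:
        if not np.allclose(spacing, hilum_spacing, atol=1e-6):
            raise ValueError("spacing mismatch between volumes")
    return np.where(hilum > 0, hilum, av).astype(av.dtype)


def confusion(predicted: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Particle-level confusion counts (artery positive)."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must cover the same particles")
    return ConfusionCounts(
        tp=int(((predicted == ARTERY) & (truth == ARTERY)).sum()),
        tn=int(((predicted == VEIN) & (truth == VEIN)).sum()),
        fp=int(((predicted == ARTERY) & (truth == VEIN)).sum()),
        fn=int(((predicted == VEIN) & (truth == ARTERY)).sum()),
    )


def metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity); zero denominators give NaN."""
    acc = (c.tp + c.tn) / c.total if c.total > 0 else math.nan
    sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else math.nan
    spec = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else math.nan
    return acc, sens, spec


def dsc(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice similarity coefficient 2|P∩G| / (|P| + |G|); both empty -> 1."""
    pred = np.asarray(pred, bool)
    truth = np.asarray(truth, bool)
    if pred.shape != truth.shape:
        raise ValueError("volumes must share geometry")
    p = int(pred.sum())
    g = int(truth.sum())
    if p + g == 0:
        return 1.0
    return 2.0 * int((pred & truth).sum()) / (p + g)
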
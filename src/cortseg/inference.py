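"""Whole-volume prediction by valid-patch tiling and threshold selection.

Because every convolution in the network is valid, a patch of side ``s``
yields predictions only for its central ``s - 40`` cube.  To predict a whole
volume, the volume is reflection-padded by 20 voxels per side, the output
windows tile the volume in disjoint fashion (edge tiles are shifted inward
and later tiles overwrite earlier ones, so every voxel is predicted exactly
once), and each output window's input window extends 20 voxels beyond it
into the padded volume.

The operating threshold on the sigmoid probability is chosen on a
validation set by a 0.05-step grid search maximizing the mean per-subject
Dice coefficient, with ties broken toward the lower threshold (favouring
sensitivity).
"""

from __future__ import annotations

import warnings
from typing import List, Optional, Sequence, Tuple

import numpy as np

from ._nn import sigmoid
from .evaluation import apply_min_size
from .network import MARGIN, UNet3D
from .volumes_io import LabelVolume, SubjectCase

#: grid of candidate thresholds, 0.05 ... 0.95 in steps of 0.05.
THRESHOLD_GRID = tuple(np.round(np.linspace(0.05, 0.95, 19), 2))


def fit_input_side(dims: Sequence[int], cap: int = 104) -> int:
    """Largest feasible input side whose output tile fits every axis.

    Feasible sides are multiples of 4 that are at least 44; the output side
    is ``side - 40``.  ``cap`` bounds the patch size (memory control).
    """
    limit = min(min(dims) + MARGIN, cap)
    side = (limit // 4) * 4
    if side < 44:
        raise ValueError(f"volume {tuple(dims)} too small for one output tile")
    return side


def tile_plan(volume_dims: Sequence[int], input_side: int = 88,
              output_side: int = 48) -> List[Tuple[Tuple[slice, ...], Tuple[slice, ...]]]:
    """Plan (input window, output window) pairs covering a volume.

    Output windows (slices into the original volume) tile it exactly once:
    regular tiles start at multiples of ``output_side`` and the final tile
    on each axis is shifted inward to end at the boundary; overlap is
    resolved by later-tile-overwrites (lexicographic priority).  Input
    windows are slices into the volume after reflection padding by 20 per
    side.  Raises ``ValueError`` if any axis is smaller than one output
    tile.
    """
    if output_side != input_side - MARGIN:
        raise ValueError(f"output_side must equal input_side - {MARGIN}")
    half = MARGIN // 2
    starts_per_axis = []
    for dim in volume_dims:
        if dim < output_side:
            raise ValueError(
                f"axis of size {dim} smaller than one {output_side}-voxel output tile")
        starts = list(range(0, dim - output_side + 1, output_side))
        if starts[-1] != dim - output_side:
            starts.append(dim - output_side)
        starts_per_axis.append(starts)
    plan = []
    for sx in starts_per_axis[0]:
        for sy in starts_per_axis[1]:
            for sz in starts_per_axis[2]:
                out_sl = (slice(sx, sx + output_side), slice(sy, sy + output_side),
                          slice(sz, sz + output_side))
                # padded coords: original index i lives at i + half
                in_sl = (slice(sx, sx + input_side), slice(sy, sy + input_side),
                         slice(sz, sz + input_side))
                plan.append((in_sl, out_sl))
    return plan


def predict_volume(model: UNet3D, case: SubjectCase, threshold: float = 0.5,
                   input_side: Optional[int] = None) -> Tuple[LabelVolume, np.ndarray]:
    """Predict a binary lesion mask and the probability volume for a subject.

    The case channels must already be z-score normalized (a warning is
    issued if the intensity mean is suspiciously far from zero).  The mask
    is ``probability >= threshold``; deterministic given the model weights.
    """
    dims = case.shape
    for name, vol in (("FLAIR", case.flair), ("MP2RAGE", case.mp2rage)):
        if abs(float(vol.data.mean())) > 0.5:
            warnings.warn(f"{name} channel of {case.subject_id} does not look "
                          "z-score normalized (|mean| > 0.5)", stacklevel=2)
    if input_side is None:
        input_side = fit_input_side(dims)
    half = MARGIN // 2
    pad = [(half, half)] * 3
    x = np.stack([np.pad(case.flair.data, pad, mode="reflect"),
                  np.pad(case.mp2rage.data, pad, mode="reflect")]).astype(np.float32)
    prob = np.empty(dims, dtype=np.float64)
    for in_sl, out_sl in tile_plan(dims, input_side, input_side - MARGIN):
        logits = model.forward(np.ascontiguousarray(x[(slice(None),) + in_sl]))[0]
        prob[out_sl] = sigmoid(logits)
    mask = (prob >= threshold).astype(np.uint8)
    return (LabelVolume(mask, case.spacing, case.flair.affine), prob)


def _dice(pred: np.ndarray, gt: np.ndarray) -> float:
    p = pred != 0
    g = gt != 0
    denom = int(p.sum()) + int(g.sum())
    if denom == 0:
        return np.nan
    return 2.0 * int((p & g).sum()) / denom


def select_threshold(prob_volumes: Sequence[np.ndarray],
                     gts: Sequence[np.ndarray],
                     min_size: int = 3, connectivity: int = 18,
                     grid: Sequence[float] = THRESHOLD_GRID) -> float:
    """Pick the grid threshold maximizing mean per-subject Dice.

    Masks are min-size filtered before Dice, matching the evaluation
    pipeline; ties are broken toward the LOWER threshold.  Subjects whose
    ground truth is empty are skipped.
    """
    if len(prob_volumes) == 0 or len(prob_volumes) != len(gts):
        raise ValueError("need matched, non-empty probability and ground-truth lists")
    best_t, best_score = None, -np.inf
    for t in grid:
        scores = []
        for prob, gt in zip(prob_volumes, gts):
            gt_arr = gt.labels if isinstance(gt, LabelVolume) else np.asarray(gt)
            gt_f = apply_min_size((gt_arr != 0).astype(np.uint8), min_size, connectivity)
            if not gt_f.any():
                continue
            mask = apply_min_size((prob >= t).astype(np.uint8), min_size, connectivity)
            scores.append(_dice(mask, gt_f))
        if not scores:
            continue
        score = float(np.mean(scores))
        if score > best_score + 1e-12:  # strict: ties keep the lower threshold
            best_score, best_t = score, float(t)
    if best_t is None:
        raise ValueError("threshold selection impossible: all validation ground truths empty")
    return best_t
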
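"""Lesion-wise and voxel-wise evaluation of segmentation masks.

The unit of "lesion" throughout is the connected component (default
18-connectivity in 3D, the MS-lesion-challenge convention; 6 and 26 are
available).  Before any metric is computed, components smaller than 3 voxels
are re-classified as background -- in the ground truth and in the
predictions alike.

Voxel-wise metrics: Dice similarity coefficient (DSC), voxel-wise positive
predictive value (PPV) and absolute volume difference (AVD), computed on
the pooled binary masks.  Lesion-wise metrics: a ground-truth lesion counts
as detected if at least one of its voxels is covered by any predicted
component (LTPR, and per-type LTPR_WM / LTPR_CL); a predicted component
overlapping no ground-truth lesion is a false positive (LFPR).  Undefined
metrics (empty denominators) are reported as NaN and excluded from cohort
aggregates, never silently set to 0 or 1.

Cohort-level analysis: median/IQR aggregation, Pearson correlation of
manual vs automatic total lesion volume, size-stratified detection rates,
and paired Wilcoxon signed-rank comparisons with Bonferroni correction.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .volumes_io import CL, WML, LabelVolume

#: default minimum lesion size in voxels.
MIN_LESION_VOXELS = 3

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}

_LABEL_TYPE = {WML: "WML", CL: "CL"}


def _structure(connectivity: int) -> np.ndarray:
    try:
        return _STRUCTURES[connectivity]
    except KeyError:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}, got {connectivity}")


@dataclasses.dataclass
class LesionComponent:
    """One connected lesion: its voxels, size, physical volume and type."""

    voxels: np.ndarray  # (n, 3) int index triples
    size: int
    volume_ul: float
    lesion_type: str  # "WML" | "CL" | "untyped"

    def voxel_set(self) -> set:
        return set(map(tuple, self.voxels))


def connected_components(grid: np.ndarray, connectivity: int = 18,
                         spacing: Sequence[float] = (1.0, 1.0, 1.0),
                         typed: bool = False) -> List[LesionComponent]:
    """Partition foreground voxels into maximal connected components.

    With ``typed=True`` the grid is read as {0, 1 = WML, 2 = CL} and
    components are extracted per label, so a touching WML and CL remain
    distinct components of their own types.  Otherwise any non-zero voxel is
    foreground and components are untyped.
    """
    struct = _structure(connectivity)
    vox_ul = float(np.prod(spacing))
    comps: List[LesionComponent] = []
    if typed:
        groups = [(grid == lab, _LABEL_TYPE[lab]) for lab in (WML, CL)]
    else:
        groups = [(grid != 0, "untyped")]
    for mask, tname in groups:
        lab, n = ndimage.label(mask, structure=struct)
        for obj_idx, sl in enumerate(ndimage.find_objects(lab), start=1):
            if sl is None:
                continue
            local = np.argwhere(lab[sl] == obj_idx)
            local += [s.start for s in sl]
            comps.append(LesionComponent(voxels=local, size=len(local),
                                         volume_ul=len(local) * vox_ul,
                                         lesion_type=tname))
    return comps


def apply_min_size(grid: np.ndarray, min_voxels: int = MIN_LESION_VOXELS,
                   connectivity: int = 18) -> np.ndarray:
    """Re-classify components smaller than ``min_voxels`` as background.

    Applied identically to ground truth and predictions before all metrics.
    Typed grids are filtered per label.  Idempotent; ``min_voxels=1`` is the
    identity.
    """
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    struct = _structure(connectivity)
    out = np.array(grid, copy=True)
    for value in np.unique(out):
        if value == 0:
            continue
        mask = out == value
        lab, n = ndimage.label(mask, structure=struct)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())
        small = np.flatnonzero(sizes < min_voxels)
        small = small[small != 0]
        if len(small):
            out[np.isin(lab, small)] = 0
    return out


def voxel_metrics(pred: np.ndarray, gt: np.ndarray) -> Dict[str, float]:
    """DSC, PPV and AVD on binary grids (assumed min-size filtered).

    DSC = 2|P&G| / (|P|+|G|); PPV = |P&G| / |P|; AVD = ||P|-|G|| / |G|.
    Empty G leaves DSC and AVD undefined (NaN); empty P leaves PPV undefined.
    """
    p = np.asarray(pred) != 0
    g = np.asarray(gt) != 0
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    np_, ng = int(p.sum()), int(g.sum())
    inter = int((p & g).sum())
    dsc = 2.0 * inter / (np_ + ng) if ng > 0 else math.nan
    ppv = inter / np_ if np_ > 0 else math.nan
    avd = abs(np_ - ng) / ng if ng > 0 else math.nan
    return {"dsc": dsc, "ppv": ppv, "avd": avd}


def _overlap_flags(gt_components: Sequence[LesionComponent],
                   pred_components: Sequence[LesionComponent]):
    pred_voxels = set()
    for c in pred_components:
        pred_voxels.update(map(tuple, c.voxels))
    gt_voxels = set()
    for c in gt_components:
        gt_voxels.update(map(tuple, c.voxels))
    detected = [any(tuple(v) in pred_voxels for v in c.voxels) for c in gt_components]
    false_pos = [not any(tuple(v) in gt_voxels for v in c.voxels) for c in pred_components]
    return detected, false_pos


def lesion_detection(gt_components: Sequence[LesionComponent],
                     pred_components: Sequence[LesionComponent]) -> Dict[str, float]:
    """Lesion-wise detection rates.

    A ground-truth component is detected if any of its voxels is covered by
    any predicted component (a prediction bridging a WML and a CL detects
    both).  A predicted component overlapping no ground-truth component is a
    false positive.  Missing denominators yield NaN.
    """
    detected, false_pos = _overlap_flags(gt_components, pred_components)

    def _rate(flags):
        return sum(flags) / len(flags) if flags else math.nan

    by_type = {"WML": [], "CL": []}
    for comp, det in zip(gt_components, detected):
        if comp.lesion_type in by_type:
            by_type[comp.lesion_type].append(det)
    return {
        "ltpr": _rate(detected),
        "ltpr_wm": _rate(by_type["WML"]),
        "ltpr_cl": _rate(by_type["CL"]),
        "lfpr": _rate(false_pos),
        "n_gt": len(gt_components),
        "n_pred": len(pred_components),
    }


def size_stratified_detection(gt_components: Sequence[LesionComponent],
                              pred_components: Sequence[LesionComponent],
                              bins: Sequence[Tuple[float, Optional[float]]],
                              ) -> pd.DataFrame:
    """Detection rate per lesion-size range.

    ``bins`` are half-open [lo, hi) voxel-count ranges (hi None = unbounded);
    they must be sorted, non-overlapping and contiguous.  Returns one row per
    bin with the ground-truth count and the detection rate (NaN if the bin is
    empty).
    """
    norm = [(float(lo), math.inf if hi is None else float(hi)) for lo, hi in bins]
    for (lo, hi), (lo2, _hi2) in zip(norm, norm[1:]):
        if hi != lo2:
            raise ValueError(f"bins must be contiguous and non-overlapping, got {bins}")
    detected, _ = _overlap_flags(gt_components, pred_components)
    rows = []
    for lo, hi in norm:
        flags = [det for comp, det in zip(gt_components, detected)
                 if lo <= comp.size < hi]
        rows.append(dict(lo=lo, hi=hi, n_gt=len(flags),
                         detection_rate=(sum(flags) / len(flags)) if flags else math.nan))
    return pd.DataFrame(rows)


def volume_correlation(manual_volumes: Sequence[float],
                       automatic_volumes: Sequence[float]) -> Dict[str, float]:
    """Pearson r and least-squares line between paired per-subject volumes."""
    m = np.asarray(manual_volumes, dtype=float)
    a = np.asarray(automatic_volumes, dtype=float)
    if m.shape != a.shape or m.ndim != 1 or len(m) < 3:
        raise ValueError("need paired 1-D volume vectors of length >= 3")
    if m.std() == 0 or a.std() == 0:
        raise ValueError("zero variance in a volume vector; correlation undefined")
    r, p = stats.pearsonr(m, a)
    fit = stats.linregress(m, a)
    return {"r": float(r), "p": float(p), "slope": float(fit.slope),
            "intercept": float(fit.intercept)}


def compare_methods(per_subject_metric_a: Sequence[float],
                    per_subject_metric_b: Sequence[float],
                    n_comparisons: int = 1) -> Dict[str, float]:
    """Two-sided paired Wilcoxon signed-rank test with Bonferroni correction.

    Zero differences are dropped (Wilcoxon convention); if every pair is
    tied the test is undefined and flagged.  ``significant`` is evaluated at
    0.05 on the Bonferroni-adjusted p-value.
    """
    a = np.asarray(per_subject_metric_a, dtype=float)
    b = np.asarray(per_subject_metric_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 6:
        raise ValueError("need paired samples of equal length >= 6")
    diffs = a - b
    if np.all(diffs == 0):
        return {"statistic": math.nan, "p_raw": math.nan, "p_adjusted": math.nan,
                "significant": False, "undefined": True}
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
    p_adj = min(1.0, float(res.pvalue) * n_comparisons)
    return {"statistic": float(res.statistic), "p_raw": float(res.pvalue),
            "p_adjusted": p_adj, "significant": bool(p_adj < 0.05),
            "undefined": False}


def spherical_volume_mm3(diameter_mm: float) -> float:
    """Volume of a sphere of the given diameter (e.g. the clinical 3-mm
    minimum WM-lesion diameter corresponds to about 14 mm^3)."""
    r = diameter_mm / 2.0
    return 4.0 / 3.0 * math.pi * r ** 3


def min_lesion_volume_ul(spacing: Sequence[float],
                         min_voxels: int = MIN_LESION_VOXELS) -> float:
    """Physical volume of the minimum countable lesion at a given spacing."""
    return float(min_voxels * np.prod(spacing))


def evaluate_case(pred: LabelVolume, gt: LabelVolume, min_size: int = MIN_LESION_VOXELS,
                  connectivity: int = 18) -> Dict[str, float]:
    """Full per-subject metric row for one (prediction, ground truth) pair.

    Both masks are min-size filtered first; voxel metrics are computed on the
    pooled binary masks, lesion metrics on typed ground-truth components vs
    untyped predicted components.  Volumes are in microlitres.
    """
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    spacing = gt.spacing
    gt_f = apply_min_size(gt.labels, min_size, connectivity)
    pred_f = apply_min_size(pred.labels, min_size, connectivity)
    gt_comps = connected_components(gt_f, connectivity, spacing, typed=True)
    pred_comps = connected_components(pred_f, connectivity, spacing, typed=False)
    row: Dict[str, float] = {}
    row.update(voxel_metrics(pred_f != 0, gt_f != 0))
    row.update(lesion_detection(gt_comps, pred_comps))
    vox_ul = float(np.prod(spacing))
    row["manual_volume_ul"] = float((gt_f != 0).sum()) * vox_ul
    row["auto_volume_ul"] = float((pred_f != 0).sum()) * vox_ul
    return row


_METRIC_COLS = ["dsc", "avd", "ppv", "ltpr", "ltpr_wm", "ltpr_cl", "lfpr"]


@dataclasses.dataclass
class MetricsReport:
    """Per-subject metric table plus cohort aggregates.

    ``per_subject`` has one row per subject (indexed by subject id) with the
    seven headline metrics and the paired manual/automatic volumes.
    """

    per_subject: pd.DataFrame

    @classmethod
    def from_rows(cls, rows: Dict[str, Dict[str, float]]) -> "MetricsReport":
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index.name = "subject_id"
        return cls(per_subject=df)

    def cohort_summary(self) -> pd.DataFrame:
        """Median and IQR per metric, NaN rows excluded per metric."""
        recs = []
        for col in _METRIC_COLS:
            if col not in self.per_subject:
                continue
            vals = self.per_subject[col].dropna()
            if len(vals) == 0:
                recs.append(dict(metric=col, median=math.nan, iqr=math.nan, n=0))
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            recs.append(dict(metric=col, median=float(med), iqr=float(q3 - q1), n=len(vals)))
        return pd.DataFrame(recs).set_index("metric")

    def volume_pairs(self) -> Tuple[np.ndarray, np.ndarray]:
        return (self.per_subject["manual_volume_ul"].to_numpy(),
                self.per_subject["auto_volume_ul"].to_numpy())
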
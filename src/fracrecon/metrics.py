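"""Reconstruction quality metrics: bone IoU and ASSD, plus cohort reports.

Convention from the evaluation protocol: the auxiliary (fracture-gap) class
is merged into the background in BOTH prediction and ground truth before
computing the bone-class metrics, so a three-class network is scored on the
same footing as a two-class one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .volumes import BinaryMask, EmptyMaskError, LabelVolume

TYPE_ORDER = ("intact", "nondisplaced", "displaced")


def bone_mask_from_labels(labels: np.ndarray) -> np.ndarray:
    """Binary bone mask with auxiliary voxels merged into background."""
    return np.asarray(labels) == LabelVolume.BONE


def iou_arrays(pred: np.ndarray, gt: np.ndarray) -> float:
    """Bone-class IoU of two label arrays (any matching shape)."""
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    a = bone_mask_from_labels(pred)
    b = bone_mask_from_labels(gt)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def iou(pred: LabelVolume, gt: LabelVolume) -> float:
    """Intersection-over-union on the bone class (aux merged to background).

    Defined as 1.0 when both bone masks are empty.
    """
    return iou_arrays(pred.data, gt.data)


def extract_surface(mask: BinaryMask) -> np.ndarray:
    """Surface voxel coordinates in mm, (n, 3).

    A surface voxel has at least one face neighbour outside the mask; the
    grid boundary counts as outside.
    """
    if not mask.data.any():
        raise EmptyMaskError("surface of an empty mask is undefined")
    face = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(mask.data, structure=face, border_value=0)
    surface = mask.data & ~interior
    coords = np.argwhere(surface).astype(float)
    return coords * np.asarray(mask.spacing)


def _surface_voxels(data: np.ndarray) -> np.ndarray:
    face = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(data, structure=face, border_value=0)
    return data & ~interior


def assd(pred: BinaryMask, gt: BinaryMask) -> float:
    """Average symmetric surface distance in mm.

    Directed distances are taken between surface voxel centres via Euclidean
    distance transforms; the symmetric value is the sum of both directed
    distance totals divided by the total surface voxel count.
    """
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    if not pred.data.any() or not gt.data.any():
        raise EmptyMaskError("ASSD is undefined for empty masks")
    spacing = pred.spacing
    sa = _surface_voxels(pred.data)
    sb = _surface_voxels(gt.data)
    dist_to_b = ndimage.distance_transform_edt(~sb, sampling=spacing)
    dist_to_a = ndimage.distance_transform_edt(~sa, sampling=spacing)
    total = dist_to_b[sa].sum() + dist_to_a[sb].sum()
    return float(total / (sa.sum() + sb.sum()))


def assd_bruteforce(pred: BinaryMask, gt: BinaryMask) -> float:
    """Exhaustive all-pairs ASSD; O(|Sa|·|Sb|) oracle for small masks."""
    sa = np.argwhere(_surface_voxels(pred.data)) * np.asarray(pred.spacing)
    sb = np.argwhere(_surface_voxels(gt.data)) * np.asarray(gt.spacing)
    if sa.size == 0 or sb.size == 0:
        raise EmptyMaskError("ASSD is undefined for empty masks")
    d = np.sqrt(((sa[:, None, :] - sb[None, :, :]) ** 2).sum(axis=2))
    return float((d.min(axis=1).sum() + d.min(axis=0).sum()) / (len(sa) + len(sb)))


@dataclass
class EvalResult:
    """Per-sample metrics plus per-type and overall aggregates."""

    per_sample: pd.DataFrame   # columns: sample, type_tag, iou, assd
    summary: pd.DataFrame      # rows: Overall + types; mean/sd per metric

    def to_csv(self, path) -> None:
        self.summary.to_csv(path, index=False)


def evaluate_cohort(
    preds: list[LabelVolume],
    gts: list[LabelVolume],
    type_tags: list[str],
    sample_ids: list[str] | None = None,
) -> EvalResult:
    """Bone IoU and ASSD per sample, aggregated per sample type.

    Output rows follow the fixed order Overall, intact, nondisplaced,
    displaced (types absent from the cohort are omitted).
    """
    if not (len(preds) == len(gts) == len(type_tags)):
        raise ValueError("preds, gts and type_tags must be aligned")
    ids = sample_ids or [f"sample_{i:03d}" for i in range(len(preds))]
    rows = []
    for sid, pred, gt, tag in zip(ids, preds, gts, type_tags):
        bone_p = BinaryMask(bone_mask_from_labels(pred.data), pred.spacing)
        bone_g = BinaryMask(bone_mask_from_labels(gt.data), gt.spacing)
        rows.append(
            {
                "sample": sid,
                "type_tag": tag,
                "iou": iou(pred, gt),
                "assd": assd(bone_p, bone_g),
            }
        )
    per_sample = pd.DataFrame(rows)
    summary_rows = []

    def agg(name: str, frame: pd.DataFrame) -> None:
        summary_rows.append(
            {
                "sample_type": name,
                "n": len(frame),
                "miou": frame["iou"].mean(),
                "miou_sd": frame["iou"].std(ddof=0),
                "massd": frame["assd"].mean(),
                "massd_sd": frame["assd"].std(ddof=0),
            }
        )

    agg("Overall", per_sample)
    for tag in TYPE_ORDER:
        sub = per_sample[per_sample["type_tag"] == tag]
        if len(sub):
            agg(tag, sub)
    return EvalResult(per_sample, pd.DataFrame(summary_rows))


def paired_ttest(scores_a, scores_b) -> tuple[float, float]:
    """Two-sided paired t-test on per-fold metric values.

    Identical lists give (0.0, 1.0).  A constant nonzero difference has zero
    variance; the t statistic is ±inf and is flagged with a warning rather
    than raising.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length 1D score lists with >= 2 entries")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0
        warnings.warn(
            "paired differences have zero variance; t statistic is infinite",
            RuntimeWarning,
            stacklevel=2,
        )
        return float(np.sign(d.mean()) * np.inf), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)
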
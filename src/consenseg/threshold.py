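"""SUVmax-percentage threshold segmentation of PET lesions.

A lesion is segmented by keeping all voxels whose SUV is at least ``t``
percent of the lesion's maximum SUV, then retaining only the connected
component (26-neighborhood by default) containing the SUVmax voxel. Sweeping
``t`` from 0% to 100% in 0.5-point steps and scoring each segmentation
against a reference (typically the multi-observer consensus) by Dice yields
a Dice-vs-threshold curve per lesion; the threshold maximizing the mean
Dice over lesions is the operating point.

Conventions: the comparison uses ``>=`` (voxels exactly at the cutoff are
kept, so t=100% retains the max voxel); component growth is unclipped by
default, which deliberately reproduces the known failure mode of leaking
into nearby physiological hot spots (the pituitary gland under SSTR
tracers) — ``clip_to_roi=True`` is the safeguard; argmax ties over
thresholds break toward the smaller (more inclusive, hence conservative
for radiotherapy) threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import BinaryMask, GridMismatchError, SUVVolume
from .metrics import SegmentationMetrics, dice, hausdorff, mask_volume

__all__ = [
    "LesionROI",
    "lesion_suvmax",
    "threshold_segment",
    "ThresholdSweep",
    "ThresholdSweepResult",
    "sweep_thresholds",
    "evaluate_on_validation",
    "roi_from_masks",
]

_CONN_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class LesionROI:
    """Search region for SUVmax (and optional growth clip) of one lesion."""

    lesion_id: str
    region: BinaryMask

    def __post_init__(self):
        if self.region.is_empty():
            raise ValueError(f"ROI for lesion {self.lesion_id!r} is empty")


def roi_from_masks(masks, lesion_id: str = "lesion", pad: int = 3) -> LesionROI:
    """Default ROI: padded bounding box of the union of available masks.

    Used when no explicit lesion region is supplied; ``pad`` is in voxels.
    """
    masks = list(masks)
    union = np.zeros(masks[0].grid.shape, dtype=bool)
    for m in masks:
        union |= m.values
    if not union.any():
        raise ValueError("cannot derive an ROI from all-empty masks")
    idx = np.argwhere(union)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, union.shape)
    box = np.zeros_like(union)
    box[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = True
    return LesionROI(lesion_id=lesion_id, region=BinaryMask(masks[0].grid, box))


def lesion_suvmax(pet: SUVVolume, roi: LesionROI):
    """Maximum SUV within the ROI and the voxel index attaining it.

    Ties break toward the lexicographically smallest index.
    """
    bad = pet.grid.mismatch(roi.region.grid)
    if bad is not None:
        raise GridMismatchError(f"PET and ROI are on different grids (field '{bad}')")
    inside = roi.region.values
    vals = pet.values[inside]
    suv = float(vals.max())
    # argwhere is row-major sorted, so the first hit is the lexicographic min
    argmax = tuple(int(v) for v in np.argwhere(inside & (pet.values == suv))[0])
    return suv, argmax


def threshold_segment(
    pet: SUVVolume,
    roi: LesionROI,
    t_percent: float,
    clip_to_roi: bool = False,
    connectivity: int = 26,
) -> BinaryMask:
    """Segment one lesion at ``t_percent`` % of its SUVmax.

    The suprathreshold set ``{SUV >= (t/100)·SUVmax}`` (optionally
    intersected with the ROI) is reduced to the connected component
    containing the SUVmax voxel.
    """
    if not 0 <= t_percent <= 100:
        raise ValueError(f"t_percent must lie in [0, 100], got {t_percent}")
    if connectivity not in _CONN_STRUCTS:
        raise ValueError("connectivity must be 6 or 26")
    suv, seed = lesion_suvmax(pet, roi)
    if suv == 0:
        raise ValueError("lesion SUVmax is 0; threshold segmentation is undefined")
    supra = pet.values >= (t_percent / 100.0) * suv
    if clip_to_roi:
        supra = supra & roi.region.values
    labels, _ = ndimage.label(supra, structure=_CONN_STRUCTS[connectivity])
    return BinaryMask(pet.grid, labels == labels[seed])


@dataclass
class ThresholdSweepResult:
    """Dice-vs-threshold curves and the Dice-maximizing operating point."""

    thresholds: np.ndarray  # percentages, strictly increasing
    dice_matrix: pd.DataFrame  # rows: lesion_id, columns: thresholds
    mean_dice: np.ndarray  # per-threshold unweighted mean over lesions
    best_threshold: float
    best_mean_dice: float
    per_lesion_best: pd.Series  # per-lesion argmax threshold

    def summary(self) -> str:
        lines = [
            "SUVmax-percentage threshold sweep",
            f"  lesions        : {len(self.dice_matrix)}",
            f"  thresholds     : {self.thresholds[0]:g}% .. {self.thresholds[-1]:g}% "
            f"step {self.thresholds[1] - self.thresholds[0]:g}",
            f"  best threshold : {self.best_threshold:g}% of SUVmax",
            f"  mean Dice there: {self.best_mean_dice:.4f}",
            "  per-lesion optima (% of SUVmax):",
        ]
        for lid, t in self.per_lesion_best.items():
            d = self.dice_matrix.loc[lid].max()
            lines.append(f"    {lid:<12} t*={t:6.1f}%  dice={d:.4f}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long form: lesion_id, threshold_pct, dice."""
        df = self.dice_matrix.copy()
        df.index.name = "lesion_id"
        long = df.reset_index().melt(
            id_vars="lesion_id", var_name="threshold_pct", value_name="dice"
        )
        long["threshold_pct"] = long["threshold_pct"].astype(float)
        return long.sort_values(["lesion_id", "threshold_pct"]).reset_index(drop=True)

    def plot(self, ax=None):
        """Per-lesion Dice-vs-threshold curves with the per-lesion optima marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4.5))
        for lid, row in self.dice_matrix.iterrows():
            ax.plot(self.thresholds, row.values, lw=0.9, alpha=0.7, label=str(lid))
            t_best = self.per_lesion_best[lid]
            ax.plot(t_best, row.max(), "ro", ms=4)
        ax.axvline(self.best_threshold, color="k", ls="--", lw=0.8)
        ax.set_xlabel("threshold (% of SUVmax)")
        ax.set_ylabel("Dice vs consensus")
        ax.set_title(
            f"best threshold {self.best_threshold:g}% "
            f"(mean Dice {self.best_mean_dice:.3f})"
        )
        return ax


class ThresholdSweep:
    """Threshold-selection model over a battery of lesions.

    Parameters
    ----------
    lesions
        List of ``(lesion_id, pet, roi, reference)`` where ``reference`` is
        the non-empty consensus mask the segmentations are scored against.
    t_start, t_stop, t_step
        Sweep grid in percent of SUVmax; defaults cover 0–100 in 0.5-point
        steps (201 thresholds).
    """

    def __init__(
        self,
        lesions,
        t_start: float = 0.0,
        t_stop: float = 100.0,
        t_step: float = 0.5,
        clip_to_roi: bool = False,
        connectivity: int = 26,
    ):
        lesions = list(lesions)
        if not lesions:
            raise ValueError("need at least one lesion")
        for lid, pet, roi, ref in lesions:
            if ref.is_empty():
                raise ValueError(f"reference mask for lesion {lid!r} is empty")
        if not (0 <= t_start < t_stop <= 100) or t_step <= 0:
            raise ValueError("need 0 <= t_start < t_stop <= 100 and t_step > 0")
        self.lesions = lesions
        n_steps = int(round((t_stop - t_start) / t_step))
        if abs(t_start + n_steps * t_step - t_stop) > 1e-9:
            raise ValueError("t_step must divide the sweep range")
        self.thresholds = t_start + t_step * np.arange(n_steps + 1)
        self.clip_to_roi = clip_to_roi
        self.connectivity = connectivity

    def fit(self) -> ThresholdSweepResult:
        """Run the sweep and pick the mean-Dice-maximizing threshold.

        Empty segmentations against a non-empty reference score Dice 0 so
        the mean over lesions stays defined across the whole sweep; argmax
        ties break toward the smaller threshold.
        """
        rows = {}
        for lid, pet, roi, ref in self.lesions:
            dices = np.empty(len(self.thresholds))
            for k, t in enumerate(self.thresholds):
                seg = threshold_segment(
                    pet, roi, float(t), clip_to_roi=self.clip_to_roi,
                    connectivity=self.connectivity,
                )
                dices[k] = 0.0 if seg.is_empty() else dice(seg, ref)
            rows[lid] = dices
        dice_matrix = pd.DataFrame.from_dict(rows, orient="index", columns=self.thresholds)
        mean_dice = dice_matrix.to_numpy().mean(axis=0)
        best_k = int(np.argmax(mean_dice))  # argmax returns the first (smallest t) tie
        per_lesion_best = pd.Series(
            self.thresholds[dice_matrix.to_numpy().argmax(axis=1)],
            index=dice_matrix.index,
            name="best_threshold_pct",
        )
        return ThresholdSweepResult(
            thresholds=self.thresholds,
            dice_matrix=dice_matrix,
            mean_dice=mean_dice,
            best_threshold=float(self.thresholds[best_k]),
            best_mean_dice=float(mean_dice[best_k]),
            per_lesion_best=per_lesion_best,
        )


def sweep_thresholds(
    pets_and_rois,
    references,
    t_start: float = 0.0,
    t_stop: float = 100.0,
    t_step: float = 0.5,
    clip_to_roi: bool = False,
    connectivity: int = 26,
) -> ThresholdSweepResult:
    """Functional wrapper: align per-lesion (id, pet, roi) with references."""
    pets_and_rois = list(pets_and_rois)
    references = list(references)
    if len(pets_and_rois) != len(references):
        raise ValueError(
            f"{len(pets_and_rois)} lesions but {len(references)} reference masks"
        )
    lesions = [
        (lid, pet, roi, ref) for (lid, pet, roi), ref in zip(pets_and_rois, references)
    ]
    return ThresholdSweep(
        lesions,
        t_start=t_start,
        t_stop=t_stop,
        t_step=t_step,
        clip_to_roi=clip_to_roi,
        connectivity=connectivity,
    ).fit()


def evaluate_on_validation(
    threshold: float,
    pets_and_rois,
    reference_masks,
    clip_to_roi: bool = False,
    connectivity: int = 26,
) -> pd.DataFrame:
    """Apply a fixed threshold to an independent lesion set and score it.

    No re-optimization happens here: the threshold tuned on one cohort is
    applied as-is. Returns one row per lesion with dice, hausdorff_mm (NaN
    when the segmentation is empty), and both volumes in cm^3.
    """
    if not 0 <= threshold <= 100:
        raise ValueError(f"threshold must lie in [0, 100], got {threshold}")
    pets_and_rois = list(pets_and_rois)
    reference_masks = list(reference_masks)
    if len(pets_and_rois) != len(reference_masks):
        raise ValueError("lesion list and reference list have different lengths")
    rows = []
    for (lid, pet, roi), ref in zip(pets_and_rois, reference_masks):
        seg = threshold_segment(
            pet, roi, threshold, clip_to_roi=clip_to_roi, connectivity=connectivity
        )
        if seg.is_empty() or ref.is_empty():
            m = SegmentationMetrics(
                dice=0.0 if (seg.is_empty() != ref.is_empty()) else 1.0,
                hausdorff_mm=float("nan"),
                volume_a_cm3=mask_volume(seg),
                volume_b_cm3=mask_volume(ref),
            )
        else:
            m = SegmentationMetrics(
                dice=dice(seg, ref),
                hausdorff_mm=hausdorff(seg, ref),
                volume_a_cm3=mask_volume(seg),
                volume_b_cm3=mask_volume(ref),
            )
        rows.append(
            {
                "lesion_id": lid,
                "threshold_pct": threshold,
                "dice": m.dice,
                "hausdorff_mm": m.hausdorff_mm,
                "volume_threshold_cm3": m.volume_a_cm3,
                "volume_reference_cm3": m.volume_b_cm3,
            }
        )
    return pd.DataFrame(rows)
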
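"""Segmentation agreement metrics.

Overlap between two cord masks is quantified with the Jaccard index
J = TP / (TP + FP + FN), convertible to the Dice coefficient through
D = 2J / (1 + J).  Edge accuracy is the symmetric Hausdorff distance
between the two edge curves, rasterised as integer (y, z) point sets and
measured in pixels (Euclidean); pixel distances convert to millimetres at
the acquisition resolution (0.6875 mm/px by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .image_model import DEFAULT_RESOLUTION_MM, PathCurve, SegmentationMask

__all__ = ["OverlapCounts", "AgreementReport", "overlap_counts", "jaccard",
           "dice_from_jaccard", "hausdorff", "px_to_mm", "majority_vote",
           "agreement_report"]


@dataclass(frozen=True)
class OverlapCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def jaccard(self) -> float:
        denom = self.tp + self.fp + self.fn
        if denom == 0:
            raise ValueError("Jaccard undefined: both masks are empty")
        return self.tp / denom


@dataclass
class AgreementReport:
    jaccard: float
    dice: float
    hausdorff_anterior_px: float | None = None
    hausdorff_posterior_px: float | None = None
    hausdorff_anterior_mm: float | None = None
    hausdorff_posterior_mm: float | None = None
    auto_pixels: int = 0
    ref_pixels: int = 0


def _crop_rows(data: np.ndarray, z_range: tuple[int, int] | None) -> np.ndarray:
    if z_range is None:
        return data
    z0, z1 = z_range
    return data[z0:z1 + 1]


def overlap_counts(auto: SegmentationMask, ref: SegmentationMask,
                   z_range: tuple[int, int] | None = None) -> OverlapCounts:
    if auto.shape != ref.shape:
        raise ValueError("masks are not aligned")
    a = _crop_rows(auto.data, z_range)
    r = _crop_rows(ref.data, z_range)
    return OverlapCounts(tp=int(np.sum(a & r)), fp=int(np.sum(a & ~r)),
                         fn=int(np.sum(~a & r)))


def jaccard(auto: SegmentationMask, ref: SegmentationMask,
            z_range: tuple[int, int] | None = None) -> float:
    """Jaccard overlap of two masks, optionally restricted to a row range
    (used to score cord masks within the canal extent only)."""
    return overlap_counts(auto, ref, z_range).jaccard


def dice_from_jaccard(j: float) -> float:
    """Dice coefficient from a Jaccard index: D = 2J / (1 + J)."""
    if not 0.0 <= j <= 1.0:
        raise ValueError(f"Jaccard index {j} outside [0, 1]")
    return 2.0 * j / (1.0 + j)


def hausdorff(a: PathCurve, b: PathCurve) -> float:
    """Symmetric Hausdorff distance (pixels) between two curves treated as
    (y, z) integer point sets."""
    pa = a.as_points().astype(np.float64)
    pb = b.as_points().astype(np.float64)
    if len(pa) == 0 or len(pb) == 0:
        raise ValueError("empty curve")
    d = cdist(pa, pb)
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


def px_to_mm(v: float, resolution_mm: float = DEFAULT_RESOLUTION_MM) -> float:
    """Convert a pixel measurement to millimetres."""
    if resolution_mm <= 0:
        raise ValueError("resolution must be positive")
    return v * resolution_mm


def majority_vote(masks: list[SegmentationMask]) -> SegmentationMask:
    """Per-pixel majority vote over >= 3 masks (the gold-standard builder)."""
    if len(masks) < 3:
        raise ValueError("majority vote needs at least 3 masks")
    shapes = {m.shape for m in masks}
    if len(shapes) > 1:
        raise ValueError("masks are not aligned")
    votes = np.sum([m.data for m in masks], axis=0)
    return SegmentationMask(votes > len(masks) / 2, label="majority_vote")


def agreement_report(auto: SegmentationMask, ref: SegmentationMask,
                     auto_edges: tuple[PathCurve, PathCurve] | None = None,
                     ref_edges: tuple[PathCurve, PathCurve] | None = None,
                     z_range: tuple[int, int] | None = None,
                     resolution_mm: float = DEFAULT_RESOLUTION_MM
                     ) -> AgreementReport:
    """Bundle mask overlap and (optionally) edge distances in one report."""
    j = jaccard(auto, ref, z_range)
    report = AgreementReport(jaccard=j, dice=dice_from_jaccard(j),
                             auto_pixels=auto.area, ref_pixels=ref.area)
    if auto_edges is not None and ref_edges is not None:
        pairs = zip(auto_edges, ref_edges)
        names = ("anterior", "posterior")
        for name, (ae, re) in zip(names, pairs):
            if z_range is not None:
                z0 = max(ae.z_sup, re.z_sup, z_range[0])
                z1 = min(ae.z_inf, re.z_inf, z_range[1])
                ae, re = ae.crop(z0, z1), re.crop(z0, z1)
            h = hausdorff(ae, re)
            setattr(report, f"hausdorff_{name}_px", h)
            setattr(report, f"hausdorff_{name}_mm", px_to_mm(h, resolution_mm))
    return report
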
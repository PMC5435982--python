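"""Vertebral-body / disk segmentation and anatomical labeling.

The vertebral column sits between the anterior column edge (B5) and the
PLL (B3).  Its pixels are bimodal: hypointense cortex, annulus and
ligament versus isointense bone marrow.  A threshold ``t_VB`` is placed at
the midpoint of the two histogram peaks.  A sixth DP path ``B6``
("truncated ALL") then hugs the anterior edges of the disks and cuts
prevertebral soft tissue off the column, after which region growing of the
supra-threshold pixels between B6 and B3 yields vertebral-body candidates.

Labeling is knowledge-based: the C2 body plus odontoid appears as one
region about 1.5x the height of a lower cervical body, so the topmost
sufficiently tall region followed by more than five valid regions, with a
centre-to-centre gap to the next of less than 70 px (50 mm), is C2; the
rest are labeled downward (C3, C4, ..., C7, T1, ...).  The canal extent is
approximated by the superior edge of C2 and the inferior edge of T1, the
latter extrapolated on z from the C3 and C7 centres (T1 height taken as
C7's) to avoid trusting detected regions beyond the reliable C3..C7 span.

Disks are the void regions left between the labeled vertebral bodies,
extracted regardless of signal intensity so that dehydrated (hypointense)
disks are still found.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks

from .dp_engine import BandBounds, FitnessField, find_best_path
from .image_model import GrayImage, PathCurve

logger = logging.getLogger(__name__)

__all__ = ["ColumnThreshold", "SpineRegion", "LabeledSpine", "compute_tvb",
           "fitness_f6", "detect_B6", "segment_vb_regions", "label_vertebrae",
           "segment_disks", "apply_manual_override", "LabelingError"]

VB_MIN_AREA = 150          # strict: a valid VB region has area > 150 px
DISK_MIN_AREA = 100        # strict: a valid disk region has area > 100 px
C2_GAP_PX = 70             # max C2-C3 centre gap (50 mm at 0.6875 mm/px)
C2_LARGE_FACTOR = 1.3      # "large region" = height >= 1.3 x median below
F6_POSTERIOR_PIXELS = 20
HIST_SMOOTH_WIDTH = 5
PEAK_PROMINENCE_FRAC = 0.05

_FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

#: vertebral level names from C2 downward
_LEVELS = [f"C{i}" for i in range(2, 8)] + [f"T{i}" for i in range(1, 13)]


class LabelingError(RuntimeError):
    """Raised when automatic vertebra labeling fails and no manual canal
    extent was supplied."""


@dataclass(frozen=True)
class ColumnThreshold:
    """Gray-level threshold separating cortex/annulus from marrow."""

    t_vb: int
    hypo_peak: int | None = None
    iso_peak: int | None = None
    used_fallback: bool = False


@dataclass
class SpineRegion:
    """One connected region of the vertebral column (VB or disk)."""

    mask: np.ndarray                # boolean, full image shape
    kind: str = "VB"                # "VB" | "disk"
    label: str | None = None
    area: int = 0
    z_center: float = 0.0
    y_center: float = 0.0
    z_min: int = 0
    z_max: int = 0
    y_min: int = 0
    y_max: int = 0

    @classmethod
    def from_mask(cls, mask: np.ndarray, kind: str = "VB") -> "SpineRegion":
        zs, ys = np.nonzero(mask)
        return cls(mask=mask, kind=kind, area=len(zs),
                   z_center=float(zs.mean()), y_center=float(ys.mean()),
                   z_min=int(zs.min()), z_max=int(zs.max()),
                   y_min=int(ys.min()), y_max=int(ys.max()))

    @property
    def height(self) -> int:
        return self.z_max - self.z_min + 1

    @property
    def depth(self) -> int:
        return self.y_max - self.y_min + 1


@dataclass
class LabeledSpine:
    """Labeled regions plus the approximated canal row extent."""

    regions: list[SpineRegion] = field(default_factory=list)
    disks: list[SpineRegion] = field(default_factory=list)
    canal_z_sup: int | None = None
    canal_z_inf: int | None = None
    B6: PathCurve | None = None
    labeling_failed: bool = False
    manual_override: bool = False
    c2_height_estimate: float | None = None

    @property
    def canal_extent(self) -> tuple[int, int]:
        if self.canal_z_sup is None or self.canal_z_inf is None:
            raise LabelingError(
                "no canal extent available: labeling failed and no manual "
                "override was supplied")
        return self.canal_z_sup, self.canal_z_inf

    def region(self, label: str) -> SpineRegion | None:
        for r in self.regions + self.disks:
            if r.label == label:
                return r
        return None


# ---------------------------------------------------------------------------
# t_VB
# ---------------------------------------------------------------------------

def _column_mask(shape: tuple[int, int], left: PathCurve, right: PathCurve
                 ) -> np.ndarray:
    """Boolean mask of pixels with left_z <= y <= right_z on each row."""
    nz, ny = shape
    mask = np.zeros(shape, dtype=bool)
    ys = np.arange(ny)
    for z in range(left.z_sup, left.z_inf + 1):
        mask[z] = (ys >= left.y_at(z)) & (ys <= right.y_at(z))
    return mask


def compute_tvb(img: GrayImage, B5: PathCurve, B3: PathCurve,
                fallback_threshold: int | None = None) -> ColumnThreshold:
    """Histogram the vertebral-column pixels (B5..B3), locate the two most
    prominent peaks, and place t_VB at their midpoint.

    If the histogram is not bimodal the EM-derived lower isointense
    threshold is used instead (``fallback_threshold``), with a warning.
    """
    mask = _column_mask(img.shape, B5, B3)
    values = img.pixels[mask]
    hist = np.bincount(values, minlength=256).astype(np.float64)
    kernel = np.ones(HIST_SMOOTH_WIDTH) / HIST_SMOOTH_WIDTH
    smooth = np.convolve(hist, kernel, mode="same")
    peaks, props = find_peaks(smooth, prominence=PEAK_PROMINENCE_FRAC * smooth.max())
    if len(peaks) >= 2:
        top2 = peaks[np.argsort(props["prominences"])[-2:]]
        lo, hi = int(min(top2)), int(max(top2))
        return ColumnThreshold(t_vb=int(round((lo + hi) / 2)),
                               hypo_peak=lo, iso_peak=hi)
    if fallback_threshold is None:
        fallback_threshold = 64
    logger.warning("column histogram not bimodal; falling back to t_VB = %d",
                   fallback_threshold)
    return ColumnThreshold(t_vb=int(fallback_threshold), used_fallback=True)


# ---------------------------------------------------------------------------
# f6 / B6
# ---------------------------------------------------------------------------

def fitness_f6(img: GrayImage, t: ColumnThreshold) -> FitnessField:
    """Dark-pixel term plus 65536 x the count of sub-threshold pixels among
    the 20 pixels posterior (pixels outside the image count as gray 0)."""
    from .structure_detection import _window_sum

    arr = img.astype_float()
    nz, ny = arr.shape
    v = (arr < t.t_vb).astype(np.float64)
    count = _window_sum(v, 1, F6_POSTERIOR_PIXELS)
    # out-of-image pixels are air-like (gray 0 < t_VB): add their count back
    ys = np.arange(ny)
    n_outside = np.maximum(ys + F6_POSTERIOR_PIXELS - (ny - 1), 0)
    count = count + np.minimum(n_outside, F6_POSTERIOR_PIXELS)[None, :]
    return FitnessField((256.0 - arr) ** 2 + 65536.0 * count, name="f6")


def detect_B6(img: GrayImage, B5: PathCurve, B3: PathCurve, t: ColumnThreshold
              ) -> PathCurve:
    f = fitness_f6(img, t)
    nz, _ = img.shape
    band = BandBounds(0, nz - 1, B5.values, B3.values - 1, img.shape)
    return find_best_path(f, band)


# ---------------------------------------------------------------------------
# region growing
# ---------------------------------------------------------------------------

def segment_vb_regions(img: GrayImage, B6: PathCurve, B3: PathCurve,
                       t: ColumnThreshold) -> list[SpineRegion]:
    """4-connected components of supra-threshold pixels between B6 and B3,
    keeping regions strictly larger than 150 px, sorted superior->inferior
    (ties by y-centre)."""
    column = _column_mask(img.shape, B6, B3)
    marrow = column & (img.pixels >= t.t_vb)
    labels, n = ndimage.label(marrow, structure=_FOUR_CONNECTED)
    regions = []
    for i in range(1, n + 1):
        mask = labels == i
        if mask.sum() > VB_MIN_AREA:
            regions.append(SpineRegion.from_mask(mask, kind="VB"))
    regions.sort(key=lambda r: (r.z_center, r.y_center))
    return regions


# ---------------------------------------------------------------------------
# labeling
# ---------------------------------------------------------------------------

def label_vertebrae(regions: list[SpineRegion], resolution_mm: float = 0.6875
                    ) -> LabeledSpine:
    """Identify C2 and label downward; approximate the canal row extent.

    Returns a :class:`LabeledSpine` with ``labeling_failed`` set when no
    region satisfies the C2 criteria (a manual canal extent must then be
    supplied via :func:`apply_manual_override`).
    """
    del resolution_mm  # all constants are kept in pixels at 0.6875 mm
    spine = LabeledSpine(regions=list(regions))
    c2_index = None
    for i, r in enumerate(regions):
        below = regions[i + 1:]
        if len(below) <= 5:
            break
        median_h = float(np.median([b.height for b in below]))
        gap = below[0].z_center - r.z_center
        if r.height >= C2_LARGE_FACTOR * median_h and gap < C2_GAP_PX:
            c2_index = i
            break
    if c2_index is None:
        logger.warning("vertebra labeling failed: no C2 candidate among "
                       "%d regions", len(regions))
        spine.labeling_failed = True
        return spine

    labeled = regions[c2_index:]
    for r, name in zip(labeled, _LEVELS):
        r.label = name

    c3, c7 = labeled[1], labeled[5]
    spacing = (c7.z_center - c3.z_center) / 4.0
    heights = [labeled[j].height for j in range(1, 6)]
    disk_gap = max(spacing - float(np.median(heights)), 0.0)
    t1_inferior = c7.z_center + c7.height / 2.0 + disk_gap + c7.height
    spine.canal_z_sup = int(labeled[0].z_min)
    spine.canal_z_inf = int(round(t1_inferior))
    spine.c2_height_estimate = 1.5 * c3.height
    return spine


# ---------------------------------------------------------------------------
# disks
# ---------------------------------------------------------------------------

def _format_disk_label(above: str, below: str) -> str:
    if above[0] == below[0]:
        return f"{above}-{below[1:]}"
    return f"{above}-{below}"


def segment_disks(img: GrayImage, B6: PathCurve, B3: PathCurve,
                  spine: LabeledSpine) -> list[SpineRegion]:
    """Void regions of the column after removing the labeled VB spans.

    Each labeled vertebral body is removed across the full column depth for
    the rows it occupies, so the remaining slabs between consecutive bodies
    are the disks (plus end plates / cortex rims).  Components larger than
    100 px lying between two labeled bodies are kept, regardless of signal
    intensity, and named after the adjacent bodies (e.g. ``C3-4``).
    """
    labeled = [r for r in spine.regions if r.label is not None]
    if not labeled:
        return []
    column = _column_mask(img.shape, B6, B3)
    void = column.copy()
    for r in labeled:
        void[r.z_min:r.z_max + 1, :] = False
    comp, n = ndimage.label(void, structure=_FOUR_CONNECTED)
    disks: list[SpineRegion] = []
    for i in range(1, n + 1):
        mask = comp == i
        if mask.sum() <= DISK_MIN_AREA:
            continue
        region = SpineRegion.from_mask(mask, kind="disk")
        above = [r for r in labeled if r.z_center < region.z_center]
        below = [r for r in labeled if r.z_center > region.z_center]
        if not above or not below:
            continue  # slab beyond the labeled span, not a disk
        a = max(above, key=lambda r: r.z_center)
        b = min(below, key=lambda r: r.z_center)
        region.label = _format_disk_label(a.label, b.label)  # type: ignore[arg-type]
        disks.append(region)
    disks.sort(key=lambda r: r.z_center)
    return disks


# ---------------------------------------------------------------------------
# manual override
# ---------------------------------------------------------------------------

def apply_manual_override(spine: LabeledSpine, z_sup: int, z_inf: int,
                          height: int | None = None) -> LabeledSpine:
    """Replace the canal extent with user-designated rows."""
    if z_sup >= z_inf:
        raise ValueError(f"override requires z_sup < z_inf, got ({z_sup}, {z_inf})")
    if z_sup < 0 or (height is not None and z_inf >= height):
        raise ValueError("override rows outside the image")
    new = replace(spine)
    new.canal_z_sup = int(z_sup)
    new.canal_z_inf = int(z_inf)
    new.manual_override = True
    return new
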
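"""Spinal cord edge detection with compound fitness functions (B7 / B8).

Signal inside the cord drifts with z (field inhomogeneity, saturation
bands), so a per-row reference is built first: ``c_z`` is the median gray
level of the hypo- and isointense pixels in an 11 x 31 window around the
refined cord line B2.  The anterior-edge fitness f7 then combines, for a
candidate edge pixel (y, z) whose outside neighbour is y-1 and whose inside
run is y..y+3:

* ``f7s`` similarity: + reward for the outside pixel differing from c_z,
  - penalty for the inside pixels differing from c_z
  (0.5 (I[y-1]-c)^2 - 3 (I[y]-c)^2 - (I[y+1]-c)^2 - (I[y+2]-c)^2 - (I[y+3]-c)^2);
* ``f7h`` heterogeneity among the inside run
  (-(I[y]-I[y+1])^2 - (I[y]-I[y+2])^2 - (I[y]-I[y+3])^2);
* ``f7c`` contrast across the edge (0.5 (I[y]-I[y-1])^2);
* ``f7p`` a -65536 step penalty when the path pixel is classified hyper-
  or air-intense -- large enough to dominate any single squared-difference
  term, so the path cannot run through CSF or background.

f8 (posterior edge) mirrors every constituent pixel about the path pixel.
Both DP runs are restricted to the canal row extent; f7 searches between
the PLL and B2, f8 between B2 and the LF.  The region between B7 and B8
(inclusive) is the cord mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dp_engine import BandBounds, FitnessField, find_best_path
from .image_model import GrayImage, PathCurve, SegmentationMask

logger = logging.getLogger(__name__)

__all__ = ["CordProfile", "CordSegmentation", "median_cord_profile",
           "fitness_f7", "fitness_f8", "detect_cord_edges"]

PROFILE_Y_HALFWIDTH = 5
PROFILE_Z_HALFWIDTH = 15
NONCORD_PENALTY = 65536.0


@dataclass
class CordProfile:
    """Median cord gray level per canal row."""

    z_sup: int
    z_inf: int
    c: np.ndarray  # length z_inf - z_sup + 1

    def c_at(self, z: int) -> float:
        return float(self.c[z - self.z_sup])

    def as_full_column(self, height: int) -> np.ndarray:
        """c_z extended over all image rows (edge rows hold the end values)."""
        full = np.empty(height, dtype=np.float64)
        full[: self.z_sup] = self.c[0]
        full[self.z_sup: self.z_inf + 1] = self.c
        full[self.z_inf + 1:] = self.c[-1]
        return full


@dataclass
class CordSegmentation:
    B7: PathCurve
    B8: PathCurve
    mask: SegmentationMask
    clamped_rows: list[int]


def median_cord_profile(img: GrayImage, B2: PathCurve, class_map: np.ndarray,
                        canal: tuple[int, int]) -> CordProfile:
    """For each canal row, the median gray of hypo/isointense pixels within
    B2 +- 5 columns and +- 15 rows (windows truncated at the canal and image
    borders).  Rows with an empty pool copy the nearest defined row."""
    z_sup, z_inf = canal
    arr = img.astype_float()
    pool_ok = (class_map == "hypo") | (class_map == "iso")
    nz, ny = img.shape
    c = np.full(z_inf - z_sup + 1, np.nan)
    for z in range(z_sup, z_inf + 1):
        zlo = max(z - PROFILE_Z_HALFWIDTH, z_sup, 0)
        zhi = min(z + PROFILE_Z_HALFWIDTH, z_inf, nz - 1)
        ylo = max(B2.y_at(z) - PROFILE_Y_HALFWIDTH, 0)
        yhi = min(B2.y_at(z) + PROFILE_Y_HALFWIDTH, ny - 1)
        window = arr[zlo:zhi + 1, ylo:yhi + 1]
        ok = pool_ok[zlo:zhi + 1, ylo:yhi + 1]
        if ok.any():
            c[z - z_sup] = np.median(window[ok])
    if np.isnan(c).any():
        if np.isnan(c).all():
            raise ValueError("no hypo/isointense pixels anywhere in the canal")
        logger.warning("empty median window on %d rows; copying nearest rows",
                       int(np.isnan(c).sum()))
        idx = np.arange(len(c))
        good = ~np.isnan(c)
        c = np.interp(idx, idx[good], c[good])  # nearest-ish fill via interp
    return CordProfile(z_sup=z_sup, z_inf=z_inf, c=c)


# ---------------------------------------------------------------------------
# fitness fields
# ---------------------------------------------------------------------------

def _shift_y(arr: np.ndarray, j: int) -> np.ndarray:
    """arr[:, y+j] with out-of-image pixels treated as gray level 0."""
    nz, ny = arr.shape
    out = np.zeros_like(arr)
    if j == 0:
        return arr.copy()
    if j > 0:
        out[:, :ny - j] = arr[:, j:]
    else:
        out[:, -j:] = arr[:, :ny + j]
    return out


def _compound_field(img: GrayImage, profile: CordProfile, class_map: np.ndarray,
                    sign: int, name: str) -> FitnessField:
    """Shared implementation of f7 (sign=+1: inside lies posterior) and
    f8 (sign=-1: the mirrored pixel ordering)."""
    arr = img.astype_float()
    c = profile.as_full_column(img.height_z)[:, None]
    I0 = arr
    out1 = _shift_y(arr, -sign)          # the outside pixel (y -+ 1)
    in1 = _shift_y(arr, sign)
    in2 = _shift_y(arr, 2 * sign)
    in3 = _shift_y(arr, 3 * sign)

    fs = (0.5 * (out1 - c) ** 2 - 3.0 * (I0 - c) ** 2
          - (in1 - c) ** 2 - (in2 - c) ** 2 - (in3 - c) ** 2)
    fh = -((I0 - in1) ** 2 + (I0 - in2) ** 2 + (I0 - in3) ** 2)
    fc = 0.5 * (I0 - out1) ** 2
    fp = np.where((class_map == "hyper") | (class_map == "air"),
                  -NONCORD_PENALTY, 0.0)
    return FitnessField(fs + fh + fc + fp, name=name)


def fitness_f7(img: GrayImage, profile: CordProfile, class_map: np.ndarray
               ) -> FitnessField:
    """Anterior-edge compound fitness (raw, before the non-negativity
    offset applied at detection time)."""
    return _compound_field(img, profile, class_map, sign=+1, name="f7")


def fitness_f8(img: GrayImage, profile: CordProfile, class_map: np.ndarray
               ) -> FitnessField:
    """Posterior-edge compound fitness: f7 with the constituent pixels in
    reverse order about the path pixel."""
    return _compound_field(img, profile, class_map, sign=-1, name="f8")


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def _offset_nonnegative(f: FitnessField, band: BandBounds) -> FitnessField:
    """Subtract the in-band minimum so the engine's positivity contract
    holds (mirrors the additive-constant device of the other fields)."""
    vals = f.values
    m = np.inf
    for r in range(band.n_rows):
        row = vals[band.z_sup + r]
        m = min(m, float(row[band.in_band(r)].min()))
    return FitnessField(vals - m, name=f.name)


def detect_cord_edges(img: GrayImage, f7: FitnessField, f8: FitnessField,
                      B2: PathCurve, B3: PathCurve, B4: PathCurve,
                      canal: tuple[int, int]) -> CordSegmentation:
    """DP on f7 within [B3+1, B2] and on f8 within [B2, B4-1], restricted
    to the canal rows; fill the mask between the resulting edges.

    Rows where the anterior edge lands posterior to the posterior edge
    (degenerate stenosis) are clamped to B2 with a warning.
    """
    z_sup, z_inf = canal
    nz, ny = img.shape
    if not 0 <= z_sup < z_inf <= nz - 1:
        raise ValueError(f"canal extent ({z_sup}, {z_inf}) outside the image")
    band7 = BandBounds(z_sup, z_inf, B3.values + 1, B2.values, img.shape)
    band8 = BandBounds(z_sup, z_inf, B2.values, B4.values - 1, img.shape)
    B7 = find_best_path(_offset_nonnegative(f7, band7), band7)
    B8 = find_best_path(_offset_nonnegative(f8, band8), band8)

    b7, b8 = B7.values.copy(), B8.values.copy()
    bad = b7 > b8
    clamped = [int(z) for z in np.nonzero(bad)[0] + z_sup]
    if clamped:
        logger.warning("anterior edge posterior to posterior edge on rows %s; "
                       "collapsing the crossed rows (degenerate stenosis)", clamped)
        # swap the crossed rows; min/max of 1-Lipschitz curves stays 1-Lipschitz
        lo, hi = np.minimum(b7, b8), np.maximum(b7, b8)
        B7 = PathCurve(z_sup, z_inf, lo)
        B8 = PathCurve(z_sup, z_inf, hi)

    mask = np.zeros(img.shape, dtype=bool)
    ys = np.arange(ny)
    for z in range(z_sup, z_inf + 1):
        mask[z] = (ys >= B7.y_at(z)) & (ys <= B8.y_at(z))
    return CordSegmentation(B7=B7, B8=B8,
                            mask=SegmentationMask(mask, label="spinal_cord"),
                            clamped_rows=clamped)
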
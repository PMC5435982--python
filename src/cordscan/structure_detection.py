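"""Detection of the cord line and the longitudinal ligaments (B1..B5).

Five DP detections run on the chosen midsagittal slice, each with its own
fitness field and band:

* ``B1`` -- coarse cord line: f1 counts isointense pixels among the five
  y-neighbours of each pixel; the cord is the longest isointense structure
  of sufficient depth, so the full-image best path lands on it.
* ``B2`` -- refined cord line: f2 rewards local intensity homogeneity over
  six consecutive pixel pairs, searched within +-40 columns of B1.
* ``B3``/``B4`` -- posterior longitudinal ligament / ligamentum flavum:
  f3 = f4 = (256 - I)^2 favours dark pixels, searched in 30-column bands
  immediately anterior / posterior to B2.
* ``B5`` -- anterior longitudinal ligament (anterior vertebral column
  edge): f5 adds the squared intensities of the 16 pixels posterior to the
  dark-pixel term, so the dark band backed by bright bone marrow wins over
  the air-filled trachea; searched 21..60 columns anterior to B3.

Pixels outside the image contribute gray level 0 (air-like) to intensity
windows and count as non-isointense in f1: the image borders are air under
this acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dp_engine import BandBounds, FitnessField, find_best_path
from .image_model import GrayImage, PathCurve
from .intensity_em import GmmFit

__all__ = ["StructureSet", "fitness_f1", "detect_B1", "fitness_f2", "detect_B2",
           "choose_candidate_slice", "fitness_f3f4", "detect_B3_B4",
           "fitness_f5", "detect_B5", "detect_structures"]

B2_BAND_HALFWIDTH = 40
CANAL_BAND_WIDTH = 30       # B3 / B4 search depth on either side of B2
B5_BAND_NEAR = 21           # B5 band: [B3 - 60, B3 - 21]
B5_BAND_FAR = 60
F5_MARROW_PIXELS = 16
STABILITY_WINDOW = 31       # moving-average window of the slice arbitration


@dataclass
class StructureSet:
    """The five detected curves on one slice, with their provenance."""

    B1: PathCurve
    B2: PathCurve
    B3: PathCurve
    B4: PathCurve
    B5: PathCurve
    chosen_slice: int = 1
    fit: GmmFit | None = None

    def __post_init__(self) -> None:
        b2, b3, b4, b5 = (self.B2.values, self.B3.values,
                          self.B4.values, self.B5.values)
        if not (np.all(b5 < b3) and np.all(b3 < b2) and np.all(b2 < b4)):
            raise ValueError("anterior->posterior ordering B5 < B3 < B2 < B4 violated")


# ---------------------------------------------------------------------------
# sliding-window helpers (zero-padded in y)
# ---------------------------------------------------------------------------

def _window_sum(arr: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """For each column y, the sum of arr[:, y+lo .. y+hi] with zero padding."""
    nz, ny = arr.shape
    width = hi - lo + 1
    padded = np.zeros((nz, ny + width), dtype=np.float64)
    # column y of the output starts at padded index y + lo + pad_left
    pad_left = -lo if lo < 0 else 0
    padded[:, pad_left:pad_left + ny] = arr
    c = np.cumsum(padded, axis=1)
    c = np.concatenate([np.zeros((nz, 1)), c], axis=1)
    start = np.arange(ny) + lo + pad_left
    return c[:, start + width] - c[:, start]


# ---------------------------------------------------------------------------
# f1 / B1: longest isointense structure
# ---------------------------------------------------------------------------

def fitness_f1(img: GrayImage, fit: GmmFit) -> FitnessField:
    """Count of isointense pixels among the 5 y-neighbours centred at (y, z)."""
    u = fit.iso_mask(img).astype(np.float64)
    return FitnessField(_window_sum(u, -2, 2), name="f1")


def detect_B1(img: GrayImage, fit: GmmFit) -> PathCurve:
    f = fitness_f1(img, fit)
    nz, ny = img.shape
    return find_best_path(f, BandBounds(0, nz - 1, 0, ny - 1, img.shape))


# ---------------------------------------------------------------------------
# f2 / B2: local homogeneity refinement
# ---------------------------------------------------------------------------

def fitness_f2(img: GrayImage) -> FitnessField:
    """Sum over the 6 consecutive pixel pairs spanning y-3..y+3 of
    65536 - (I[y+j+1] - I[y+j])^2; maximal (393216) where intensity is
    locally constant."""
    arr = img.astype_float()
    nz, ny = arr.shape
    ext = np.zeros((nz, ny + 6), dtype=np.float64)
    ext[:, 3:3 + ny] = arr
    terms = 65536.0 - np.diff(ext, axis=1) ** 2      # shape (nz, ny + 5)
    c = np.concatenate([np.zeros((nz, 1)), np.cumsum(terms, axis=1)], axis=1)
    vals = c[:, 6:] - c[:, :-6]                       # window of 6 terms
    return FitnessField(vals, name="f2")


def detect_B2(img: GrayImage, B1: PathCurve,
              halfwidth: int = B2_BAND_HALFWIDTH) -> PathCurve:
    f = fitness_f2(img)
    nz, ny = img.shape
    band = BandBounds(0, nz - 1, B1.values - halfwidth,
                      B1.values + halfwidth, img.shape)
    return find_best_path(f, band)


# ---------------------------------------------------------------------------
# candidate-slice arbitration
# ---------------------------------------------------------------------------

def _centered_moving_average(v: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with the window truncated near the ends."""
    n = len(v)
    half = window // 2
    c = np.concatenate([[0.0], np.cumsum(v)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half, n - 1)
    return (c[hi + 1] - c[lo]) / (hi - lo + 1)


def cord_stability_score(img: GrayImage, B2: PathCurve) -> float:
    """Total absolute deviation of the B2 signal from its 31-pixel moving
    average, summed over the lower two thirds of the image."""
    zs = np.arange(B2.z_sup, B2.z_inf + 1)
    v = img.astype_float()[zs, B2.values]
    ma = _centered_moving_average(v, STABILITY_WINDOW)
    start = int(np.ceil(img.height_z / 3))
    keep = zs >= start
    return float(np.abs(v - ma)[keep].sum())


def choose_candidate_slice(candidates: list[tuple[GrayImage, PathCurve]]) -> int:
    """Return the index (into ``candidates``) of the slice whose signal along
    B2 is the most stable; ties go to the first (lower slice index)."""
    if not candidates:
        raise ValueError("no candidate slices")
    if len(candidates) == 1:
        return 0
    scores = [cord_stability_score(img, b2) for img, b2 in candidates]
    return int(np.argmin(scores))


# ---------------------------------------------------------------------------
# f3 / f4 / f5: ligament detections
# ---------------------------------------------------------------------------

def fitness_f3f4(img: GrayImage) -> FitnessField:
    """Dark-pixel fitness (256 - I)^2, shared by the PLL and LF detections."""
    return FitnessField((256.0 - img.astype_float()) ** 2, name="f3f4")


def detect_B3_B4(img: GrayImage, B2: PathCurve,
                 width: int = CANAL_BAND_WIDTH) -> tuple[PathCurve, PathCurve]:
    f = fitness_f3f4(img)
    nz, ny = img.shape
    band3 = BandBounds(0, nz - 1, B2.values - width, B2.values - 1, img.shape)
    band4 = BandBounds(0, nz - 1, B2.values + 1, B2.values + width, img.shape)
    return find_best_path(f, band3), find_best_path(f, band4)


def fitness_f5(img: GrayImage) -> FitnessField:
    """Dark-pixel term plus the summed squared intensities of the 16 pixels
    posterior to it (the isointense bone marrow behind the ALL)."""
    arr = img.astype_float()
    marrow = _window_sum(arr ** 2, 1, F5_MARROW_PIXELS)
    return FitnessField((256.0 - arr) ** 2 + marrow, name="f5")


def detect_B5(img: GrayImage, B3: PathCurve, near: int = B5_BAND_NEAR,
              far: int = B5_BAND_FAR) -> PathCurve:
    f = fitness_f5(img)
    nz, ny = img.shape
    band = BandBounds(0, nz - 1, B3.values - far, B3.values - near, img.shape)
    return find_best_path(f, band)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def detect_structures(img: GrayImage, fit: GmmFit, chosen_slice: int = 1
                      ) -> StructureSet:
    """Run the five detections in dependency order on one classified slice."""
    B1 = detect_B1(img, fit)
    B2 = detect_B2(img, B1)
    B3, B4 = detect_B3_B4(img, B2)
    B5 = detect_B5(img, B3)
    return StructureSet(B1=B1, B2=B2, B3=B3, B4=B4, B5=B5,
                        chosen_slice=chosen_slice, fit=fit)
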
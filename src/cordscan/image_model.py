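"""Core raster types and I/O for sagittal cervical-spine MR series.

Conventions
-----------
A sagittal slice is stored as a 2D ``uint8``-valued array indexed
``pixels[z, y]`` where

* ``y`` increases anterior -> posterior (image column),
* ``z`` increases superior -> inferior (image row).

Internally everything is 0-based and half-open where ranges appear.
Formulas quoted from the clinical description of the method use 1-based
inclusive coordinates ``1 <= y, z <= 320``; :func:`to_internal_coords` and
:func:`to_one_based_coords` translate between the two at module boundaries.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

logger = logging.getLogger(__name__)

#: In-plane pixel size of the acquisition protocol this pipeline targets.
DEFAULT_RESOLUTION_MM = 0.6875

#: Conformant image side length; other sizes are accepted but logged.
CONFORMANT_SIZE = 320

_IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}
_DICOM_EXTENSIONS = {".dcm", ".ima"}


@dataclass
class GrayImage:
    """One sagittal slice with integer gray levels in [0, 255]."""

    pixels: np.ndarray
    resolution_mm: float = DEFAULT_RESOLUTION_MM

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected a 2D pixel grid, got shape {px.shape}")
        if px.size == 0:
            raise ValueError("empty image")
        if not np.issubdtype(px.dtype, np.integer):
            if not np.allclose(px, np.round(px)):
                raise ValueError("pixel values must be integers")
            px = np.round(px).astype(np.int64)
        if px.min() < 0 or px.max() > 255:
            raise ValueError("pixel values must lie in [0, 255]")
        if self.resolution_mm <= 0:
            raise ValueError("resolution_mm must be positive")
        self.pixels = px.astype(np.uint8)
        if self.shape != (CONFORMANT_SIZE, CONFORMANT_SIZE):
            logger.info("non-conformant image size %s (expected 320x320)", self.shape)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def height_z(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_y(self) -> int:
        return self.pixels.shape[1]

    def astype_float(self) -> np.ndarray:
        return self.pixels.astype(np.float64)


@dataclass
class SagittalSeries:
    """An ordered stack of sagittal slices ``I^1 ... I^K`` (default K = 13)."""

    slices: list[GrayImage]
    slice_thickness_mm: float = 3.0
    gap_mm: float = 0.33

    def __post_init__(self) -> None:
        if not self.slices:
            raise ValueError("a series needs at least one slice")
        shapes = {s.shape for s in self.slices}
        if len(shapes) > 1:
            raise ValueError(f"slices have mixed dimensions: {sorted(shapes)}")

    def __len__(self) -> int:
        return len(self.slices)

    def __getitem__(self, k: int) -> GrayImage:
        """1-based slice access, matching the acquisition numbering."""
        if not 1 <= k <= len(self.slices):
            raise IndexError(f"slice index {k} outside 1..{len(self.slices)}")
        return self.slices[k - 1]

    @property
    def resolution_mm(self) -> float:
        return self.slices[0].resolution_mm


@dataclass
class PathCurve:
    """A continuous DP path: one y-coordinate per row z in [z_sup, z_inf].

    Continuity means consecutive values differ by at most one pixel, i.e.
    the path can only move straight down or diagonally by one column.
    """

    z_sup: int
    z_inf: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.z_sup > self.z_inf:
            raise ValueError("z_sup must be <= z_inf")
        n = self.z_inf - self.z_sup + 1
        if self.values.shape != (n,):
            raise ValueError(f"expected {n} path values, got {self.values.shape}")
        if n > 1 and np.abs(np.diff(self.values)).max() > 1:
            raise ValueError("path violates |b_{z+1} - b_z| <= 1 continuity")
        if self.values.min() < 0:
            raise ValueError("path leaves the image on the left")

    def __len__(self) -> int:
        return len(self.values)

    def y_at(self, z: int) -> int:
        if not self.z_sup <= z <= self.z_inf:
            raise IndexError(f"row {z} outside [{self.z_sup}, {self.z_inf}]")
        return int(self.values[z - self.z_sup])

    def crop(self, z0: int, z1: int) -> "PathCurve":
        """Restrict the curve to rows [z0, z1] (inclusive, clamped)."""
        z0 = max(z0, self.z_sup)
        z1 = min(z1, self.z_inf)
        if z0 > z1:
            raise ValueError("empty crop range")
        return PathCurve(z0, z1, self.values[z0 - self.z_sup : z1 - self.z_sup + 1])

    def as_points(self) -> np.ndarray:
        """Return the path as an (n, 2) array of (y, z) integer points."""
        zs = np.arange(self.z_sup, self.z_inf + 1)
        return np.stack([self.values, zs], axis=1)

    def to_jsonable(self) -> dict:
        return {"z_sup": int(self.z_sup), "z_inf": int(self.z_inf),
                "values": [int(v) for v in self.values]}

    @classmethod
    def from_jsonable(cls, d: dict) -> "PathCurve":
        return cls(int(d["z_sup"]), int(d["z_inf"]), np.asarray(d["values"]))


@dataclass
class SegmentationMask:
    """A binary mask aligned with a :class:`GrayImage`."""

    data: np.ndarray
    label: str = "mask"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 2:
            raise ValueError("mask must be 2D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def area(self) -> int:
        return int(self.data.sum())


# ---------------------------------------------------------------------------
# coordinate conversion
# ---------------------------------------------------------------------------

def to_internal_coords(y1: int, z1: int,
                       shape: tuple[int, int] = (CONFORMANT_SIZE, CONFORMANT_SIZE)
                       ) -> tuple[int, int]:
    """Convert 1-based (y, z) to the internal 0-based convention."""
    nz, ny = shape
    if not (1 <= y1 <= ny and 1 <= z1 <= nz):
        raise ValueError(f"({y1}, {z1}) outside 1-based bounds {ny}x{nz}")
    return y1 - 1, z1 - 1


def to_one_based_coords(y0: int, z0: int,
                    shape: tuple[int, int] = (CONFORMANT_SIZE, CONFORMANT_SIZE)
                    ) -> tuple[int, int]:
    """Inverse of :func:`to_internal_coords`."""
    nz, ny = shape
    if not (0 <= y0 < ny and 0 <= z0 < nz):
        raise ValueError(f"({y0}, {z0}) outside 0-based bounds {ny}x{nz}")
    return y0 + 1, z0 + 1


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _natural_key(path: Path):
    parts = re.split(r"(\d+)", path.name)
    return [int(p) if p.isdigit() else p for p in parts]


def _load_gray_file(path: Path, resolution_mm: float) -> GrayImage:
    with Image.open(path) as im:
        if im.mode != "L":
            logger.warning("%s is not 8-bit grayscale (mode %s); converting", path, im.mode)
            im = im.convert("L")
        arr = np.asarray(im, dtype=np.uint8)
    return GrayImage(arr, resolution_mm=resolution_mm)


def _load_dicom_series(files: list[Path], resolution_mm: float) -> SagittalSeries:
    import pydicom

    datasets = [pydicom.dcmread(str(f)) for f in files]
    # order by InstanceNumber when present, else filename
    try:
        datasets.sort(key=lambda d: int(d.InstanceNumber))
    except Exception:
        pass
    arrays = [d.pixel_array.astype(np.float64) for d in datasets]
    lo = min(a.min() for a in arrays)
    hi = max(a.max() for a in arrays)
    scale = 255.0 / (hi - lo) if hi > lo else 0.0
    slices = [GrayImage(np.round((a - lo) * scale).astype(np.uint8),
                        resolution_mm=resolution_mm) for a in arrays]
    return SagittalSeries(slices)


def read_series(path: str | Path, resolution_mm: float = DEFAULT_RESOLUTION_MM
                ) -> SagittalSeries:
    """Load an ordered slice stack from a directory, or one slice from a file.

    Plain raster files (PNG/JPEG/...) are sorted into acquisition order by the
    numeric components of their filenames.  A directory of DICOM files is
    window-mapped linearly (series-wide min-max) onto 256 gray levels.
    """
    path = Path(path)
    if path.is_file():
        if path.suffix.lower() in _DICOM_EXTENSIONS:
            return _load_dicom_series([path], resolution_mm)
        return SagittalSeries([_load_gray_file(path, resolution_mm)])
    if not path.is_dir():
        raise FileNotFoundError(path)
    files = sorted((p for p in path.iterdir() if p.suffix.lower() in _IMAGE_EXTENSIONS),
                   key=_natural_key)
    dicoms = sorted((p for p in path.iterdir() if p.suffix.lower() in _DICOM_EXTENSIONS),
                    key=_natural_key)
    if dicoms and not files:
        return _load_dicom_series(dicoms, resolution_mm)
    if not files:
        raise ValueError(f"no images found in {path}")
    return SagittalSeries([_load_gray_file(f, resolution_mm) for f in files])


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_mask(mask: SegmentationMask, path: str | Path,
               curves: dict[str, PathCurve] | None = None,
               canal_extent: tuple[int, int] | None = None) -> Path:
    """Write a mask as a lossless 0/255 PNG plus a JSON sidecar.

    The sidecar records the structure label and, optionally, the DP curves
    (0-based integer arrays) and the canal row extent that produced the mask.
    Returns the sidecar path.
    """
    path = Path(path)
    img = Image.fromarray(np.where(mask.data, 255, 0).astype(np.uint8), mode="L")
    img.save(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    payload: dict = {"label": mask.label}
    if curves:
        payload["curves"] = {name: c.to_jsonable() for name, c in curves.items()}
    if canal_extent is not None:
        payload["canal_extent"] = [int(canal_extent[0]), int(canal_extent[1])]
    sidecar.write_text(json.dumps(payload, indent=2))
    return sidecar


def read_mask(path: str | Path) -> tuple[SegmentationMask, dict]:
    """Read a mask PNG written by :func:`write_mask` with its sidecar."""
    path = Path(path)
    with Image.open(path) as im:
        data = np.asarray(im.convert("L")) > 127
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return SegmentationMask(data, label=meta.get("label", "mask")), meta
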
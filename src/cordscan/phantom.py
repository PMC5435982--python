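"""Seeded synthetic sagittal cervical-spine phantom with ground truth.

The phantom emulates the anatomy and intensity model the segmentation
pipeline assumes on T2-weighted midsagittal images:

* tissue classes ordered air << hypointense (ligaments, cortex, annulus)
  < isointense (cord, marrow, muscle) < hyperintense (CSF, nucleus);
* a vertebral column of rounded-rectangle bodies with 2-px hypointense
  cortex rims, separated by disks, bounded by thin ALL / PLL bands, a
  CSF-filled canal containing the cord, and a ligamentum flavum behind it;
* a C2 body + odontoid complex about 1.5x the height of a lower cervical
  body, with a clivus block above it;
* a 13-slice stack that is mirror-symmetric about a planted midsagittal
  position (integer or half-integer): slices away from the midline narrow
  the canal and thin the cord, as the paramedian anatomy does;
* a superior->inferior linear drift of the cord signal, plus seeded
  Gaussian noise whose standard deviation is tissue-dependent (CSF flow,
  trabecular marrow and muscle are noisier than the cord), so homogeneity
  is informative the way it is on real images.

Geometry parameters left unset are sampled per seed from the normal ranges
of the adult cervical spine at 0.6875 mm/px: vertebral-body depth 22-30 px,
height 14-22 px (area kept within 300-600 px), canal depth 22-30 px.
Everything is deterministic for a fixed spec + seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .image_model import DEFAULT_RESOLUTION_MM, GrayImage, PathCurve, SagittalSeries

__all__ = ["PhantomSpec", "PhantomTruth", "generate", "generate_stenotic_pair",
           "degrade", "TISSUE_MEANS", "TISSUE_TEXTURE"]

#: default tissue mean gray levels (air < ligament/cortex band < iso < hyper);
#: ligament is kept slightly darker than cortex, as on real T2 images, so the
#: two are distinguishable where they abut
TISSUE_MEANS = {
    "air": 5.0, "ligament": 28.0, "cortex": 34.0, "annulus": 34.0,
    "marrow": 80.0, "cord": 80.0, "muscle": 70.0, "csf": 180.0,
    "nucleus": 180.0, "bone": 34.0,
}

#: relative noise levels: CSF pulsation, trabecular marrow and muscle are
#: noisier than the cord, which is what makes homogeneity informative
TISSUE_TEXTURE = {
    "air": 1.2, "ligament": 1.2, "cortex": 1.3, "annulus": 1.3,
    "marrow": 1.6, "cord": 1.0, "muscle": 1.6, "csf": 1.6,
    "nucleus": 1.6, "bone": 1.3,
}

_TISSUES = list(TISSUE_MEANS)
_TID = {name: i for i, name in enumerate(_TISSUES)}

_LEVEL_NAMES = [f"C{i}" for i in range(2, 8)] + [f"T{i}" for i in range(1, 13)]


@dataclass
class PhantomSpec:
    """Generator conditions; ``None`` geometry fields are sampled per seed."""

    seed: int = 0
    height: int = 320
    width: int = 320
    n_slices: int = 13
    resolution_mm: float = DEFAULT_RESOLUTION_MM
    k_msp: float = 7.0                      # planted midsagittal position
    means: dict = field(default_factory=lambda: dict(TISSUE_MEANS))
    noise_sd: float = 3.0                   # base noise (cord-referenced)
    drift_total: float = 8.0                # cord gray drop from top to bottom
    vb_depth: int | None = None             # [22, 30] px
    vb_height: int | None = None            # [14, 22] px, area in [300, 600]
    disk_height: int | None = None          # [5, 8] px
    canal_depth: int | None = None          # [22, 30] px
    cord_depth: int | None = None           # [8, 12] px
    column_anterior_y: int | None = None    # [90, 110]
    curve_amplitude: float | None = None    # [0, 5] px midline bow
    vb_top: int | None = None               # [40, 55]
    cortex_rim: int = 1
    ligament_thickness: int = 2
    c2_factor: float = 1.5
    disk_nucleus: bool = False              # hydrated nucleus core in disks
    prevertebral_blob: bool = False         # soft-tissue blob anterior to ALL
    stenosis: list[tuple[str, float]] = field(default_factory=list)
    stenosis_halfwidth: int = 14


@dataclass
class _Geometry:
    """Fully resolved deterministic geometry (midsagittal, reduction 0)."""

    spec: PhantomSpec
    vb_depth: int
    vb_height: int
    disk_height: int
    canal_depth: int
    cord_depth: int
    y_a: int
    curve_amplitude: float
    vb_top: int
    blocks: list[tuple[str | None, int, int]]  # (label, z0, z1) half-open


@dataclass
class PhantomTruth:
    """Ground truth for the midsagittal candidate slice(s)."""

    k_msp: float
    candidate_indices: list[int]
    canal_extent: tuple[int, int]
    masks: dict                          # tissue name -> bool array
    vb_masks: dict                       # label -> marrow mask
    disk_masks: dict                     # label -> disk mask
    cord_anterior: PathCurve
    cord_posterior: PathCurve
    column_anterior: PathCurve
    pll: PathCurve
    lf: PathCurve
    tissue_map: np.ndarray
    geometry: _Geometry

    @property
    def cord_mask(self) -> np.ndarray:
        return self.masks["cord"]

    @property
    def vb_labels(self) -> list[str]:
        return list(self.vb_masks)


def _resolve_geometry(spec: PhantomSpec, rng: np.random.Generator) -> _Geometry:
    def pick(value, lo, hi):
        return int(value) if value is not None else int(rng.integers(lo, hi + 1))

    d = pick(spec.vb_depth, 22, 30)
    h_lo = max(14, math.ceil(300 / d))
    h_hi = min(22, 600 // d)
    h = pick(spec.vb_height, h_lo, h_hi)
    disk_h = pick(spec.disk_height, 5, 8)
    canal = pick(spec.canal_depth, 22, min(30, d + 4))
    cord = pick(spec.cord_depth, 8, 12)
    y_a = pick(spec.column_anterior_y, 90, 110)
    amp = (float(spec.curve_amplitude) if spec.curve_amplitude is not None
           else float(rng.uniform(0, 5)))
    top = pick(spec.vb_top, 40, 55)

    if cord + 4 > canal:
        raise ValueError("inconsistent geometry: cord too deep for the canal")
    if canal > d + 4:
        raise ValueError("inconsistent geometry: canal wider than the column")
    if not 300 <= d * h <= 600:
        raise ValueError(f"vertebral body area {d * h} outside [300, 600] px")

    # block stack: clivus (unlabeled), then C2 (1.5x height), C3, ...
    blocks: list[tuple[str | None, int, int]] = [(None, 0, top - disk_h)]
    z = top
    c2_h = int(round(spec.c2_factor * h))
    for name in _LEVEL_NAMES:
        bh = c2_h if name == "C2" else h
        if z + bh > spec.height:  # only fully contained bodies are planted
            break
        blocks.append((name, z, z + bh))
        z = z + bh + disk_h
    return _Geometry(spec=spec, vb_depth=d, vb_height=h, disk_height=disk_h,
                     canal_depth=canal, cord_depth=cord, y_a=y_a,
                     curve_amplitude=amp, vb_top=top, blocks=blocks)


def _stenosis_profile(geom: _Geometry) -> tuple[np.ndarray, np.ndarray]:
    """Per-row anterior/posterior CSF-gap closures (pixels)."""
    spec = geom.spec
    nz = spec.height
    shift_a = np.zeros(nz)
    shift_p = np.zeros(nz)
    if not spec.stenosis:
        return shift_a.astype(int), shift_p.astype(int)
    labeled = {name: (z0, z1) for name, z0, z1 in geom.blocks if name}
    gap_ant = (geom.canal_depth - geom.cord_depth) // 2
    gap_post = geom.canal_depth - geom.cord_depth - gap_ant
    w = spec.stenosis_halfwidth
    zs = np.arange(nz)
    for level, severity in spec.stenosis:
        upper, lower = level.split("-")
        lower_full = lower if not lower.isdigit() else upper[0] + lower
        if upper not in labeled or lower_full not in labeled:
            raise ValueError(f"unknown stenosis level {level!r}")
        zc = (labeled[upper][1] + labeled[lower_full][0]) / 2.0
        bump = np.where(np.abs(zs - zc) <= w,
                        np.cos(np.pi * (zs - zc) / (2 * w)) ** 2, 0.0)
        shift_a = np.maximum(shift_a, severity * bump * gap_ant)
        shift_p = np.maximum(shift_p, severity * bump * gap_post)
    return np.round(shift_a).astype(int), np.round(shift_p).astype(int)


def _draw_tissues(geom: _Geometry, reduction: int) -> np.ndarray:
    """Tissue-id map for a slice ``reduction`` half-steps from the midline."""
    spec = geom.spec
    nz, ny = spec.height, spec.width
    lig = spec.ligament_thickness
    rim = spec.cortex_rim
    cord_d = max(geom.cord_depth - reduction, 3)
    canal_d = max(geom.canal_depth - 2 * reduction, cord_d + 2)

    tmap = np.full((nz, ny), _TID["air"], dtype=np.int8)
    zs = np.arange(nz)
    offset = np.round(geom.curve_amplitude * np.sin(np.pi * zs / (nz - 1))
                      ).astype(int)
    y_a = geom.y_a + offset
    shift_a, shift_p = _stenosis_profile(geom)

    col_end = y_a + geom.vb_depth                 # column [y_a, col_end)
    pll_0 = col_end + shift_a
    canal_0 = col_end + lig                        # unshifted canal start
    lf_0 = canal_0 + geom.canal_depth - shift_p    # LF pulled anteriorly
    lf_end = canal_0 + geom.canal_depth + lig
    cord_0 = canal_0 + (canal_d - cord_d) // 2
    bone_0 = canal_0 + canal_d                     # paramedian bone fill

    disk_rows = np.ones(nz, dtype=bool)            # column rows not in a VB
    for name, z0, z1 in geom.blocks:
        disk_rows[z0:z1] = False

    for z in range(nz):
        row = tmap[z]
        row[y_a[z] - lig:y_a[z]] = _TID["ligament"]            # ALL
        fill = _TID["annulus"] if disk_rows[z] else _TID["cortex"]
        row[y_a[z]:col_end[z]] = fill
        row[col_end[z]:pll_0[z]] = _TID["annulus"]             # stenotic bulge
        row[pll_0[z]:pll_0[z] + lig] = _TID["ligament"]        # PLL
        csf_0 = max(pll_0[z] + lig, canal_0[z])
        row[csf_0:canal_0[z] + canal_d] = _TID["csf"]
        row[bone_0[z]:lf_end[z]] = _TID["bone"]                # paramedian
        row[cord_0[z]:cord_0[z] + cord_d] = _TID["cord"]
        row[lf_0[z]:lf_end[z]] = _TID["ligament"]              # LF
        row[lf_end[z]:] = _TID["muscle"]

    # vertebral bodies: marrow interiors inside cortex rims; the clivus
    # block (unnamed) stays cortical so no spurious region sits above C2
    for name, z0, z1 in geom.blocks:
        if name is None:
            continue
        for z in range(max(z0 + rim, 0), min(z1 - rim, nz)):
            row = tmap[z]
            row[y_a[z] + rim:col_end[z] - rim] = _TID["marrow"]

    if spec.disk_nucleus:
        for (na, _, z1a), (nb, z0b, _) in zip(geom.blocks, geom.blocks[1:]):
            if na is None:
                continue
            zc = (z1a + z0b) // 2
            for z in range(zc - 1, zc + 1):
                if 0 <= z < nz:
                    lo = y_a[z] + geom.vb_depth // 2
                    tmap[z, lo:lo + geom.vb_depth // 3] = _TID["nucleus"]

    if spec.prevertebral_blob:
        named = [b for b in geom.blocks if b[0] == "C4"]
        if named:
            _, z0, z1 = named[0]
            for z in range(max(z0 - 4, 0), min(z1 + 4, nz)):
                tmap[z, y_a[z] - lig - 6:y_a[z] - lig] = _TID["muscle"]
    return tmap


def _render(tmap: np.ndarray, geom: _Geometry, rng: np.random.Generator
            ) -> GrayImage:
    spec = geom.spec
    nz, ny = tmap.shape
    mean_lut = np.array([spec.means.get(t, TISSUE_MEANS[t]) for t in _TISSUES])
    sd_lut = np.array([TISSUE_TEXTURE[t] for t in _TISSUES]) * spec.noise_sd
    img = mean_lut[tmap].astype(np.float64)
    # superior->inferior cord signal drift (field inhomogeneity surrogate)
    zs = np.arange(nz, dtype=np.float64)
    drift = spec.drift_total * (0.5 - zs / (nz - 1))
    img[tmap == _TID["cord"]] += np.broadcast_to(drift[:, None], tmap.shape
                                                 )[tmap == _TID["cord"]]
    img += rng.normal(0.0, 1.0, tmap.shape) * sd_lut[tmap]
    return GrayImage(np.clip(np.round(img), 0, 255).astype(np.uint8),
                     resolution_mm=spec.resolution_mm)


def _lipschitz(values: np.ndarray) -> np.ndarray:
    """Clamp per-row steps to +-1 so the curve satisfies DP continuity
    (rounding of two smooth summands can occasionally step by 2)."""
    out = values.astype(np.int64).copy()
    for i in range(1, len(out)):
        out[i] = min(max(out[i], out[i - 1] - 1), out[i - 1] + 1)
    return out


def _build_truth(geom: _Geometry, reduction: int, k_msp: float,
                 candidates: list[int]) -> PhantomTruth:
    spec = geom.spec
    tmap = _draw_tissues(geom, reduction)
    nz = spec.height
    masks = {t: tmap == _TID[t] for t in _TISSUES}

    labeled = [(n, z0, z1) for n, z0, z1 in geom.blocks if n]
    if len(labeled) < 7:
        raise ValueError("phantom too short to contain C2..T1")
    c2 = labeled[0]
    t1 = labeled[6]
    canal_extent = (c2[1], t1[2] - 1)

    marrow = masks["marrow"]
    vb_masks = {}
    for name, z0, z1 in labeled:
        m = np.zeros_like(marrow)
        m[z0:z1] = marrow[z0:z1]
        if m.any():
            vb_masks[name] = m
    disk_masks = {}
    column = (masks["cortex"] | masks["annulus"] | marrow | masks["nucleus"])
    for (na, _, z1a), (nb, z0b, _) in zip(labeled, labeled[1:]):
        m = np.zeros_like(marrow)
        m[z1a:z0b] = column[z1a:z0b]
        pa, pb = (f"{na}-{nb[1:]}" if na[0] == nb[0] else f"{na}-{nb}"), m
        disk_masks[pa] = pb

    cord = masks["cord"]
    ant = np.array([np.nonzero(cord[z])[0][0] for z in range(nz)])
    post = np.array([np.nonzero(cord[z])[0][-1] for z in range(nz)])
    zs = np.arange(nz)
    offset = np.round(geom.curve_amplitude * np.sin(np.pi * zs / (nz - 1))
                      ).astype(int)
    y_a = geom.y_a + offset
    shift_a, _ = _stenosis_profile(geom)
    lig = spec.ligament_thickness
    pll = _lipschitz(y_a + geom.vb_depth + shift_a)
    lf = y_a + geom.vb_depth + lig + geom.canal_depth

    return PhantomTruth(
        k_msp=k_msp, candidate_indices=candidates, canal_extent=canal_extent,
        masks=masks, vb_masks=vb_masks, disk_masks=disk_masks,
        cord_anterior=PathCurve(0, nz - 1, ant),
        cord_posterior=PathCurve(0, nz - 1, post),
        column_anterior=PathCurve(0, nz - 1, y_a - 1),
        pll=PathCurve(0, nz - 1, pll),
        lf=PathCurve(0, nz - 1, lf),
        tissue_map=tmap, geometry=geom)


def generate(spec: PhantomSpec) -> tuple[SagittalSeries, PhantomTruth]:
    """Generate the 13-slice series and the midsagittal ground truth.

    Deterministic for a fixed spec: the seed drives geometry sampling and
    per-slice noise in a fixed order.
    """
    if not (4 <= spec.k_msp <= spec.n_slices - 3):
        raise ValueError("planted k_msp must leave at least 4 slice pairs")
    if round(spec.k_msp * 2) != spec.k_msp * 2:
        raise ValueError("k_msp must be an integer or half-integer")
    rng = np.random.default_rng(spec.seed)
    geom = _resolve_geometry(spec, rng)

    slices = []
    for k in range(1, spec.n_slices + 1):
        reduction = int(round(2 * abs(k - spec.k_msp)))
        tmap = _draw_tissues(geom, reduction)
        slices.append(_render(tmap, geom, rng))
    series = SagittalSeries(slices)

    if spec.k_msp == int(spec.k_msp):
        candidates = [int(spec.k_msp)]
        truth_reduction = 0
    else:
        candidates = [int(spec.k_msp - 0.5), int(spec.k_msp + 0.5)]
        truth_reduction = 1
    truth = _build_truth(geom, truth_reduction, spec.k_msp, candidates)
    return series, truth


def generate_stenotic_pair(spec: PhantomSpec
                           ) -> tuple[tuple[SagittalSeries, PhantomTruth],
                                      tuple[SagittalSeries, PhantomTruth]]:
    """The same phantom with and without its stenosis, bit-identical
    everywhere outside the stenotic levels (same seed, same noise stream)."""
    normal = generate(replace(spec, stenosis=[]))
    stenotic = generate(spec)
    return normal, stenotic


def degrade(series: SagittalSeries, kind: str, magnitude: float
            ) -> SagittalSeries:
    """Apply a named acquisition artifact to every slice.

    ``drift``: an extra superior->inferior intensity ramp of ``magnitude``
    gray levels; ``gibbs_lines``: thin vertical hyperintense lines
    (truncation artifact), brightened by ``magnitude``; ``window_clip``:
    multiplicative windowing by (1 + magnitude) that saturates hyperintense
    pixels at 255.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    out = []
    for s in series.slices:
        arr = s.astype_float()
        nz, ny = arr.shape
        if kind == "drift":
            arr = arr - magnitude * (np.arange(nz) / max(nz - 1, 1))[:, None]
        elif kind == "gibbs_lines":
            arr = arr.copy()
            arr[:, 10::37] += magnitude
        elif kind == "window_clip":
            arr = arr * (1.0 + magnitude)
        else:
            raise ValueError(f"unknown degradation kind {kind!r}")
        out.append(GrayImage(np.clip(np.round(arr), 0, 255).astype(np.uint8),
                             resolution_mm=s.resolution_mm))
    return SagittalSeries(out, slice_thickness_mm=series.slice_thickness_mm,
                          gap_mm=series.gap_mm)
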
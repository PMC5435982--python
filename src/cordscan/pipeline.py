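"""End-to-end orchestration of the segmentation stages.

Stage order: midsagittal selection (skipped for single-slice input) ->
histogram EM + threshold repair and coarse/refined cord detection on each
candidate -> candidate arbitration -> ligament detections -> column
threshold, truncated-ALL path and region growing -> vertebra labeling (or
a user-designated canal extent when labeling fails) -> median cord profile
-> cord edge detection.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np

from . import cord_edges, intensity_em, midsagittal, structure_detection
from . import vertebra_labeling as vl
from .image_model import DEFAULT_RESOLUTION_MM, GrayImage, SagittalSeries

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All tunables, defaulting to the pixel constants of the reference
    protocol (320 x 320 at 0.6875 mm/px).  They are exposed because every
    one of them would need retuning for other anatomy or scanners."""

    resolution_mm: float = DEFAULT_RESOLUTION_MM
    b2_band_halfwidth: int = structure_detection.B2_BAND_HALFWIDTH
    canal_band_width: int = structure_detection.CANAL_BAND_WIDTH
    b5_band_near: int = structure_detection.B5_BAND_NEAR
    b5_band_far: int = structure_detection.B5_BAND_FAR
    f5_marrow_pixels: int = structure_detection.F5_MARROW_PIXELS
    f6_posterior_pixels: int = vl.F6_POSTERIOR_PIXELS
    vb_min_area: int = vl.VB_MIN_AREA
    disk_min_area: int = vl.DISK_MIN_AREA
    c2_gap_px: int = vl.C2_GAP_PX
    iso_band: tuple[int, int, int, int] = (64, 127, 128, 159)
    stability_window: int = structure_detection.STABILITY_WINDOW
    profile_window: tuple[int, int] = (cord_edges.PROFILE_Y_HALFWIDTH,
                                       cord_edges.PROFILE_Z_HALFWIDTH)
    canal_override: tuple[int, int] | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    image: GrayImage
    chosen_slice: int
    kmsp: midsagittal.MidsagittalCandidate | None
    fit: intensity_em.GmmFit
    structures: structure_detection.StructureSet
    tvb: vl.ColumnThreshold
    spine: vl.LabeledSpine
    disks: list[vl.SpineRegion]
    profile: cord_edges.CordProfile
    segmentation: cord_edges.CordSegmentation
    log: list[str] = field(default_factory=list)

    @property
    def cord_mask(self):
        return self.segmentation.mask

    @property
    def canal_extent(self) -> tuple[int, int]:
        return self.spine.canal_extent


def _check_config(config: PipelineConfig) -> None:
    defaults = PipelineConfig()
    overridden = {k: v for k, v in config.to_dict().items()
                  if v != getattr(defaults, k) and k != "seed"}
    if overridden:
        logger.info("non-default configuration: %s", overridden)


def run_pipeline(series: SagittalSeries | GrayImage,
                 config: PipelineConfig | None = None) -> PipelineResult:
    """Run every stage on a series (or a single pre-selected slice).

    Raises :class:`StageError` naming the failed stage; in particular the
    ``labeling`` stage fails when no canal extent could be derived and
    ``config.canal_override`` was not supplied — the pipeline equivalent of
    the interactive review step.
    """
    config = config or PipelineConfig()
    _check_config(config)
    log: list[str] = []

    if isinstance(series, GrayImage):
        series = SagittalSeries([series])

    # --- stage 1: midsagittal selection ------------------------------------
    if len(series) == 1:
        kmsp = None
        candidate_indices = [1]
        log.append("single-slice input: midsagittal selection skipped")
    else:
        try:
            kmsp = midsagittal.select_kmsp(series)
        except ValueError as e:
            raise StageError("midsagittal", str(e)) from e
        candidate_indices = kmsp.indices
        log.append(f"k_MSP = {kmsp.k_msp} (score {kmsp.score:.3f}, "
                   f"m = {kmsp.m}); candidates {candidate_indices}")

    # --- stage 2: EM + coarse/refined cord on each candidate ----------------
    candidates = []
    for idx in candidate_indices:
        img = series[idx]
        fit = intensity_em.repair_iso_upper(
            intensity_em.fit_histogram_gmm(img, seed=config.seed))
        if fit.adjusted:
            log.append(f"slice {idx}: iso threshold adjusted ({fit.adjust_reason})")
        B1 = structure_detection.detect_B1(img, fit)
        B2 = structure_detection.detect_B2(img, B1,
                                           halfwidth=config.b2_band_halfwidth)
        candidates.append((idx, img, fit, B1, B2))

    pick = structure_detection.choose_candidate_slice(
        [(img, B2) for _, img, _, _, B2 in candidates])
    idx, img, fit, B1, B2 = candidates[pick]
    log.append(f"chosen midsagittal slice: {idx}")

    # --- stage 3: ligaments --------------------------------------------------
    try:
        B3, B4 = structure_detection.detect_B3_B4(
            img, B2, width=config.canal_band_width)
        B5 = structure_detection.detect_B5(
            img, B3, near=config.b5_band_near, far=config.b5_band_far)
        structures = structure_detection.StructureSet(
            B1=B1, B2=B2, B3=B3, B4=B4, B5=B5, chosen_slice=idx, fit=fit)
    except ValueError as e:
        raise StageError("ligaments", str(e)) from e

    # --- stage 4: column threshold, B6, region growing, labeling -------------
    tvb = vl.compute_tvb(img, B5, B3, fallback_threshold=fit.iso_lower)
    B6 = vl.detect_B6(img, B5, B3, tvb)
    regions = vl.segment_vb_regions(img, B6, B3, tvb)
    spine = vl.label_vertebrae(regions, resolution_mm=config.resolution_mm)
    spine.B6 = B6
    if spine.labeling_failed:
        if config.canal_override is None:
            raise StageError(
                "labeling",
                f"vertebra labeling failed on {len(regions)} regions and no "
                "canal override was supplied")
        spine = vl.apply_manual_override(spine, *config.canal_override,
                                         height=img.height_z)
        log.append(f"labeling failed; manual canal extent "
                   f"{config.canal_override} applied")
    elif config.canal_override is not None:
        spine = vl.apply_manual_override(spine, *config.canal_override,
                                         height=img.height_z)
        log.append(f"manual canal extent {config.canal_override} overrides "
                   "the labeled one")
    else:
        log.append(f"canal extent {spine.canal_extent} from labels "
                   f"{[r.label for r in spine.regions if r.label]}")
    disks = vl.segment_disks(img, B6, B3, spine) if not spine.labeling_failed else []

    # --- stage 5: cord edges --------------------------------------------------
    class_map = fit.pixel_classes(img)
    try:
        profile = cord_edges.median_cord_profile(img, B2, class_map,
                                                 spine.canal_extent)
        f7 = cord_edges.fitness_f7(img, profile, class_map)
        f8 = cord_edges.fitness_f8(img, profile, class_map)
        segmentation = cord_edges.detect_cord_edges(img, f7, f8, B2, B3, B4,
                                                    spine.canal_extent)
    except ValueError as e:
        raise StageError("cord_edges", str(e)) from e
    log.append(f"cord mask: {segmentation.mask.area} px over canal rows "
               f"{spine.canal_extent}")

    return PipelineResult(image=img, chosen_slice=idx, kmsp=kmsp, fit=fit,
                          structures=structures, tvb=tvb, spine=spine,
                          disks=disks, profile=profile,
                          segmentation=segmentation, log=log)
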
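"""Histogram classification of T2 signal intensities by Gaussian-mixture EM.

The 256-level histogram of a sagittal slice is fitted with a mixture of up
to four Gaussians.  On T2-weighted cervical images the relevant tissue
classes, ordered by mean signal, are:

* ``air``   -- very dark background/trachea pixels (a narrow, heavy peak),
* ``hypo``  -- ligaments, cortical bone, annulus fibrosus,
* ``iso``   -- spinal cord, bone marrow, muscle (the reference class),
* ``hyper`` -- CSF and hydrated nucleus pulposus.

The mixture is grown sequentially: the converged k-component fit seeds the
(k+1)-component fit by splitting its heaviest component about its mean.
Each gray level is then assigned to the component contributing the largest
share of the mixture density at that level; levels below the air peak are
forced to ``air``.

Because field inhomogeneity, windowing, and truncation artifacts can pull
the fitted isointense band away from the true cord intensities (which sit
roughly between gray 60 and 100 under this protocol), the upper isointense
threshold is sanity-checked: values in [64, 127] pass unchanged; values
above 127 are recomputed from the isointense component as mean + 2 sd and
clamped to [127, 159]; values below 64 are reset to 128 outright.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .image_model import GrayImage

logger = logging.getLogger(__name__)

__all__ = ["GaussianComponent", "GmmFit", "fit_histogram_gmm",
           "classify_gray_levels", "repair_iso_upper"]

CLASS_NAMES = ("air", "hypo", "iso", "hyper")
#: canonical tissue-class prototype means used to name fits with < 4 components
_PROTOTYPES = {"air": 5.0, "hypo": 30.0, "iso": 80.0, "hyper": 180.0}

_VAR_FLOOR = 0.01
_WEIGHT_FLOOR = 1e-4
_TOL = 1e-6
_MAX_ITER = 500
_LL_SLACK = 1e-7  # relative slack on the monotone log-likelihood assertion


@dataclass(frozen=True)
class GaussianComponent:
    mean: float
    variance: float
    weight: float
    label: str = ""


@dataclass
class GmmFit:
    """A converged mixture fit plus the per-gray-level class table."""

    components: list[GaussianComponent]
    class_of_gray: np.ndarray = field(default_factory=lambda: np.empty(0, dtype="<U5"))
    iso_lower: int | None = None
    iso_upper: int | None = None
    adjusted: bool = False
    adjust_reason: str = ""
    log_likelihoods: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 1 <= len(self.components) <= 4:
            raise ValueError("a fit has between 1 and 4 components")
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"component weights sum to {total}, expected 1")

    def component(self, label: str) -> GaussianComponent | None:
        for c in self.components:
            if c.label == label:
                return c
        return None

    def pixel_classes(self, img: GrayImage) -> np.ndarray:
        """Per-pixel class labels obtained by table lookup."""
        return self.class_of_gray[img.pixels]

    def iso_mask(self, img: GrayImage) -> np.ndarray:
        return self.pixel_classes(img) == "iso"


# ---------------------------------------------------------------------------
# weighted EM on the 256-bin histogram
# ---------------------------------------------------------------------------

def _normal_density(x: np.ndarray, mean: np.ndarray, var: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * (x - mean) ** 2 / var) / np.sqrt(2.0 * np.pi * var)


def _run_em(levels: np.ndarray, counts: np.ndarray,
            means: np.ndarray, variances: np.ndarray, weights: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """EM to convergence on histogram data; returns params + ll history."""
    n = counts.sum()
    lls: list[float] = []
    prev_ll = -np.inf
    for _ in range(_MAX_ITER):
        dens = weights[:, None] * _normal_density(levels[None, :], means[:, None],
                                                  variances[:, None])
        total = dens.sum(axis=0)
        ll = float(np.sum(counts * np.log(total + 1e-300)))
        if lls and ll < prev_ll - _LL_SLACK * (abs(prev_ll) + 1.0):
            # the variance floor can cost an infinitesimal amount; anything
            # beyond numerical slack indicates a genuine defect
            raise AssertionError("EM log-likelihood decreased")
        lls.append(ll)
        resp = dens / (total + 1e-300)
        nk = resp @ counts
        keep = nk / n >= _WEIGHT_FLOOR
        if not keep.all():
            means, variances, weights = means[keep], variances[keep], weights[keep]
            weights = weights / weights.sum()
            prev_ll = -np.inf
            continue
        weights = nk / n
        means = (resp @ (counts * levels)) / nk
        sq = (levels[None, :] - means[:, None]) ** 2
        variances = np.maximum((resp * sq) @ counts / nk, _VAR_FLOOR)
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= _TOL * (abs(prev_ll) + 1.0):
            break
        prev_ll = ll
    return means, variances, weights, np.asarray(lls)


def _label_components(means: np.ndarray) -> list[str]:
    """Name components, ordered by ascending mean, after the tissue classes.

    With four components the names are simply air/hypo/iso/hyper.  With
    fewer, the order-preserving subset of canonical names whose prototype
    means are closest to the fitted means is chosen.
    """
    k = len(means)
    if k == 4:
        return list(CLASS_NAMES)
    from itertools import combinations

    best, best_cost = None, np.inf
    for combo in combinations(CLASS_NAMES, k):
        cost = sum(abs(m - _PROTOTYPES[c]) for m, c in zip(means, combo))
        if cost < best_cost:
            best, best_cost = combo, cost
    return list(best)  # type: ignore[arg-type]


def fit_histogram_gmm(img: GrayImage, seed: int = 0) -> GmmFit:
    """Fit the slice histogram with 1..4 Gaussians grown sequentially.

    The ``seed`` is accepted for interface uniformity; the initialisation is
    fully deterministic (moment start, heaviest-component splitting) so the
    fit does not depend on it.
    """
    del seed
    counts = np.bincount(img.pixels.ravel(), minlength=256).astype(np.float64)
    levels = np.arange(256, dtype=np.float64)
    nz = np.nonzero(counts)[0]
    if len(nz) == 1:
        logger.warning("degenerate single-valued image; single-component fit")
        comp = GaussianComponent(float(nz[0]), _VAR_FLOOR, 1.0, "iso")
        fit = GmmFit([comp], log_likelihoods=[np.zeros(1)])
        fit.components = [replace(comp, label=_label_components(np.array([comp.mean]))[0])]
        return classify_gray_levels(fit)

    mean0 = float((counts * levels).sum() / counts.sum())
    var0 = float((counts * (levels - mean0) ** 2).sum() / counts.sum())
    means = np.array([mean0])
    variances = np.array([max(var0, _VAR_FLOOR)])
    weights = np.array([1.0])

    histories: list[np.ndarray] = []
    target = min(4, len(nz))
    while True:
        means, variances, weights, lls = _run_em(levels, counts, means, variances, weights)
        histories.append(lls)
        if len(means) >= target:
            break
        # seed the next fit by splitting the dominant component -- the one
        # carrying the most spread (weight x sd), so a heavy but narrow
        # background peak is not split ahead of a broad multi-tissue peak
        i = int(np.argmax(weights * np.sqrt(variances)))
        sd = np.sqrt(variances[i])
        means = np.concatenate([np.delete(means, i),
                                [means[i] - sd, means[i] + sd]])
        variances = np.concatenate([np.delete(variances, i),
                                    [variances[i], variances[i]]])
        w = weights[i] / 2.0
        weights = np.concatenate([np.delete(weights, i), [w, w]])

    order = np.argsort(means)
    means, variances, weights = means[order], variances[order], weights[order]
    labels = _label_components(means)
    comps = [GaussianComponent(float(m), float(v), float(w), lab)
             for m, v, w, lab in zip(means, variances, weights, labels)]
    fit = GmmFit(comps, log_likelihoods=histories)
    return classify_gray_levels(fit)


# ---------------------------------------------------------------------------
# classification and threshold repair
# ---------------------------------------------------------------------------

def classify_gray_levels(fit: GmmFit) -> GmmFit:
    """Assign each of the 256 gray levels to the dominant component.

    A level g takes the label of the component with maximal weight x density
    at g (ties go to the heavier component); levels below the air-component
    mean are overridden to ``air``.  The iso thresholds are set to the
    extreme gray levels labelled ``iso``.
    """
    levels = np.arange(256, dtype=np.float64)
    means = np.array([c.mean for c in fit.components])
    variances = np.array([c.variance for c in fit.components])
    weights = np.array([c.weight for c in fit.components])
    labels = [c.label for c in fit.components]

    dens = weights[:, None] * _normal_density(levels[None, :], means[:, None],
                                              variances[:, None])
    # stable argmax with ties resolved toward the heavier component
    order = np.argsort(-weights, kind="stable")
    winner_sorted = np.argmax(dens[order], axis=0)
    winner = order[winner_sorted]
    class_map = np.array([labels[w] for w in winner], dtype="<U5")

    air = fit.component("air")
    if air is not None:
        class_map[levels < air.mean] = "air"

    iso_levels = np.nonzero(class_map == "iso")[0]
    iso_lower = int(iso_levels[0]) if len(iso_levels) else None
    iso_upper = int(iso_levels[-1]) if len(iso_levels) else None
    fit.class_of_gray = class_map
    fit.iso_lower = iso_lower
    fit.iso_upper = iso_upper
    return fit


def _rebuild_class_map(fit: GmmFit) -> np.ndarray:
    """Class map consistent with (possibly repaired) iso thresholds:
    the sub-iso levels keep their density-based air/hypo split, the iso band
    is [iso_lower, iso_upper], and everything above is hyper."""
    class_map = fit.class_of_gray.copy()
    g = np.arange(256)
    lo = fit.iso_lower if fit.iso_lower is not None else 0
    hi = fit.iso_upper if fit.iso_upper is not None else 255
    class_map[(g >= lo) & (g <= hi)] = "iso"
    class_map[g > hi] = "hyper"
    return class_map


def repair_iso_upper(fit: GmmFit) -> GmmFit:
    """Sanity-check / repair the upper isointense threshold.

    [64, 127] -> unchanged; > 127 -> iso mean + 2 sd clamped to [127, 159];
    < 64 (or missing) -> 128.  The class table is rebuilt around the
    repaired band.  Idempotent on thresholds and class map.
    """
    if fit.adjusted:  # already repaired; keep the recorded decision
        return fit
    t = fit.iso_upper
    iso = fit.component("iso")
    if t is not None and 64 <= t <= 127:
        if not fit.adjusted:
            fit.adjust_reason = "in range"
        return fit
    if t is None or t < 64:
        new_t, reason = 128, f"upper threshold {t} below 64; reset to 128"
    else:
        if iso is None:
            new_t, reason = 127, f"upper threshold {t} above 127; no iso component"
        else:
            est = iso.mean + 2.0 * np.sqrt(iso.variance)
            new_t = int(np.clip(round(est), 127, 159))
            reason = (f"upper threshold {t} above 127; recomputed as iso mean + 2 sd "
                      f"= {est:.1f}, clamped to {new_t}")
    logger.info("iso threshold repair: %s", reason)
    fit.iso_upper = new_t
    if fit.iso_lower is None or fit.iso_lower > new_t:
        fit.iso_lower = min(64, new_t)
    fit.adjusted = True
    fit.adjust_reason = reason
    fit.class_of_gray = _rebuild_class_map(fit)
    return fit
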
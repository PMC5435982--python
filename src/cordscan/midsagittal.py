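"""Symmetry-based selection of the midsagittal slice.

The cervical spine is bilaterally symmetric about the intact midsagittal
plane (iMSP).  Among the K sagittal slices of a series, the position k_MSP
closest to the iMSP is found by minimising the mean pairwise asymmetry
score over slice pairs mirrored about the candidate position:

    k_MSP = argmin_k  mean_j D(I^j, I^{2k-j})

where D is the population standard deviation of the per-pixel gray-level
differences between the two slices.  Candidates run over integers and
half-integers; an integer k names a single candidate slice, a half-integer
k names the two slices on either side of the plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image_model import GrayImage, SagittalSeries

__all__ = ["MidsagittalCandidate", "image_difference", "select_kmsp"]


@dataclass
class MidsagittalCandidate:
    """The selected sagittal position (1-based, integer or half-integer)."""

    k_msp: float
    score: float
    m: int                      # number of distinct slice pairs scored
    indices: list[int]          # the one or two nearest slice indices (1-based)
    score_table: dict[float, tuple[float, int]] = field(default_factory=dict)


def image_difference(a: GrayImage, b: GrayImage) -> float:
    """Asymmetry metric D: population std of the signed pixel differences.

    Symmetric in its arguments, zero iff a - b is constant (in particular
    D(I, I) = 0); unchanged by adding a constant to every pixel.
    """
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    diff = a.astype_float() - b.astype_float()
    return float(np.std(diff))


def _candidate_positions(K: int) -> list[float]:
    """Candidate k values with at least 4 mirror pairs available.

    Pairs (j, 2k-j) are counted with both indices in [1, K] and j <= 2k-j;
    for an integer candidate this count includes the degenerate self-pair
    (k, k), matching the way the eligibility rule pairs off all K slices.
    For K = 13 this yields k in {4, 4.5, ..., 10}.
    """
    out = []
    for twok in range(2, 2 * K + 1):  # 2k from 2 to 2K
        k = twok / 2.0
        j_lo = max(1, twok - K)
        j_hi = twok // 2  # j <= 2k - j
        if j_hi - j_lo + 1 >= 4:
            out.append(k)
    return out


def select_kmsp(series: SagittalSeries) -> MidsagittalCandidate:
    """Evaluate every eligible integer/half-integer candidate and return
    the one minimising the mean pair difference.

    The score for candidate k is the mean of D over the distinct pairs
    (j, 2k-j) with j < 2k-j; the self-pair of an integer candidate is
    identically zero and is excluded from the mean so that integer and
    half-integer candidates are scored on the same footing.  Ties are
    broken toward the smaller k.
    """
    K = len(series)
    candidates = _candidate_positions(K)
    if not candidates:
        raise ValueError(
            f"series of {K} slices has no candidate position with >= 4 mirror pairs")

    cache: dict[tuple[int, int], float] = {}

    def D(p: int, q: int) -> float:
        key = (min(p, q), max(p, q))
        if key not in cache:
            cache[key] = image_difference(series[key[0]], series[key[1]])
        return cache[key]

    table: dict[float, tuple[float, int]] = {}
    for k in candidates:
        twok = int(round(2 * k))
        pairs = [(j, twok - j) for j in range(max(1, twok - K), twok // 2 + 1)
                 if j < twok - j]
        scores = [D(j, jj) for j, jj in pairs]
        table[k] = (float(np.mean(scores)), len(pairs))

    best_k = min(table, key=lambda k: (table[k][0], k))
    score, m = table[best_k]
    if best_k == int(best_k):
        indices = [int(best_k)]
    else:
        indices = [int(best_k - 0.5), int(best_k + 0.5)]
    return MidsagittalCandidate(k_msp=best_k, score=score, m=m,
                                indices=indices, score_table=table)
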
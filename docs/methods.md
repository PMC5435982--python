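# Methods

This note documents the models, numerical choices and limitations of the
package in one place.  It states no result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate and data conventions

A slice is a 2D `uint8` grid indexed `pixels[z, y]`: y grows anterior →
posterior, z superior → inferior.  Everything internal is 0-based with
inclusive band limits; the 1-based convention used in the clinical
formulation is translated only at the `to_internal_coords` /
`to_one_based_coords` boundary.  Pixel-count constants (band widths, area
floors, the 70-px C2 gap) are deliberately **not** rescaled for images
that are not 320 × 320 at 0.6875 mm/px: they are protocol constants, and
applying the pipeline to other protocols requires retuning them (they are
all exposed on `PipelineConfig`).

## Midsagittal selection

The asymmetry metric `D` is the population standard deviation of signed
pixel differences, computed as reals (no clipping); it is symmetric,
invariant to global intensity offsets, and zero for identical slices.
Candidate positions are integers and half-integers.  Eligibility requires
at least four mirror pairs *counting the degenerate self-pair of an
integer candidate* — this reproduces the 4 ≤ k ≤ 10 candidate range for a
13-slice series.  The score itself is the mean of `D` over the distinct
pairs only (the self-pair is identically zero and would bias integer
candidates downward).  Ties break toward the smaller k.  When two
candidate slices remain, the one whose signal along the refined cord line
is most stable wins: total absolute deviation from a 31-pixel centred
moving average (window truncated at the ends), summed over rows
`z ≥ ceil(H/3)` — the lower two thirds, where vertebral anatomy is
regular.  Absolute deviation was chosen over squared deviation for outlier
robustness; the norm is otherwise immaterial to the comparison.

## Histogram EM

EM runs on the 256-bin histogram (weighted data, not per-pixel), which
makes it exact, fast and deterministic: moment initialisation for one
component, then components are added one at a time up to four.  Each
growth step splits the component with the **largest weight × sd** into two
at mean ± sd.  Splitting the *heaviest* component instead is tempting but
fails on spine histograms: the air peak is heavy yet extremely narrow, so
it gets split repeatedly while the broad mid-gray mass (ligaments + cord +
marrow) stays under-modelled; the weight × sd criterion targets the
component with the most unexplained spread.  Numerical guards: variance
floor 0.01 (delta peaks), component weight floor 1e-4 (collapse →
component removed and EM restarted on the survivors), convergence at 1e-6
relative log-likelihood change, 500 iterations cap.  The log-likelihood is
asserted non-decreasing (with 1e-7 relative slack for the variance floor).

Components are labeled air/hypo/iso/hyper by ascending mean; with fewer
than four components the order-preserving subset of canonical labels
closest to prototype means (5/30/80/180) is chosen.  Gray levels take the
label of the component with maximal weight × density; levels below the air
mean are forced to air.  After threshold repair the class table is rebuilt
as: below `iso_lower` the density-based air/hypo split, `[iso_lower,
iso_upper]` iso, above hyper — downstream detections consume the repaired
classes.  The under-specified "recompute from mean and sd" repair branch
is implemented as mean + 2 sd (≈ 97.7 % coverage of the isointense
component) before clamping to [127, 159].  Repair is idempotent: the
outcome is recorded in `adjusted` and not revisited.

## DP engine

The recurrence zeroes cumulative fitness outside the band, so a path may
effectively start mid-image; callers therefore must supply fields that are
non-negative in-band (the engine asserts it), making full-height paths
always at least as good — this mirrors the additive-constant device used
in the homogeneity and edge fields.  Tie precedence for predecessors is
straight (0), then anterior (−1), then posterior (+1); the stated special
cases (center ties for max → 0; two diagonals tied above center → −1) are
subsumed.  The backtrack start takes the smallest-y argmax.  These rules
make the engine fully deterministic; tests verify equivalence with
exhaustive path enumeration on random fields up to 10 × 10.

## Detections

Out-of-image pixels count as gray 0 (air-like) in intensity windows and
as non-isointense in the neighbour count — image borders are air in this
acquisition.  The edge bands for the cord edges, `[B3+1, B2]` and
`[B2, B4−1]`, are not dictated by the source formulation (which fixes only
the canal z-extent); they follow from anatomy — the cord lies between the
PLL and the LF, and `B2` lies inside the cord.  The unavailable fourth
term of the edge fitness (the non-cord penalty) is a class step penalty of
−65536 for hyper- or air-intense path pixels: large enough to dominate any
single squared-difference term (max 255² = 65 025), so the edge path can
never run through CSF or background, while hypointense pixels stay
traversable (needed at stenotic levels where the cord abuts ligament).
Both edge fields are shifted by their in-band minimum before DP.  Rows
where the two edges cross (degenerate stenosis) are repaired by swapping
them (min/max), which preserves path continuity; a warning lists the rows.

The truncated-ALL path `B6` deserves a note: its posterior count term
makes it hug the anterior edges of the disks but *cut into the anterior
half of vertebral bodies deeper than ~23 px* (the 20-pixel window cannot
see the posterior cortex from the anterior edge).  This is by design — the
valid-region floor of 150 px is "half of a normal body" precisely because
region growing only needs the posterior half to survive.

## Vertebra labeling

`t_VB` comes from the two most prominent peaks (scipy `find_peaks`,
prominence ≥ 5 % of the max bin) of the width-5-smoothed column histogram;
a unimodal histogram falls back to the EM `iso_lower` threshold with a
warning.  Region growing is 4-connected (diagonal leakage through 1-px
cortical gaps is the failure mode 8-connectivity invites).  "Large region"
for C2 means height ≥ 1.3 × the median height of the valid regions below
it (the C2 body + odontoid is ~1.5× a lower cervical body; 1.3 leaves
margin).  The canal's inferior edge uses extrapolation rather than the
detected T1 region: inter-body spacing = (C7 − C3 centre distance)/4,
disk gap = spacing − median body height, T1 height = C7 height.  Disks
are components of the column after removing each labeled body across the
full column depth for its rows; a component is a disk only if a labeled
body lies both above and below it.  Sorting is by z-centre with y-centre
tie-break; everything is deterministic.

## Phantom

The generator emulates what the pipeline assumes: tissue mean gray levels
air 5, ligament 28, cortex/annulus 34, muscle 70, cord/marrow 80,
CSF/nucleus 180 (ligament is kept slightly darker than cortex so the PLL
is separable from the adjacent posterior cortex — with identical means the
dark-pixel DP would tie between them, which no real image exhibits).
Noise is seeded Gaussian with tissue-dependent standard deviation
(base `noise_sd` = 3 for cord/air/ligament; ×1.3 for cortical bone,
×1.6 for CSF, marrow and muscle): CSF pulsation and trabecular/muscle
texture are what make *homogeneity* informative for the refined cord
line on real T2 images, and a texture-free phantom would leave that
fitness degenerate.  Cord signal drifts linearly superior → inferior by 8
gray levels by default, reproducing a gray-vs-z correlation of about −0.6
on cord pixels (measured by the acceptance script).  Geometry is sampled
per seed within adult cervical ranges at 0.6875 mm/px: body depth 22–30 px
and height 14–22 px with area kept in 300–600 px, canal depth 22–30 px
(capped at body depth + 4 so canal and column stay anatomically
consistent), disk height 5–8 px, 1-px cortical rims/end plates, C2 height
1.5× with a cortical clivus block above it, a gentle sinusoidal midline
bow (≤ 5 px).  Only fully-contained bodies are planted — a body clipped by
the image border is undetectable by construction and would poison
label-accuracy scoring.  Slices attenuate away from the planted
midsagittal position (integer or half-integer): canal depth shrinks by 2
and cord depth by 1 per half-slice step, mirror-symmetrically, so the
asymmetry score recovers the plant.  Stenosis closes the CSF gaps with a
smooth cos² bulge (half-width 14 rows keeps the PLL slope below the DP
continuity limit of 1 px/row); severity 1 makes the CSF vanish at that
level while the cord is untouched.  Degradations: an extra z-ramp, thin
vertical hyperintense lines (truncation artifact), and multiplicative
windowing that saturates hyperintense pixels — the last reliably drives
the iso-threshold repair's upper branch.

What the phantom does **not** emulate: partial-volume mixing at tissue
interfaces (1-px CSF rims staying isointense — an accepted failure mode),
bias fields, scoliosis/kyphosis, cord lesions, and realistic k-space/coil
physics.  Passing phantom tests therefore demonstrates the algorithmic
chain is correct under its stated assumptions, not clinical-grade
robustness.

## Problem sizes

The test suite and acceptance script use full-size series (13 × 320 × 320)
throughout; the end-to-end suites run 20 seeded phantoms and the
acceptance study 12 (cycling planted midsagittal positions across
integers and half-integers), sizes at which the whole pipeline runs in
well under a second per study.

## Known limitations

* The anterior column edge (`B5`) is the least stable detection: at disk
  rows the dark trachea just anterior of the ALL can outscore the ligament
  itself, so the path oscillates by a few pixels (tests bound the median
  error at 2 px but tolerate a small tail).
* A cervical canal must be present and roughly vertical; the method does
  not apply below the cord's caudal end (cauda equina) and needs parameter
  retuning for thoracic/lumbar protocols or other scanners.
* Congenital fusions and transitional anatomy can mislabel C2; the manual
  canal-extent override is the supported recovery path.
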
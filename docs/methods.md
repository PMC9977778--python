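# Methods

## The detection model

`redlesion` detects red lesions — microaneurysms and hemorrhages — in retinal
fundus photographs.  The model of a red lesion is purely morphological: a
comparatively dark region whose boundary is approximately roundish.  No
vessel segmentation, optic-disc localisation, training data or colour-space
transform is involved; the only preprocessing is green-channel extraction and
CLAHE.

At every eligible pixel `p_{i,j}` the detector considers a circle of inner
radius `a0` and, for each of the four circle quarters (top-right, top-left,
bottom-left, bottom-right), probes seven angles `θ ∈ {0, π/12, …, π/2}`.
For each angle it pairs the pixel at radius `a0` (inner) with the pixel at
radius `a0 + d` (outer) along the same direction, with real-valued offsets
mapped to pixels by rounding half away from zero.  The angle is *satisfied*
when

    X(outer) − X(inner) > diff_th,

i.e. the farther point is lighter by more than the threshold — the signature
of looking outward across a dark region's boundary.  A quarter is a lesion
candidate when strictly more than `number_th` of its seven angles are
satisfied (at the defaults: at least 5 of 7).

Candidates are then paired laterally: a satisfied top-right quarter must find
a satisfied top-left quarter on the same row at or to its left (and
bottom-right ↔ bottom-left), which suppresses one-sided responses such as
vessel edges.  A pixel whose two top (or bottom) quarters are both satisfied
pairs with itself.  Otherwise the detector walks column by column toward the
partner side, starting at the anchor: the walk continues only while the
partner-side quarter at the current pixel is *dark* (mean intensity of the
quarter disc below `intensity_th`), succeeds as soon as the partner quarter's
conditions hold, and gives up after `max_search` columns.  For every
successful pair, the two partner quarter discs plus the `a0`-tall band
between the partner columns (above the row for top pairs, below for bottom
pairs) are painted into the lesion mask, which is finally intersected with
the field-of-view mask.

## Parameters

| name | default | meaning |
|---|---|---|
| `a0` | 10 px | inner probe radius; sets the lesion scale the detector targets |
| `d` | 3 px | radial gap between inner and outer probes |
| `number_th` | 4 | angle-count threshold (strict: >4 of 7 angles) |
| `diff_th` | 0.06 | minimum boundary intensity step, unit scale |
| `intensity_th` | 0.28 | quarter-disc mean below which a quarter counts as dark |
| `e_theta` | π/12 | angle ladder step (7 angles on [0, π/2]) |
| `max_search` | 3·a0 | lateral walk cap, px |
| `use_skip_optimization` | on | skip bottom-right (left) quarter where top-right (left) already fired |

All intensities live on [0, 1]; `diff_th` and `intensity_th` are only
meaningful after normalisation.  Raising `diff_th` or `number_th` makes the
per-quarter condition strictly harder, so the candidate set shrinks
monotonically — a property the test suite asserts.

The `max_search` cap and the fill-band height are not part of the published
parameterisation; the cap bounds walks through long dark vessels (unbounded
walks would both slow detection and elongate false detections), and the
band height matches the quarter radius.  Both are exposed in
`DetectionParams`.

## Preprocessing choices

The green channel carries the highest lesion/vessel contrast and is the
working channel; integer images are rescaled by their dtype maximum.  CLAHE
uses clip limit 0.01 and an 8×8 tile grid (common fundus-processing
defaults; the method's source gives none), and its output is clipped back to
[0, 1].

The field of view is delimited **on the raw green channel, before CLAHE**:
thresholding at 0.1, morphological closing, keeping the largest component,
then eroding with a disk of radius `a0 + d` so every retained pixel's whole
verification circle stays inside the imaged area.  Computing the mask after
CLAHE would fail, because CLAHE amplifies the black surround's noise above
any fixed threshold.  Erosion uses a Euclidean disk, matching the reach of
the probe points.  For full-frame synthetic images the FOV step can be
disabled; probe points that leave the image simply count as unsatisfied, so
border pixels degrade gracefully.

## Numerical choices

* The bracket mapping real offsets to pixels rounds half away from zero,
  with a 1e-9 tie tolerance: products like `13·sin(π/6)` are exactly 6.5 but
  float a few ulp to either side, and without the tolerance mirror-symmetric
  angle pairs would round to different pixels.  Exact-arithmetic checks
  (sympy) pin the half-cases.
* The default angle ladder is symmetric under θ → π/2 − θ, which makes the
  candidate maps exactly equivariant under left-right mirroring (and under
  up-down mirroring when the skip optimisation is off — the skip couples
  quarters 1/4 and 2/3 and is itself only left-right symmetric).
* The production candidate evaluation is vectorised shifted-array
  arithmetic over a NaN border; `redlesion.reference` keeps the naive
  per-pixel/per-quarter/per-angle loop, and the suite requires bit-identical
  candidate maps and masks on seeded synthetic images with the skip
  optimisation both on and off.
* Quarter darkness is the mean over the closed quarter disc of radius `a0`
  clipped to the image — the simplest statistic consistent with making a
  smaller `intensity_th` strictly harder to satisfy.
* Region matching in evaluation is greedy one-to-one by descending
  intersection-over-union, ties broken by smaller predicted area then scan
  order; components use 8-connectivity so diagonally joined lesion pixels
  stay one region.

## Evaluation protocol

`ioo(pred, gt)` is intersection-over-union,
`|∩| / (|gt| + |pred| − |∩|)`.  Region-level scoring matches predicted to
ground-truth components one-to-one and calls a ground-truth region a true
positive when its match reaches the IOO threshold (default 0.8); a
region-level true negative is ill-posed and never reported.  Pixel-level
SE/SP/ACC are counted inside the field of view.  Both accountings are
reported because either reading of sensitivity/specificity is defensible for
a lesion detector.

## What the synthetic generator emulates — and what it does not

`SynthParams` defaults define the study conditions: 384×384 frames, a bright
circular FOV on black, a smooth planar illumination gradient (amplitude
0.08), five elliptical lesions per image (radius 8–13 px, axis ratio ≤ 1.3,
boundary contrast 0.25–0.45, flat core with a one-pixel cosine-tapered rim
outside the exact ground-truth disc), three vessel distractors (smoothed
random walks, width 2–4 px, contrast 0.25, steered to keep a 26-px clearance
from lesions), and additive Gaussian noise (sd 0.01, about 2.5 grey levels
of an 8-bit image).  Lesions keep a 26-px (= 2·(a0+d)) boundary gap from
each other so ground-truth components never merge.  Vessels never enter the
ground truth: any detection on one is a false positive by construction.

The generator reproduces only the structure the detector's conditions test.
It has no optic disc, fovea, texture, colour, vessel branching or calibre
variation, and its vessels are wigglier than real retinal vessels — the
random walk can hairpin or nearly self-cross, enclosing dark wedges that are
locally indistinguishable from small round lesions.  Passing tests on this
material therefore demonstrate the geometry of the method (roundish dark
regions found, straight thin dark structures rejected, exact symmetry and
determinism), not clinical performance on photographs.

Two scale limits of the method itself are worth stating plainly.  First,
lesions with radius below about `a0 − 1.5` are structurally hard at the
default operating point: the probe arcs can straddle a small disc's boundary
only from the far side, which places the top-right candidates to the *left*
of the top-left candidates, the wrong order for the pairing rule.  Detection
at the defaults is reliable for radii from roughly 8.5 px upward.  Second,
sharp vessel bends are the dominant false-positive source — on the synthetic
suite they cost about one false region per image (measured 0.95–1.25 across
suite seeds, with sensitivity 0.95–0.98), which is also the regime the
method's published specificity figures reflect.

## Problem sizes used by the test suite

Oracle-equivalence checks run on ten 128×128 images (one lesion, two
vessels) with the skip optimisation in both states; threshold-monotonicity
on five 128×128 images; the shape-selectivity study and
`scripts/acceptance.py` on twenty 384×384 images with the default
conditions.  These sizes exercise every code path while keeping the whole
suite comfortably fast on one CPU.
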
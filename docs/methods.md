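# Methods

## The problem and the method

Per-frame CNN segmentations of the fetal thoracic wall in ultrasound sweeps
are frequently *discontinuous*: the wall is a thin, low-contrast annulus, and
each frame's prediction tends to miss arc-shaped stretches of it, with the
missing arcs varying from frame to frame. `mfcy` implements two
model-agnostic ensemble repairs that operate purely on prediction rasters,
plus their combination:

**Step operator.** All fusion is built on the element-wise step function
H_phi(x) = 1 if x >= phi else 0, applied inclusively (equality maps to 1).
Any model is first *normalized*: its probability output is binarized at
phi_norm = 0.5, so fusion always consumes {0,1} rasters.

**Multi-frame fusion (MF).** For a target frame t0, the neighborhood
T(a,k) = {t0, t0±a, ..., t0±ak} (2k+1 frames) is segmented frame by frame
and the binarized predictions are combined by thresholded voting: a pixel is
positive when the fraction of neighborhood frames voting for it is at least
phi_mf. With the defaults a=3, k=3 (7 frames) and phi_mf = 3/7 this is "at
least 3 of 7 votes". Because neighboring sweep frames are similar but their
prediction failures are not, voting fills in arcs any single frame missed.

**Cylinder fusion (CY).** The wall (TW), the cavity it encloses (TC), and
the whole thorax (WT = TW ∪ TC) are segmented by three independent models.
Since TW = WT − TC identically, the wall is reconstructed as

    CY = H_phi1(TW) ∪ H_phi2(WT − TC),

with the subtraction element-wise over {−1, 0, 1} and the two terms combined
as a logical union (defaults phi1 = phi2 = 0.5). The outer boundary is thus
pinned by the WT model and the inner boundary by the TC model even where the
direct TW prediction fails.

**MFCY.** MF is applied to each of the three structure stacks with a shared
threshold phi3 (default 3/7), then CY to the three fused masks.

### Reading of the MF voting rule

Taken verbatim, thresholding the *raw sum* of binary masks at phi < 1
degenerates to a union over frames, which would make the specific value 3/7
meaningless. The package therefore defaults to `mean` semantics — the vote
*fraction* is thresholded, so 3/7 means three of seven votes — and exposes
the verbatim rule as `literal_sum` for comparison. Both are tested. With a
partial neighborhood (frames dropped at the video ends), `mean` semantics
keeps phi_mf as a fraction of the *available* frames, preserving the voting
proportion rather than making the threshold unreachable.

### Neighborhood boundary handling

Near video ends some offsets in T(a,k) fall outside the video. The default
policy is `drop` (use only real frames; never fabricate data); `clamp` and
`mirror` are available for sensitivity analysis. Clamped or reflected
offsets can collide; indices are deduplicated so a neighborhood is always a
sorted set of distinct frames — a boundary frame is never given multiple
votes.

## Label derivation

Cavity and whole-structure labels are derived from the wall annotation
alone: the cavity is the set of background pixels not reachable from the
image border through background, computed as a 4-connected hole fill
(`scipy.ndimage.binary_fill_holes` with the cross structuring element), and
the whole structure is the filled wall. 4-connected background against an
8-connected wall is the standard duality that stops diagonal leaks through
wall corners. All enclosed holes count as cavity (annotation noise can split
it). A wall that encloses nothing — empty, or broken by a gap the fill
escapes through — yields an empty cavity with a `degenerate` flag instead of
an exception, so batch derivation over imperfect annotations completes and
reports. The triple is constructed cavity-first, so the identities
TW = WT − TC, WT = TW ∪ TC, TW ∩ TC = ∅ hold bit-exactly by construction.

## Metrics and cross-validation

IoU = TP/(TP+FP+FN), Dice = 2TP/(2TP+FP+FN), Precision = TP/(TP+FP),
Recall = TP/(TP+FN), all from exact pixel tallies. When both masks are
empty, every 0/0 ratio is scored 1 with an `empty-agreement` flag
(agreement on absence keeps batch means defined; flagged rows are reported
separately); a 0/0 against a non-empty counterpart is NaN with an
`undefined` flag.

Five-fold cross-validation groups by case by default, so images of the same
subject never straddle the train/test boundary; `video` and `image`
grouping are available. Groups are shuffled deterministically from the
seed, then assigned largest-first to the currently smallest fold, balancing
fold sizes up to the largest group (538 singletons give 108/108/108/107/107).
Fold summaries report the mean and the *population* (divide-by-n) standard
deviation of the five per-fold means. ΔIoU is the per-image IoU difference
between a fusion method and the single-frame baseline.

## The phantom: what it emulates and what it does not

No clinical data ship with the package, so experiments run on a synthetic
phantom that reproduces the *geometry and failure modes* the fusions
exploit, not ultrasound physics:

* **Video**: a bright elliptical ring (wall ≈ 9 px thick, outer radius
  ≈ 40 px on a 128×128 frame — a chest filling about two-thirds of the
  image) over a darker interior and background, drifting ~0.35 px/frame
  along a seeded direction with a gentle periodic radius wobble (the sweep
  moving through the chest), corrupted by multiplicative gamma speckle
  (SD 0.35) and one 25° attenuating shadow sector per frame.
* **Ground truth**: wall/cavity/whole masks computed analytically from the
  ring geometry, never from the rendered image.
* **Degraded predictions**: starting from a ground-truth mask, two random
  40° angular arcs of the boundary band (9 px deep — the full wall
  thickness, so wall arcs are severed while filled structures are only
  nibbled at the edge) are suppressed toward probability 0.05, the boundary
  is jittered by a random sub-pixel shift (±1 px), and Gaussian noise
  (SD 0.08) is added. Arc placement is keyed to (seed, frame_index), so
  neighboring frames fail in independent places — the premise of MF — and
  each structure model is degraded with an independent seed — the premise
  of CY. Arc-shaped boundary gaps were chosen because that is how failing
  CNN wall predictions actually look.
* **Baseline segmenter**: a deterministic classical model (Gaussian smooth
  σ=1.5, intensity threshold 0.5, removal of components under 64 px,
  distance-shaded soft output whose 0.5 level set is the cleaned binary
  mask) satisfying the model contract, so the pipeline runs end to end
  without any trained network.

What passing the phantom tests shows: the fusion algebra is implemented
exactly (bit-level oracle equivalence), and MF/CY/MFCY deliver their
designed directional effect — higher IoU and recall, lower precision than
single-frame prediction — when prediction failures are frame- and
model-independent. What it does not show: performance on real speckle,
anatomy beyond a single annulus, correlated failures across frames or
models, or any absolute clinical accuracy level.

## Numerical choices and degenerate inputs

* Thresholds compare inclusively (>=) everywhere, inherited from H_phi.
* Masks are uint8 over {0,1}; loaders reject PNG values outside {0,255} and
  name the offending file; probability-map TIFFs are clipped into [0,1]
  with a logged count; non-finite rasters are rejected naming the first
  offending pixel.
* Fold assignment ties (equal fold sizes) break toward the lowest fold
  index; group shuffling is a seeded permutation of the sorted group names.
* Seeds for per-video/per-structure simulation streams are derived through
  `numpy.random.SeedSequence`, keeping streams independent and all derived
  seeds below 2^31.
* Experiment CSVs are written with a fixed float format so identical runs
  are byte-identical.

## Problem sizes

The default experiment bank is 32 videos × 21 frames at 128×128 (672
evaluated frames per method), which characterizes the method means to well
under a percentage point of simulation noise; the test suite uses the same
bank once (shared fixture) and smaller banks elsewhere.

## Known limitations

* The phantom's single-annulus geometry cannot probe multi-structure scenes
  or failures correlated between the TW/TC/WT models.
* `literal_sum` voting is provided for completeness but degenerates to a
  union for thresholds below 1; conclusions in the docs use `mean`.
* Fold-size balance is only guaranteed up to the largest group when
  grouping by case or video.
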
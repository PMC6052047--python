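# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, and what its synthetic benchmarks do and do not show.

## Coordinate and angle conventions

Pixels are 0-based with x to the right (columns) and y down (rows).  Angles
are in degrees measured from the +x axis toward +y; headings live in
[0°, 360°), the raw ellipse tilt in [−90°, 90°).  One convention is used by
the generator, the detector, the ROI resampler and the trajectory output, so
fixture ground truth and tracker output are directly comparable.

## Detection

The background is the per-pixel arithmetic mean of the first `f_background`
frames, accumulated in float64.  A mean (rather than median) background is
cheap and exact for a stable arena, but every fish leaves a "ghost" of
magnitude ≈ contrast × (dwell time / f) at each pixel it visits.  With the
default contrast (~130 grey levels) and cruising speeds, a single pass over
a pixel lasts ~15 frames, so `f_background` defaults to 300: ghosts then stay
well below the default grey threshold `thr_g` = 20.  Short clips with
lingering fish need either a larger `f_background` (up to the clip length) or
a higher `thr_g` (the 20–50 range is reasonable).

Foreground is `|frame − Bm| > thr_g` — the absolute difference, so bright-on-
dark and dark-on-bright arenas both work; the one-sided comparison is
reserved for the descriptor's binarization, where it defines which pixels
belong to the body.  Components use 8-connectivity (thin diagonal bodies stay
connected) and must reach `thr_s` = 500 px².  Geometry comes from central
second moments: tilt = ½·atan2(2μ₁₁, μ₂₀−μ₀₂), semi-axes 2√λ± (exact for a
filled ellipse).  Degenerate (collinear) components fall back to the
bounding-box axis with a warning.

## Head resolution and ROI normalization

The fitted tilt is ambiguous by 180°.  Fish are wider toward the head, so the
body-box half with the larger foreground-pixel count is the head side; exact
ties fall back to recent motion direction (if a previous centroid is
supplied) and then to the intensity sum.  The full angle is the tilt or
tilt + 180°, whichever points into the resolved head half-plane — a total
mapping verified on fixtures: the resampled patch always has the head at +x.

The ROI is the anterior `head_fraction` (default 0.5) of the body box, padded
by `roi_pad` = 1.2 over the fitted semi-axes, sampled bilinearly along the
body axis directly at the output resolution (`p_r` = 100), then smoothed with
a Gaussian of `roi_smooth_sigma` = 2.5 output pixels.  The smoothing matters:
a bilinear resample carries a harmonic of the *source* pixel grid whose
orientation rotates with the fish, and without suppression that harmonic
leaks the original pose into the gradient histograms, eroding exactly the
invariance the normalization is meant to buy.  Samples with fitted aspect
ratio below `thr_e` = 3 are rejected as bent or overlapping; rejection is
monotone in bend amplitude by construction (bending only lowers the fitted
ratio).

## The masked spiral descriptor

Standard HOG choices the source material leaves open are fixed as the classic
defaults and exposed in `Config`: 9 unsigned orientation bins, magnitude-
weighted hard binning (no bin or cell interpolation), centered [−1, 0, 1]
gradients with zero borders, 9×9 px cells without overlap, 2×2-cell blocks at
1-cell stride, L2 block normalization with ε = 1e−10.  For a 100×100 patch
this yields an 11×11 cell grid (the 1-px remainder is ignored) and a 10×10
block grid.

Relevance masking keeps a cell iff its binarized-body pixel count is
≥ `p_c` = 10 and a block iff any member cell survives.  Binarization is the
strict one-sided test against the background-model mean (flipped for dark
fish).  The spiral emits blocks from the grid centre outward — starting at
the upper-left element of the central 2×2 for even grids, first step right,
turning clockwise on the image grid — and truncates/zero-pads to exactly
`p_b` = 34 blocks (1224 values), recording a `padded` flag so callers can
drop low-coverage samples.  Any fixed spiral convention preserves the
descriptor's purpose; this one is frozen and oracle-tested so features are
comparable across runs.

## Tracklets and crossings

Nearest-neighbour matching with three rules: per-object argmin (ties to the
lowest index), cancellation when two objects share an argmin, and
reinstatement of the closer claimant when it wins by more than `thr_d` =
30 px — the shared-argmin case is treated as a stationary-fish or
coincidental-distance situation, not a crossing.  A count change between
frames raises the crossing flag.  A maximum match distance (default 100 px)
prevents cross-arena jumps when a fish is lost.

The printed matching rules alone cannot keep a merged blob's tracklet from
continuing into one of the fish after the blobs separate, which would
contaminate tracklet purity — the property the whole identity stage depends
on.  Two guards close the gap: a detection whose area exceeds
`merge_area_factor` = 1.6 × the previous frame's median detection area is a
merged-blob suspect (matches into it are severed and its tracklet marked),
and a marked tracklet's match is severed at any transition with the crossing
flag up, so it cannot cross a split.  Marked tracklets and chains shorter
than 10 frames are discarded.  Crossing events pair the cleanly ended
tracklets (filtered by spatial proximity to the restart points) with the
tracklets that start when the crossing resolves.

## Identity association

The classifier is an RBF-kernel SVM with libsvm-style pairwise-coupled
probability outputs (C = 10, γ = 1/dim; both exposed).  Per-tracklet class
probabilities are the arithmetic mean of per-frame probabilities,
renormalized.  For each crossing, the flanking group whose shortest member is
longer trains (ties to the earlier group); assignment uses the Hungarian
algorithm maximizing Σp and is accepted only if every selected probability
strictly exceeds 1/N.  Accepted matches below `thr_p` = 0.6 are flagged for
manual review (there is no interactive correction here — only the flags).
Stitching sweeps events chronologically and repeats until a fixpoint; merges
concatenate frame spans (gaps across the occlusion are allowed from this
stage on) and pool samples, which only grow.  Merging is refused when the two
tracklets overlap in time.  The final classifier trains on the tracklet group
sharing a frame whose minimum member length is maximal; remaining tracklets
claim identities in order of confidence, with frame-conflicting or
sub-1/N-confidence claims left unlabelled, so no identity ever appears twice
on one frame.

## Evaluation metrics

With F fish and T processed frames ("tracked frames" = all processed frames,
the documented reading of an ambiguous denominator): a trajectory point is
*correct* if its nearest ground-truth fish is the trajectory's mate under the
majority-overlap Hungarian correspondence, *wrong* otherwise; absent points
are *missed*.  IA = correctly identified fish / identified fish (identified =
has a correspondence mate; correct = majority of its points agree with the
mate); CA = correct points / classified points; CrossFrequency = frames with
fewer than F detections / T; AccuracyRate = 1 − wrong/T; MissRate =
missed/(F·T); ErrorRate = wrong/(F·T).

## The synthetic generator

Fish are rigid teardrops (semi-axes 28×8 px, anterior 35 % wider than the
tail — which is also what makes head resolution work), painted with a
per-individual seeded spot field (12 spots blurred to σ = 2.2 px, ±60 grey
levels) in body-fixed coordinates on the anterior half, rotating rigidly with
the heading.  The body edge is feathered over ~1 px: real optics blur
outlines, and a hard-aliased edge injects pose-dependent gradient noise that
no camera produces and that dominates descriptor variance if present.
Motion is a heading random walk (σ = 0.06 rad/frame) at ~3.5 px/frame with
reflective walls; `crossing_bias` adds attraction toward the nearest
conspecific, released within 3 body lengths so encounters are transient
fly-throughs.  Ground truth records the blob's area centroid (the axis
midpoint plus the analytic teardrop offset, 0.35·a/4, toward the head) and a
visibility flag based on 1-px-dilated support intersection — the same
condition under which 8-connected segmentation merges two blobs.  Everything
derives from one seeded generator: same scene, same seed ⇒ byte-identical
frames and truth.

Default study conditions: a 480×480 px arena for 4 fish puts the default
scene's crossing frequency in the low-crossing regime of the multi-fish
recordings the method targets (~10–25 % of frames with fewer blobs than
fish); the end-to-end benchmark uses `crossing_bias` = 0.2 and 600 frames,
which lands CrossFrequency at ~20–46 % across seeds.

What passing on these fixtures does **not** show: robustness to body
undulation (only a rigid parabolic bend exercises the aspect-ratio reject),
lighting drift, shadows, water-surface distortion, camera noise, or texture
change over weeks of growth.  The fixtures isolate the geometric and
combinatorial claims — pose-invariant features, pure tracklets, correct
association — not photometric robustness.

## Problem sizes and runtime choices

The shipped benchmarks are scaled to desk hardware: the end-to-end check runs
4 fish × 600 frames × 5 seeds (~1 minute total), the descriptor-robustness
check 5 individuals × 50 headings, and oracle-equivalence checks use ≤ 7
objects or ≤ 6×6 matrices with exhaustive enumeration as the reference.
Larger runs only change runtime, not any fixed parameter.

## Known limitations

* The mean background model assumes a stable arena; slow illumination drift
  is not tracked (by design — the target setting is a laboratory tank).
* Fish lost at low contrast or small area simply go missing (raising
  MissRate); there is no motion-model extrapolation, which is deliberate:
  appearance, not kinematics, carries identity here.
* Simultaneous crossings that keep the total blob count constant can evade
  the count-based crossing flag; the area guard catches the common cases.
* `evaluate` needs ground truth with per-frame positions; the majority-
  overlap correspondence assumes trajectories are mostly right — it cannot
  fairly score output that is wrong more often than not.
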
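# Methods

## The detection model

The detector assumes that over one cardiac cycle the coronary arteries
move and change width smoothly, so any reasonable frame representation
traces a closed loop in feature space with the two pole states
(vasodilation/vasoconstriction) at maximal distance from each other.
The N×N pairwise-similarity matrix of such a sequence is periodic along
both axes; cells pairing opposite poles are local minima of similarity
(maxima of difference). The algorithm therefore reduces keyframe
detection to a windowed extremum search on that matrix followed by a
greedy temporal-separation filter.

No neural network is trained or run inside this package. The w+-space
encoder that motivates the cosine metric is treated strictly as an
external embedding provider: the `external` backend reads its saved
per-frame codes (one row per frame, e.g. 18×512 = 9216 columns) from
delimited text. The built-in backends (`flatten`, `downsample`, `pca`)
are simple, deterministic stand-ins adequate for sequences where the
vessel dominates the frame-to-frame signal.

## Comparators

* **cosine** — on embedding rows; similarity orientation (keyframe
  pairs are matrix minima).
* **l1** — raw sum of absolute pixel differences, no normaliser
  (an optional per-pixel mean exists but defaults off); difference
  orientation (keyframe pairs are maxima).
* **psnr** — 10·log₁₀(L²/MSE) with MSE the mean squared per-pixel
  difference; identical frames give +∞, which compares greater than any
  finite value, so "most similar" stays well ordered. Inside the
  pairwise matrix, +∞ cells are stored as (finite maximum + 1): the
  matrix stays CSV-exportable and a cap can never become a minimum, so
  detection is unaffected.
* **ssim** — computed over a **single global window** (one mean,
  variance and covariance per frame), with population (1/n) moments and
  constants C1 = (0.01·L)², C2 = (0.03·L)². The population convention
  makes the constant-frame closed form (2cd+C1)/(c²+d²+C1) exact, which
  the tests assert at 1e−12. The common 11×11 Gaussian-windowed
  mean-SSIM is deliberately out of scope — the pipeline needs the plain
  whole-frame statistic, not its perceptual refinements.

All four comparators are symmetric; the matrix is filled once per
unordered pair and mirrored. The dynamic range L comes from the
sequence (bit depth of the input files; 255 for 8-bit), because PSNR
and SSIM are meaningless without an explicit range.

## Extremum search and suppression

A cell (i, j) is a candidate iff its value is **strictly** more extreme
than every other cell of the full symmetric matrix within Chebyshev
distance `window_radius` (default 2, i.e. a 5×5 neighbourhood).
Strictness means plateaus — in particular constant sequences — yield no
candidates at all. Candidates are restricted to the upper triangle with
j − i ≥ `min_separation`: the mirrored cell is the same event, and a
systole/diastole pair cannot be adjacent frames.

**Border policy.** `find_local_extrema` clips the window at the matrix
border by default, which is the natural completion for arbitrary
matrices. The full pipeline (`detect`), however, passes
`require_full_window=True`, excluding cells whose 5×5 window leaves the
matrix: a border cell competes against a truncated neighbourhood, and a
sequence that ends (or begins) while still approaching a cardiac pole
would otherwise always produce a spurious detection at its first/last
frames — the truncated trend's endpoint masquerades as an extremum. The
price is that a true extreme lying within `window_radius` frames of the
sequence ends cannot be detected (the phantom's frame 0 is the standing
example); the benefit is that every reported keyframe is certified
against a complete neighbourhood. On clinical-length sequences (tens of
frames spanning several cycles) losing the two end windows is cheap;
zero-cost false positives are not.

Suppression processes candidate pairs most-extreme-first (ascending
value for similarity orientation, descending for difference; ties
broken lexicographically by (i, j) for determinism). Each endpoint
frame is accepted iff its index distance to every already-accepted
frame is ≥ `min_separation`; the threshold is strict ("closer than" is
suppressed, exactly at the threshold is retained), with default 2.

## The phantom generator

The phantom emulates the geometry of a DSA heartbeat: a dark
curvilinear vessel (cubic-spline centerline through 5 control points,
Gaussian cross-section of width `base_width` = 4 px) on a brighter
background (level 200) with smooth large-scale texture (amplitude 10)
and optional per-frame Gaussian noise. Frame t has phase
φ(t) = 2πt/period + `phase_offset`; the width scales by
1 + 0.35·sin φ and the centerline displaces 2 px·sin φ along its
normals. The default `phase_offset` = −π/2 puts the poles exactly on
integer frames, so ground-truth labels have no sampling ties. Labels
mark the argmin and argmax of the sampled width within each *complete*
cycle; a flat (non-pulsating) signal gets no labels, and a trailing
partial cycle gets none either. Intensities are quantised to 8-bit
levels at generation, making the PNG round-trip lossless.

What the phantom does **not** emulate: contrast-agent wash-in/wash-out,
branching vasculature, table/patient motion, X-ray quantum noise
statistics, or background anatomy that moves with the heartbeat.
Passing the phantom tests therefore shows that the matrix/extremum/
suppression machinery is correct and noise-tolerant, not that any
particular embedding separates vessel from background on clinical
images — on the phantom the pixel-domain comparators succeed too,
whereas on clinical data that separation is precisely what the learned
embedding contributes.

## Default problem sizes

The recovery studies run at 30 frames (period 10, noise-free) and
60 frames (period 20, noise σ = 2% of the dynamic range, 20 replicate
seeds) at 128×128 resolution — two to three full cycles, enough for
every interior pole to be certified by a full window, while keeping a
complete simulate–detect–evaluate sweep at a few seconds per sequence.
Evaluation uses a ±1-frame matching tolerance (greedy one-to-one,
nearest pairs first, ties to the earlier truth frame): annotating the
exact pole frame is inherently ±1 ambiguous on a sampled sinusoid.
Precision and recall with empty denominators are reported as NaN, never
coerced to 0 or 1.

## Numerical conventions

* Cosine values are clipped to [−1, 1] against floating-point overshoot;
  a zero-norm vector raises a degenerate-input error rather than
  returning NaN.
* PCA embeddings use a full SVD with the largest-magnitude-loading-
  positive sign convention, so repeated runs are bit-identical.
* Frame order on disk is a numeric-aware filename sort (`f2` before
  `f10`); DICOM series use `InstanceNumber` when every file has one.
  Indices are 0-based everywhere.
* All randomness (phantom texture/noise, PCA seed) flows from explicit
  integer seeds; identical inputs and seeds give byte-identical outputs.

## Known limitations

* Keyframes within `window_radius` frames of the sequence ends are
  undetectable by design (see border policy).
* The detector labels frames as extreme-phase but does not classify
  which pole is systole and which diastole.
* Sub-frame (interpolated) phase estimation is out of scope; the
  temporal resolution is one frame.
* Sequences shorter than ~1.5 cycles leave too few interior cells for a
  reliable extremum; the phantom config refuses fewer frames than one
  full period.
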
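# Methods

This note records the models, numerical choices and open design
decisions behind `echostrain`, and states precisely what the synthetic
phantom does and does not demonstrate.

## Contour regression model

**Tokenisation and hierarchy.** A pre-processed clip (3, 64, 224, 224)
is partitioned into 2×4×4 cubes, each flattened and linearly projected
to the embedding width, giving a 32×56×56 token grid: every token
already spans two frames of wall motion.  The encoder then runs three
stages; each stage begins with a 2×2 spatial patch merge (concatenate
four neighbours, LayerNorm, linear 4C→2C without bias) and continues
with an even number of transformer blocks.  Placing the merge at the
stage *entry* — so blocks operate on the 28×28, 14×14 and 7×7 grids and
the emitted features F1–F3 are the block outputs at those resolutions —
is the package's design choice: it produces the canonical 32×28×28 /
32×14×14 / 32×7×7 feature shapes from a 224×224 input, and it is the
layout under which the calibrated configuration (below) reproduces the
published compute profile.  The temporal axis is never downsampled.

**Attention.** Blocks are pre-norm residual transformer blocks with a
GELU MLP.  Self-attention runs inside 8×7×7 token windows,
`softmax(QKᵀ/√d + B)V`, with B a learned per-head relative-position
bias table of (2·8−1)(2·7−1)(2·7−1) = 2535 entries indexed by the 3D
offset between token pairs.  Every second block cyclically shifts the
grid by (4, 3, 3) tokens before windowing and shifts back after; an
additive −∞ mask forbids attention between token pairs that were
wrapped in from opposite borders (and to zero-padding tokens when a
grid axis is not a multiple of the window).  On axes the window covers
entirely, the window is clipped to the grid and the shift is dropped —
at the 7×7 stage this makes spatial attention global within the plane
while the temporal axis still partitions into four groups of eight.

**Configuration calibration.** The depth/width setting is not uniquely
determined by the feature shapes, so the default was fixed by a grid
search over (embed_dim, depths, expansion) against the published
compute profile of the full model — 121.38 M parameters and 574.53
GFLOPs for one 64-frame chunk — using the package's own analytic
counts.  The selected configuration, embed_dim 128, depths (8, 6, 6),
heads (8, 16, 32), expansion 4, gives 121.09 M parameters and 572.23
GFLOPs (8.94/frame), both within 0.5 %.  FLOPs are counted as
multiply–accumulates (1 MAC = 1 FLOP) over all matmul-backed layers,
including the QKᵀ and attention-value products; normalisations,
softmax and residual adds are excluded.  This is the convention under
which the published per-frame figures of the comparison models are
reproduced by their known architectures.

**Fusion and head.** Each stage output is refined per frame by a 3×3
convolution to D = 1024 channels; F3′ is nearest-neighbour upsampled
×2 and added to F2′, the sum upsampled ×2 and added to F1′ (bilinear
upsampling is a config option).  Global average pooling gives one
1024-vector per temporal step; the 32 steps are linearly interpolated
(half-frame-centre convention) to the 64 clip frames *before* the
head, the cheapest operator producing one contour per frame.  The
linear head emits 98 scalars per frame, read as 49 x- then 49
y-coordinates — a 49-point contour must carry 98 scalars for
dimensional consistency.  The head output is multiplied by a fixed
`output_scale` (the model-frame side, 224 by default) and its bias is
initialised at 0.5, i.e. predictions start at the frame centre; this is
standard coordinate-regression practice and keeps head parameters on an
O(1) scale so the optimiser step size is width-independent.

**Loss.** L = (1/T) Σₜ (1/49) Σᵢ ‖yₜᵢ − ŷₜᵢ‖²; strictly convex in the
predictions, invariant to joint frame permutations.

**De-chunking.** Videos are cut into 64-frame chunks starting at
0, 54, 108, … (10-frame overlap; a chunk running past the end repeats
the last frame).  On overlapped frames the *later* chunk's prediction
wins — it has more forward context — making stitching deterministic.

## Training

Adam with learning rate 1e-4, β₁ = 0.9 (the stated "momentum"; Adam
has no classical momentum term), β₂ = 0.999, and weight decay 1e-4
applied in coupled L2 form.  No learning-rate schedule.  Augmentation
draws one photometric and one geometric transform per clip, applied
identically to all frames and pushed through the contour coordinates:
additive brightness noise with variance 75 on the 8-bit scale (read as
σ = √75 ≈ 8.66; a σ = 75 reading is selectable via
`brightness_mode="sigma"`), contrast scaling 1 ± U(0, 0.3) about the
clip mean, shift up to 6.25 % of the side, isotropic scale within
±20 %, rotation within ±40° about the frame centre.  Points pushed
outside the frame are clipped to its boundary so loss targets stay
finite.  The toy convergence experiment in the test-suite (width-8
encoder, 20 phantom clips of 16 frames at 64×64) uses learning rate
1e-3: narrow models tolerate proportionally larger steps, and at 1e-4
the centre-initialised head cannot traverse the coordinate range within
50 epochs at this scale.

The engine underneath is a compact numpy reverse-mode autodiff tape
(float32 by default; float64 selectable for finite-difference gradient
checks, which the suite runs for every primitive).  Single-threaded
numpy makes runs with a fixed seed bit-reproducible.

## ED/ES detection and strain

**Length series.** Contour length is the chord sum over the 48
consecutive segments, optionally scaled by mm/px; the series is used
raw — no smoothing at any point.

**Dynamic program.** The detector selects an alternating keyframe
sequence ED₁ < ES₁ < ED₂ < … maximising

    Σ pairs (L[ED] − L[ES])  −  λ · (number of keyframes),

with consecutive keyframes at least d_min frames apart.  Defaults:
d_min = 0.15 s × frame rate (a lower bound on how fast a phase can be
traversed; 3 frames if the rate is unknown) and λ = 0.5 ×
median |ΔL| × d_min, which scales with both the series units and its
frame-to-frame noise, so detection is invariant to adding a constant to
or uniformly rescaling the lengths.  Because the score of a prefix
ending in an ED (or ES) at frame t depends only on t, a two-state
recurrence with running prefix maxima finds the exact global optimum in
O(T); the test-suite verifies equality with exhaustive enumeration of
every admissible chain on series up to length 40.  Ties resolve to the
earliest frame.  A constant series admits no positive-score chain and
returns no pairs.  This formulation is a reconstruction: it is globally
optimal and needs no peak-prominence tuning, but the exact cost terms
of the original are not public.

**Estimators.** `dp`: per-pair strain 100·(L_ES − L_ED)/L_ED at the DP
keyframes, averaged across pairs (the mean is applied uniformly, though
only the pairwise competitor states it explicitly).  Each ED is paired
with the following ES only.  `pairwise_extrema` and `mean_length` use
prominence-filtered local extrema (explicit, tunable parameters — that
is their documented weakness) and differ in whether strains or lengths
are averaged.  Shortening is negative by clinical convention.
Multi-view GLS is the arithmetic mean across views, and model-vs-expert
comparison uses (model − expert)/expert.

**Noise sensitivity.** Reading single-frame lengths at detected
extremes makes the DP estimator noise-inflating: with per-frame length
noise σ, selecting the maximal/minimal frames biases |GLS| upward by a
few times 100·σ/L₀.  At σ = 2 % of L₀ on the default phantom (2 cycles
of 40 frames) the measured bias is ≈ −3.7 strain-points, and no
estimator can do much better from the same data: the per-pair
uncertainty floor is 100·σ√2/L₀ ≈ 2.8 points and the Cramér–Rao bound
for the cosine amplitude from all 80 frames is ≈ 0.6 points.  The
corresponding acceptance check is therefore expected to fail at a
0.5-point tolerance; the noiseless round-trips are exact to 1e-6.

## Evaluation statistics

Dice = 2|A∩B|/(|A|+|B|) and IoU = |A∩B|/|A∪B| with the both-empty = 1,
one-empty = 0 convention.  Hausdorff distances operate on foreground
pixel centres of full area masks (not contour polylines), so magnitudes
are comparable to area-mask evaluations; the unit (px or mm) is carried
explicitly.  The ICC is the two-way mixed-effects, absolute-agreement,
single-measurement variant ICC(A,1) with its F-based 95 % CI (computed
via pingouin and cross-checked in the tests against a raw ANOVA
mean-squares oracle); a systematic offset between methods strictly
lowers it.  Bland–Altman reports bias = mean difference and
LOA = 1.96 × sample SD of differences, with the plotting data
returned.  ROC analysis labels impaired LV function as expert
GLS > −16 % and normal as < −18 %; values between the thresholds are
excluded from the respective arm, and the model's GLS is the score
(sign-flipped for the normal arm).

Rasterisation of a 49-point contour closes the polygon with the basal
segment (point 48 back to point 0) and fills pixels whose centres fall
inside (even-odd rule, which also resolves self-intersections); a
contour enclosing less than half a pixel of area yields an empty mask.

## Synthetic phantom

The phantom emulates the geometry and first-order appearance of an
apical view: a dark half-elliptical cavity (long-axis/half-base ratio
2.2) inside bright tissue (gray level 200), softened by a Gaussian
blur of 1.5 px and modulated by spatially correlated multiplicative
Rayleigh speckle (mean 1, blend weight 0.4).  The contour follows
L(t) = L₀(1 − s(0.5 − 0.5 cos 2πt/F)) with defaults L₀ = 260 px,
s = 0.18 (the middle of the normal clinical GLS range), two cycles of
40 frames at 50 Hz (0.8 s period ≈ 75 bpm) and 0.4 mm/px spacing — a
typical clinical acquisition.  The 49 truth points are sampled at equal
arc length and rescaled so their chord-sum length equals L(t) to
machine precision, making GLS = −100·s exact by construction.  Geometry
is a deterministic function of the configuration; the seed drives only
speckle (and the optional Gaussian noise of standalone length curves),
so phantoms differing only in seed share identical truth.

What passing phantom tests shows: the pipeline's bookkeeping
(geometry, coordinate mapping, chunk stitching), the exactness of the
DP optimum, and that the architecture can learn contour regression on
in-distribution data.  What it does not show: performance on real
ultrasound — the phantom has no probe sector, valves, dropout,
reverberation, out-of-plane motion, foreshortening or pathology, its
motion is perfectly periodic, and its speckle is only a first-order
statistical stand-in.

## Problem sizes used by the test-suite

Forward-pass contracts run a width-8 encoder on one full 64×224×224
chunk; training convergence runs 20 phantoms of 16 frames at 64×64 for
50 epochs; DP-vs-enumeration runs 100 seeded series of length ≤ 40
with d_min = 5; metric identities use 1000 random 12×12 mask pairs and
100 Hausdorff triples.  These sizes keep the whole suite at a few
minutes on one CPU core while exercising every contract at full
fidelity.

## Known limitations

* No pretrained weights are shipped; full-size training is out of scope
  (the full configuration is instantiated only analytically).
* AVI/MP4 input requires an ffmpeg-backed imageio plugin at runtime;
  DICOM and `.npz` paths have no such dependency.
* The DP detector assumes each ED precedes its ES within one cycle and
  computes ED→ES strain only; ES→next-ED (lengthening) segments are not
  scored.
* Self-intersecting predicted contours are rasterised with the even-odd
  rule rather than rejected.
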
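# Methods

## Problem setting

Patient-specific QA for VMAT compares the dose a machine actually delivers
for a plan against the planned dose, usually summarized as gamma passing
rates (GPR) at %/mm criteria. `vmatqa` implements the virtual variant: a
convolutional model predicts the nine-criterion GPR vector of a plan from
images derived from the plan itself — three isocenter dose planes, the MLC
leaf position map (MLPM), or a cylindrical surface dose — so that fragile
plans can be flagged without a measurement session. The package contains the
whole chain (plan I/O, MLPM, gamma, model, training protocol) plus a
synthetic cohort generator that stands in for clinical data.

## MLPM construction

`build_leaf_matrix` stacks the 120 leaf coordinates of each control point
into a 120×n matrix (bank A leaves 1–60, then bank B leaves 1–60). The
closed-state coordinate of a pair is taken as the pair midline averaged over
the control points at which the pair's gap is within the closure tolerance
(0.5 mm, the scale of a dosimetric leaf gap); for a pair that never closes,
the midline over all control points is used as the junction estimate. The
map value is the *absolute* distance of each leaf tip from that coordinate —
the closed state is exactly 0 regardless of where on the travel axis the
pair parks. Signed alternatives (per-bank signed offsets) were considered
and rejected: the two bank blocks already separate the signs spatially, and
an absolute map keeps the all-closed plan at exactly zero.

Leaf pairs whose gap never exceeds the tolerance anywhere in the cohort are
dropped from the map ("always closed in all cases"); with the generator's
five designated closed pairs this reduces 120 rows to 110. During
cross-validation the exclusion set is recomputed on the training plans only
and frozen for validation/test, avoiding leakage; the generator guarantees
that every non-designated pair opens in every plan, so the set is stable
across splits. Plans shorter than the configured map width are right-padded
with zeros (padding must not fabricate leaf motion); longer plans are
rejected rather than resampled. For network input the maps are divided by
the cohort-wide maximum displacement, giving values in [0, 1].

## Gamma engine

Global gamma with the reference maximum as normalization dose, the threshold
(default 10%) applied to the reference, 2D on the detector plane (the labels
emulate a planar/array measurement). Numerical parameters, which commercial
QA software does not disclose, are fixed as: evaluated dose bilinearly
interpolated on a fine lattice whose step is the pixel spacing divided by
the smallest integer that brings it to ≤ 0.1·DTA; exhaustive minimum over
all lattice offsets within 3·DTA, with two exactness-preserving speedups
(offsets visited in increasing spatial order; a point is retired once its
current γ² is below the spatial term alone). When the nine criteria are
evaluated together, all of them share the lattice of the tightest DTA so a
looser criterion searches a superset of a tighter criterion's candidates —
this makes the monotonicity of GPR in both tolerances hold by construction
rather than approximately. The engine is verified against an independent
brute-force search written in the test suite.

## Network and training

The architecture is fixed: per input branch, Conv3×3 (same-padded, 16
channels) → MaxPool3×3/3 → Conv3×3 (valid) → MaxPool → Conv3×3 (valid) →
MaxPool → flatten → affine to a 20-d embedding; branch embeddings fused by
elementwise addition; shared ReLU → BatchNorm → Dropout(0.3) → Affine(20→20);
nine parallel Affine(20→1) heads, one per criterion. Design points worth
recording:

* **Fusion by addition after the embeddings.** The addition layer's 20-wide
  output only makes sense summing the 20-d branch embeddings; summing the
  1-d head outputs would contradict that width. Parameter counts are
  unaffected by the placement.
* **Nine separate 20→1 heads** (21 parameters each) rather than one 20→9
  affine — equivalent in expressiveness, but it keeps the per-criterion
  parameter accounting explicit.
* **BatchNorm carries 2 learnable parameters per feature** (40 trainable for
  20 features) plus running statistics; framework-specific accountings that
  fold in the running buffers are not reproduced.
* **No activations inside the branches** — max pooling is the only
  within-branch nonlinearity; the shared trunk holds the single ReLU.
* Initialization is Glorot-uniform, seed-controlled, with two deliberate
  bias choices: the per-branch embedding biases start at +0.1 so the fused
  pre-ReLU features are mostly alive at the start (with batch-4 training,
  runs whose fused features die early can end up adopting a useless early
  epoch), and the output-head biases start at 0.9, the unit scale of a
  typical passing rate (Adam moves each weight by roughly the learning rate
  per step, so crawling from 0 to ~0.9 would consume most of the epoch
  budget). Labels are scaled to GPR/100 for training and reported in
  percent.
* BatchNorm normalizes with the biased batch variance but tracks the
  *unbiased* variance in its running (inference) statistics — with batches
  of 4 the biased estimator understates the population variance by a
  quarter, which visibly skews inference-mode predictions.

The layers are implemented directly on NumPy with hand-written backprop
(conv as nine shifted tensor contractions, inverted dropout, train-mode
batch-norm backward) and an Adam optimizer (β₁ 0.9, β₂ 0.999, ε 1e-8). At
this model size (tens of thousands of parameters) this is fast enough on one
CPU and makes the whole pipeline bit-reproducible for a fixed seed; gradient
correctness is pinned by per-layer finite-difference tests and an end-to-end
wiring check.

Training protocol: Adam at 0.001, batch 4, 200 epochs, MSE averaged
uniformly over the nine unit-scaled outputs (the protocol names no loss; MSE
is the standard choice for multi-output regression). The adopted weights are
those of the epoch with the smallest validation loss; ties break toward the
earlier epoch (less optimized against the validation set). Data are split
3:1 train/test with 20% of the training portion as validation, assigned by
seeded shuffle without stratification; cross-validation uses four folds and
reports per-criterion MAE, Pearson r (computed on the pooled test cases of
each fold, then averaged over folds) and the fraction of predictions within
±3%, each as mean ± sample SD across folds. A fold with zero variance in
either vector reports r as undefined-with-flag rather than NaN.

## Synthetic cohort generator

No public patient-QA cohort with per-plan MLC sequences and measured GPRs
exists, so the generator creates one with the statistical structure the
method assumes. What it emulates, and how:

* **Plans:** single 360° arcs, 178 control points (clinical scale), two
  60-leaf banks at 2.5 mm uniform leaf width, five designated peripheral
  pairs that never open, elliptic aperture envelope across the bank with
  smooth random gap/midline trajectories, leaf travel capped per control
  point (5 mm default), cumulative meterset from random positive increments.
  Per-plan aperture complexity is drawn from ranges (mean gap 9–40 mm,
  jitter 2–8 mm) so the cohort spans simple to heavily modulated plans.
* **Dose:** gantry-angle-weighted accumulation of the binary aperture
  projected through an isocentric grid (2 mm), followed by a 2.5 mm-σ
  Gaussian penumbra blur and scaling to the prescription dose. This is a
  fluence-projection toy, not transport: no attenuation, scatter, or
  heterogeneity. Its role is to give dose images and labels a common,
  physically sensible origin.
* **Delivery errors:** a per-plan latent severity (mostly small, 15% chance
  of a large draw) scales three components — a systematic gap error with
  random sign but narrowly distributed magnitude (≈0.4 mm, the calibration
  scale of a dosimetric-leaf-gap error), per-leaf noise whose σ grows with
  leaf speed between control points (fast leaves position worse), and an
  output-scale factor near 1. The zero model reproduces the planned dose
  bit-for-bit.
* **Labels:** global 2D gamma on the coronal isocenter (detector) plane
  between planned and delivered dose, at all nine criteria.

Two emergent properties carry the learnable signal. First, a fixed-scale gap
error costs small-aperture plans far more dose accuracy than large-aperture
ones, so complexity — visible in both the MLPM and the dose planes — drives
expected GPR. Second, the velocity coupling makes jittery leaf motion
(explicit in the MLPM, nearly invisible in the integrated dose) an
additional GPR predictor, which is what gives the MLPM-augmented variant its
edge over the dose-planes-only variant. The per-plan severity draw is
irreducible noise, keeping held-out correlations well below 1, as in real
cohorts. Label ranges were calibrated once to the intended study conditions:
3%/3 mm mostly 90–100%, 1%/1 mm broadly 70–100% with a long lower tail.

What passing tests on this cohort do **not** show: accuracy on clinical
data. The simulator has no TPS modeling, no detector geometry, no
measurement noise model, and its error taxonomy is three-dimensional where
real delivery errors are not; results on it characterize the method's
mechanics (shapes, protocol, trainability, input ranking), not clinical
performance.

## Problem sizes

Clinical-scale shapes (178 control points, 68×146/64×200/143×242 planes,
110×178 MLPM, 220×680 surface) are used for all architecture and MLPM
checks. End-to-end training experiments run at a reduced desk scale chosen
as the package's standard experiment size: 96 plans, 60 control points,
44³ dose grid at 2 mm, 51×51 planes (the smallest side length the three
conv+pool stages admit) and a 110×60 MLPM; training experiments use a
single 3:1 split per seed, with the 4-fold protocol exercised at small n.

## Surface (phantom-like) input

How the published surface dose image is constructed from a phantom
recalculation is not specified anywhere usable, so the package defines it
as: trilinear sampling of the dose grid on a cylinder around the
superior–inferior axis through the isocenter (default radius 105 mm,
diode-array-like), unrolled to rows = 220 axial mm × columns = 680 azimuth
bins, zeros outside the grid. It reproduces the expected input geometry; it
is a stated stand-in, not a reconstruction of any vendor's format.

## Numerical choices and degenerate inputs

* Closure tolerance 0.5 mm everywhere a "closed" decision is made.
* Crossed leaf pairs after error perturbation collapse to their midpoint.
* The all-zero MLPM normalizes with constant 1 (no 0/0).
* Gamma on an all-zero reference, or with every point under the threshold,
  raises a degenerate-input error instead of returning an empty mean.
* A constant-label cohort triggers a warning flag (correlation undefined
  downstream).
* Non-finite training or validation loss aborts with a diverged-training
  error.

## Known limitations

* The dose model's simplicity means MAE/r values on synthetic cohorts are
  not comparable in absolute terms to measurement-based studies.
* Uniform 2.5 mm leaf width (real HD-MLCs mix 2.5/5 mm); no
  collimator/couch rotation; single-arc plans only.
* The gamma engine is 2D global; local gamma and 3D gamma are out of scope.
* Bit-reproducibility holds per machine/BLAS build, not across platforms.
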
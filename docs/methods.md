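# Methods

## Problem and scope

The pipeline addresses binary discrimination of rare uterine sarcomas
(positive class; includes STUMPs) from common benign leiomyomas (negative
class) on preoperative multi-sequence MRI. The clinical difficulty it
models: sarcoma margins are typically irregular and their T2 signal high
relative to myometrium, but degenerated leiomyomas mimic both features.
The package implements the full computational chain — data model,
augmentation, cross-validated multi-model training, ensembling, scoring,
combination search, and evaluation statistics — and a synthetic cohort
generator, because clinical cohorts of this kind are not redistributable.
Results on phantoms validate the *pipeline*, not clinical performance;
see "What the phantoms do and do not show".

## Cohort model

Hierarchy: patient → study (examination) → series (one sequence type) →
slice. Fifteen sequence types form a closed enumeration (ADC, DWI,
dynamicaxi, dynamicsag, fsT1axi, fsT1CEaxi, fsT1CEcor, fsT1CEsag, fsT1sag,
fsT2axi, T1axi, T1sag, T2axi, T2cor, T2sag). The *patient* is the
cross-validation unit — all studies of a patient share a CV group, so
models are never evaluated on patients they trained on. The *study* is the
prediction unit: positive patients may carry several examinations, each
predicted separately. The splitter balances per-class slice totals across
groups with class-stratified greedy largest-first bin packing (patients
sorted by descending slice count, each placed into the lightest group;
ties broken by a seeded shuffle). This is deterministic and near-optimal —
provably optimal on the documented reference toy, and within one patient's
slice count of the brute-force optimum in general — but it is a heuristic,
not an exact partitioner. Sequence composition of the groups is
deliberately not balanced.

## Phantom generator

A slice is a uniform background (myometrium proxy) plus an elliptical
tumor whose boundary radius is perturbed sinusoidally:
r(θ) = 1 + 0.25·m·sin(9θ + φ), with m ∈ [0,1] the margin irregularity.
Inside the mask, intensity is background + gain·t2, with t2 ∈ [0,1] the
relative signal level and (background, gain) a per-sequence contrast
lookup — sequence identity never changes geometry, only contrast, because
geometry is patient-level truth. Heterogeneity (degeneration proxy,
h ∈ [0,1]) adds a Gaussian-smoothed random texture of s.d. 35·h intensity
units inside the mask; acquisition noise is i.i.d. Gaussian. Slices
off-centre in a series shrink the cross-section as an ellipsoid cut would.
Images are 8-bit grayscale PNG, default canvas 128×128 (tests use 64,
configurable to 512); bounding boxes are 0-based half-open pixel
coordinates.

Patient-level draws: sarcoma-group patients get t2 ~ N(0.80, 0.05) clipped
to [0.65, 0.95], margin ~ U(0.55, 0.95), heterogeneity ~ U(0.5, 0.9);
leiomyomas t2 ~ N(0.20, 0.05) clipped to [0.05, 0.35] with low margin and
heterogeneity unless a sub-phenotype is drawn — degeneration only (33%),
irregular margin only (5.5%), both (4.5%) — which raises the corresponding
feature into the sarcoma range. Tumor axes are U(35, 85) mm at an emulated
160 mm field of view. Default availability is 98.0% (T2axi), 98.4%
(T2sag), 96.5% (DWI) and 75% for the other twelve sequences; every patient
is guaranteed at least one sequence. Class counts are exact, not
stochastic; availability and phenotypes are Bernoulli draws verified at
n = 5,000 within binomial 3σ. A fixed seed yields byte-identical cohorts.

### What the phantoms do and do not show

They reproduce class imbalance, availability structure, sub-phenotype
rates, multi-study positives, and the two discriminative feature axes
(signal level, margin/texture) with controllable separation — enough to
test every pipeline contract and to verify that learning, aggregation and
ranking behave correctly when the signal is known. They do not model MR
physics, anatomy, partial-volume effects, inter-institution contrast
variation, or realistic feature overlap; passing tests therefore says
nothing about clinical accuracy on real MRI.

## Augmentation and pools

Transforms: horizontal/vertical flips, rotation within ±20°, zoom in
[0.9, 1.1], multiplicative brightness in [0.8, 1.2] (magnitudes are
package defaults; bilinear interpolation, reflection padding at borders).
The tumor bounding box is tracked through every transform as the
axis-aligned envelope of its mapped corners; a draw that pushes the tumor
off-canvas is re-drawn a bounded number of times. Crops always contain the
bbox centre and the maximal feasible fraction of the bbox; evaluation
crops are deterministic (tumor-centred), training crops sample uniformly
among feasible windows. Images smaller than the crop are isotropically
upscaled then edge-padded; evaluation images are cropped, then resized if
needed (crop-then-resize order is a package choice).

A pool is a class-balanced manifest of exactly `target_per_class` entries
per class (437,500 at full scale), each a (source slice, transform seed)
pair drawn uniformly *over slices* with replacement — patients and
sequences are intentionally not rebalanced. Pools are materialized lazily
one crop at a time, so the 875,000-entry pool never exists as files.

## Training

The model matrix has T training-set replicates × F folds. For fold f the
pool is restricted to entries whose source patient lies outside CV group
f; replicates differ only in their random stream (initialization and
epoch subsampling). Per epoch, min(slices_per_epoch, pool) entries are
drawn without replacement (with replacement across epochs) and visited in
batches of 32. Full scale: T = 24, F = 6 (144 models), 50 epochs × 35,000
slices, AMSGrad (β₁ = 0.9, β₂ = 0.999, bias-corrected, non-decreasing
second moment) at learning rate 1e-4.

Backbones: the reference architecture is MobileNet-V2 (width 1.0,
224 × 224 × 3, 1000-class head), represented as a layer table whose
parameter count — weights, biases, and all four batch-norm parameters per
channel — totals 3,538,984 (3,504,872 excluding the running statistics).
The trainable backbone is a four-conv-block NumPy CNN (3×3 convs with
channels 8/16/32/32, ReLU, 2×2 max-pool, global average pooling, single
sigmoid unit; 15,313 parameters), with analytic gradients verified
against numeric differentiation. It exists so the complete pipeline trains
on one CPU in minutes; the binary head uses binary cross-entropy (the
loss is a package choice), and grayscale phantoms are replicated to three
channels for backbone compatibility.

## Ensembles, calls and likelihood

Each evaluation slice receives one probability per training-set replicate
from its own fold's model. A sequence-level call for (study, sequence)
averages slice probabilities within each member model, then averages over
ensemble members; the call is positive iff the mean ≥ 0.5 (ties positive;
a majority-vote alternative is a config switch). A sequence with no slices
returns a distinguished "unavailable" result, never a silent negative.
The T leave-one-out ensemble sets each produce a patient-level call via
the scoring layer, and the sarcoma likelihood is 100 × (positive
ensembles)/T — implemented as the fraction-of-positive-ensembles reading;
the mean-probability reading is available through the single-model path.

## Scoring and combination search

For a combination C, score(case) = Σ over available s ∈ C of ±1. The
threshold maximizes SS-Avg over cut-points "positive ⇔ score ≥ t" with t
ranging over observed scores plus one beyond the maximum; among ties the
smallest t wins. Cases with zero contributing sequences are called
negative regardless of threshold (excluding them is a config alternative).
The threshold is selected on the pooled cross-validated evaluation calls,
mirroring the study procedure; this is optimistic — the threshold sees
evaluation labels — and is documented as such rather than hidden.
Combinations are ranked by SS-Avg, then accuracy, then fewer sequences,
then canonical order; the empty set is part of the 2¹⁵ enumeration but
carries no metrics and is excluded from ranking. Top-k metrics are
arithmetic means of the k results.

## Evaluation statistics

Accuracy = (TP+TN)/(TP+TN+FP+FN); sensitivity = TP/(TP+FN); specificity =
TN/(TN+FP); SS-Avg is their mean and equals accuracy exactly under class
balance. Percentages print at one decimal, round-half-even. ROC/AUC uses
the standard full-sweep trapezoidal construction with tied scores grouped
(equivalently, Mann–Whitney pair counting — the test suite checks this
equivalence). Two-sample comparisons expose Student (pooled variance),
Welch, and an auto mode (F-ratio pretest at α = 0.05); the conventional
mapping of test to variance assumption is the default. Tumor volume
defaults to the protocol's printed coefficient, V = (3/4)π·a·b·c with
a, b, c the half-axes; the geometric ellipsoid (4/3)π·a·b·c — a factor
16/9 larger — is selectable, since the printed coefficient contradicts
the ellipsoid formula. The misdiagnosis crosstab tags each case by whether
strictly more than half of the ensemble sets and/or readers miscalled it.

## Desk-scale preset and problem sizes

`pipeline.desk_scale_config` is the package's scaled-down study condition:
30 + 60 patients, three sequence types at the work-horse availability
(98.0/98.4/96.5%), 64 × 64 noiseless canvases, T = 3, F = 3, 3 epochs,
pool of 500 entries per class, 1,000 slices per epoch, AMSGrad at 1e-2.
The larger learning rate is deliberate: 1e-4 is the full-scale setting for
the pretrain-free MobileNet schedule, far too small for a 15k-parameter
CNN given ~280 optimizer steps; 1e-2 lets the small network converge and
calibrate its 0.5 decision boundary within the 3-epoch schedule. This
preset runs in about three minutes on one CPU and is the condition under
which the end-to-end saturation property (likelihood 100/0, top SS-Avg
near 100%) is asserted.

## Numerical choices and degenerate inputs

Sequence-call ties (mean exactly 0.5) are positive; threshold ties take
the smallest t; ranking ties are broken deterministically as above.
Max-pool gradient routes to the first argmax on ties. Bounding-box
envelopes use a 1e-9 tolerance before floor/ceil so exact-angle
transforms don't inflate the box by one pixel. Empty classes, single-class
label sets, sub-batch pools, oversized tumors, unknown sequence names and
out-of-bounds boxes all raise informative errors naming the offending
unit. Identical samples in a t-test return (t = 0, p = 1).

## Known limitations

Phantom realism as above; the MobileNet-V2 backbone is counted and
described but not trained in-process (the trainable path is the NumPy
CNN); threshold selection on pooled evaluation calls is optimistic by
construction; probability calibration is out of scope, as are saliency
maps, nested cross-validation, and per-histotype classification.
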
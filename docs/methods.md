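# Methods

## Scope and design

The package reproduces a tile-based H&E analysis pipeline for
glioblastoma: region-annotated slides are cut into overlapping tiles, a
convolutional backbone with one of two task heads is trained per
cross-validation fold (subtype fractions with squared error; survival risk
with the Cox partial-likelihood loss), tile predictions are aggregated to
patient-level calls, and nucleus/marker morphometrics characterize the
microenvironment. Since real whole-slide cohorts are impractical on a
single CPU, a synthetic cohort generator provides inputs whose statistical
structure matches what the analysis assumes, making every stage testable
end to end.

## Synthetic cohort model

**Subtype mixtures.** Each patient's (classical, mesenchymal, proneural)
fraction vector is drawn from a two-component Dirichlet mixture: with
probability `p_spiky = 0.555` from a spiky concentration (30, 2, 2) whose
large component is placed on a dominant subtype drawn with probabilities
proportional to 34:50:21 (the predominant-class composition of the
reference cohort), otherwise from a flat Dirichlet(5, 5, 5). These
constants were calibrated once by simulation so that the share of draws
with a component ≥ 0.70 is ≈ 0.556, matching a cohort in which 44.4 % of
tumors are "mixed"; they are fixed, not tuned per experiment.

**Survival.** A standardized latent risk z drives a Weibull
proportional-hazards model: T = λ₀ (E / e^lp)^{1/k} with E ~ Exp(1),
shape k = 1.5, scale λ₀ = 1.136 y, and log hazard
lp = β z + log(1.025)(age − 60) + log(1.14)·male + log(0.43)·TMZ.
The covariate hazard ratios are the reference cohort's fitted values; λ₀
was calibrated once so the population median overall survival is ≈ 1.16 y
under the default covariate mix (age ~ N(62.5, 11²), 61.6 % male, 74.3 %
radiochemotherapy). β defaults to 1.0 — the strong-effect regime the
recovery experiments presume; with these defaults the latent risk attains
a concordance of ≈ 0.72 against observed survival, and censoring
(minimum of a 5-year administrative horizon and a uniform draw on
[0, 8 y]) yields an expected event fraction of 0.77.

**Slides.** The canvas is an eosin-pink background with three disjoint
region classes: a wavy preexisting-brain band along the left edge
(fraction 0.15 — the infiltration front), smoothed-noise necrosis blobs
(0.08) and bleeding blobs (0.015), thresholded at the quantile that gives
the configured area fraction. A per-pixel subtype weight field is a
softmax of smoothed Gaussian logit fields, biased upward for proneural
within two tile-widths of preexisting tissue and for mesenchymal within
two tile-widths of necrosis, then offset-calibrated (iterative
proportional fitting, ≤ 40 rounds) so canvas-averaged weights match the
patient mixture to < 10⁻³.

Nuclei are planted by an inhomogeneous hard-core point process (thinning
plus a minimum-distance occupancy grid at 2.3 equivalent radii, which
keeps nuclei separable by the detector) with local intensity
Σ_k w_k(x)·d_k · exp(γ·risk), where d = (6146, 5484, 5321) / mm² are the
per-subtype cellularity medians and γ = 0.2 sets the log-density shift per
risk SD (the high-risk-regions-are-denser direction). Each nucleus is an
ellipse with:

* mean area from the subtype-weighted field over (36, 30, 24) µm² —
  proneural nuclei smallest, consistent with the uniform
  oligodendroglial/OPC-like morphology described for proneural regions.
  This size axis is a generator design choice (no published per-subtype
  size medians exist): without it the subtype signal lives only in weak
  density/eccentricity contrasts that pooled convolutional features
  cannot resolve at desk scale, leaving the subtype head nothing to learn;
* lognormal area spread σ = 0.18 + 0.12·sigmoid(risk) — pleomorphism
  grows with risk;
* eccentricity from the subtype-weighted field over (0.60, 0.75, 0.45),
  giving the circularity ordering proneural > classical > mesenchymal.

The per-pixel risk field is the patient's latent risk plus a smoothed
random field (SD 0.5), so risk varies within a slide — risk heatmaps have
genuine spatial structure and high- versus low-risk *regions* can be
compared within slides, which is how the CD8-depletion direction is
checked (a paired region comparison over planted ±1 SD risk partitions;
an across-patient comparison is hopelessly confounded by the four-fold
between-subtype CD8 spread).

Marker maps are Poisson point processes on tumor tissue with
subtype-weighted intensities equal to the reference medians (CD3 34/129/25,
CD8 10/36/9, CD68 96/243/72, CD163 9/348/37, Ki-67 290/108/60 per mm²);
the CD8 intensity is additionally scaled by exp(−0.4·risk) (T-cell
depletion in high-risk tissue). HLA-DR and CD34 are stained-area masks
with subtype-weighted target percentages (2/8/1 % and 4/5/2 %).

All randomness derives from one seed; per-patient substreams come from
`SeedSequence((seed, crc32(patient_id), stream))`, so cohorts are
reproducible patient-by-patient and under parallel generation.

**Geometry profiles.** The full profile uses 3072² px at 0.46 µm/px with
1024-px tiles and 64-px overlap. The desk profile used by the tests and
the reproduction script uses 512² px canvases with 64-px tiles and 8-px
overlap at 0.92 µm/px; the doubled pixel size keeps ≈ 20 nuclei in a
64-px tile — at full-scale resolution such a tile would hold ~5 nuclei
and carry almost no signal. Both profiles run the same code path.

## Tiling and filters

Tile grids advance with stride `tile − overlap` and anchor a final tile at
`dim − tile`, so coverage is complete (needed for heatmaps). Per-tile
region fractions are exact pixel counts over the masks; tumor is the
complement class. Context flags use ε = 0.05 ("contains both" with more
than 5 % of each) to suppress single-pixel mask noise. Tiles are kept iff
tumor fraction > 0.5 (strict), and patients with fewer than 50 kept tiles
are excluded entirely.

## Model and training

With no deep-learning framework available, the trainable model is a small
NumPy CNN with analytic backward passes, verified against central finite
differences to < 10⁻¹⁰. The `tiny_test` backbone is two stride-2 valid
convolutions: a **fixed oriented-filter stem** (24 filters: two color
probes — luminance and a hematoxylin-direction contrast — times six 3×3
spatial kernels, both signs), playing the role generic pretrained early
layers play in transfer learning, and a random He-initialized mixing
convolution (16 channels). The pooled feature vector concatenates
mean-pooled stem activations with mean- and energy-pooled (squared)
outputs of the second convolution (56 features), so first- and
second-order tile statistics are both linearly available to the heads.
Feature location/scale are frozen from the first batch seen
(batch-norm-style calibration), after which the model is a fixed
deterministic function.

The full-size `xception_shaped` backbone is represented by its exact layer
table: 20,861,480 headless parameters including batch-normalization
buffers, of which 4,741,632 (the depthwise+pointwise kernels of the final
two separable convolutions, 1024→1536 and 1536→2048) are unfrozen by
fine-tuning; ten such models concatenate to 20,480 pooled features. These
counts are computed from the table at runtime, not hard-coded sums.

Training follows the two-phase protocol: phase 1 trains only the head
(Adam, staircase decay `lr·decay^⌊step/400⌋`); phase 2 unfreezes the last
convolutions at a lower rate. The full-size schedule is 25 + 10 epochs ×
150 steps at batch 64 (lr 10⁻³/0.9 then 10⁻⁴/0.8); the desk schedule
(`TrainConfig.desk()`) is 5 + 2 epochs × 60 steps, lr 3·10⁻³ then 10⁻⁴,
fine-tuning only the mixing convolution — the stem stays fixed, mirroring
the freeze-early-layers logic, and a larger phase-2 rate destabilizes the
frozen feature calibration. Batches are assembled by a cycle sampler (one
random tile per patient per cycle); 10–20 validation batches are cached
before training and scored once per epoch (MSE for the subtype head,
concordance for the risk head). Desk-scale training uses geometric-only
augmentation; the full H&E policy (HSV and stain-space jitter, blur,
noise, JPEG artifacts) is available and tested but photometric jitter at
64-px scale erodes the density cue that desk-size tiles rely on.

**Cox loss conventions.** Risk sets are formed within the mini-batch; tied
event times share a risk set (Breslow); the loss is normalized by the
event count d (stable gradient scale across batches) and defined as 0 for
event-free batches; the log-sum-exp is max-shifted. The analytic gradient
is exercised directly by the training loop.

## Aggregation and statistics

Raw risk scores are z-scored with the population SD within each validation
fold before concatenation (per-fold scoping removes cross-fold offsets; a
global option exists). Patient calls: mean z-scored risk, fraction of
tiles with z > 1 (strict), high-risk iff that fraction ≥ 0.25 (boundary
inclusive — the cutoff statement does not resolve the boundary, so it is
configurable). Winner-takes-all subtype ties break by the fixed order
classical < mesenchymal < proneural (exact ties are measure-zero for
softmax outputs; fixtures exercise the rule). Survival misclassification
flags high-risk patients surviving > 18 months and low-risk patients
surviving < 12 months; the 12–18-month window is deliberately unflagged.
"Near correct" subtype mismatches are those where the top predicted score
exceeds the true subtype's predicted score by < 0.01.

Permutation tests shuffle labels at the patient level and use the add-one
estimator p = (1 + #{null ≥ observed}) / (1 + n_perm) ("≤" for error-type
metrics); p-values are verified super-uniform under the null by a KS
calibration suite. Harrell's c is implemented from the pair definition
(event-anchored comparable pairs, half-credit ties) and checked exactly
against an exhaustive double loop and against scikit-survival.
Kaplan–Meier curves, log-rank tests and Cox fits delegate to lifelines
(Efron ties — indistinguishable from Breslow here because simulated times
are continuous); ROC/confusion summaries delegate to scikit-learn.

## Microenvironment quantification

The nucleus detector is deliberately minimal and fully parameterized:
stain deconvolution to the hematoxylin channel, Gaussian smoothing
(0.7 µm), fixed threshold (0.06 OD), connected components within a
physical area window (8–850 µm²). Circularity is 4πA/P² clipped to 1 with
the Crofton 4-direction perimeter estimator, whose disk circularity
converges to 1 and decreases monotonically with ellipse eccentricity.
Parity with any interactive tool's detector is a non-goal; absolute
densities depend on detector settings, so only planted-fixture recovery
and orderings are asserted.

## Numerical and degenerate-input choices

Zero-variance score sets refuse to z-score; empty region masks refuse
density computation; a zero administrative horizon censors every record;
`necrosis_area_frac = 0` produces an empty mask; tile dimensions smaller
than the tile size yield an empty grid with a warning; a patient with zero
kept tiles is an upstream-filter error, not a silent skip. Heatmap
localization smooths the prediction grid (Gaussian, one grid cell —
per-window predictions are noisy and heatmaps are conventionally smoothed
before display) and thresholds with Otsu's method rather than a tuned
cutoff.

## What the synthetic tests do and do not show

Passing recovery tests demonstrates that the pipeline's machinery —
losses, sampling, aggregation rules, statistics, morphometrics — is
correct and that the training loop can extract a planted
histology-to-outcome signal at desk scale. They do not show that the tiny
backbone would learn real histology, that the generator's phenotype model
matches real glioblastoma beyond the anchored medians and directions, or
anything about stain/scanner variability, which the generator does not
model. Desk-scale problem sizes (60 patients, 512² canvases, 5 + 2-epoch
schedules) are the package's chosen study conditions for reproducible
single-CPU runs.
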
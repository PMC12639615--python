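# Methods

This note documents the models, conventions and design choices behind
`satb2quant`, in the order data flows through the pipeline.

## Image quantification

### Quantization and histograms

All threshold algorithms operate on 256-bin histograms of 8-bit images,
matching the Fiji/ImageJ toolchain in which these area statistics are
conventionally computed. Floating-point input is min–max rescaled to
[0, 255] with round-half-up; a constant image maps to all zeros. Because
the rescale removes offsets exactly, every mask is invariant to adding a
constant to all intensities (tested as a property). Histograms are
per-image and unsmoothed.

### The four threshold algorithms

* **Otsu** — maximizes the between-class variance of the classes
  {≤ t} and {> t}; computed for all 255 cut points, lowest level on ties.
* **Li** — iterative minimum-cross-entropy scheme: given a level, the
  background/foreground means update the level via
  t ← (μ_b − μ_f)/(ln μ_b − ln μ_f), iterated on integer partitions until
  stationary (change < 0.5 gray level). Gray values are shifted by +1
  internally so the logarithms are defined at bin 0; the returned level is
  on the original scale. A limit cycle returns the last iterate with
  `converged=False`.
* **Moments** — Tsai's moment-preserving threshold: the first three
  gray-level moments determine the two representative levels z0 < z1 and
  the dark-class fraction p0 = (z1 − m1)/(z1 − z0); the level is the
  p0-percentile of the cumulative histogram. Zero variance or a negative
  discriminant returns the modal bin with a degenerate flag.
* **Minimum** — the histogram is repeatedly smoothed with an edge-clamped
  3-point running mean until exactly two interior local maxima remain;
  the level is the minimum between them (lowest index on ties). Peak
  counting is plateau-aware: a run of equal values bracketed by strictly
  lower neighbors counts as one maximum, and runs touching bins 0 or 255
  are not interior maxima (so monotone histograms correctly fail with a
  non-bimodal error after the 10,000-iteration cap).

Foreground is strictly *greater than* the level everywhere ("above
threshold is object"). Degenerate histograms yield the single occupied
bin, hence an empty foreground; downstream ratios treat empty masks as
explicit missing values (NaN) excluded from group statistics with the
exclusion count reported — never as silent zeros, which would bias group
means.

Otsu and Moments are each validated exactly against an independent
brute-force implementation on 1,000 random histograms; Li is validated as
a fixed point of its own update and against an exhaustive cross-entropy
scan (the objective is exactly flat across empty gap bins, so candidate
levels are compared through the objective value).

### Ratio statistics

The channel/method pairing is hard-wired per metric — it *is* the
statistic: aggregation uses Moments (protein) over Minimum (DNA);
colocalization uses Moments for both; nuclear fraction uses Li (protein)
and Otsu (DNA). Overriding the pairing requires an explicit config flag
that watermarks the output as non-standard. Coordinates are 0-based
row-major; intensity profiles sample both channels by bilinear
interpolation at 1-pixel steps, with distances converted to micrometers
when a pixel size is present.

## Synthetic micrographs

The generator emulates the assay's four observed nuclear phenotypes with
exact ground truth:

* The DNA channel is an elliptical nucleus (randomized axes/orientation)
  with 1–3 dark nucleoli and bright heterochromatin blobs covering ~40%
  of the nuclear area. The blob union is the DNA-foreground truth mask,
  standing for the AT-rich, Hoechst-bright chromatin with which variant
  proteins do or do not colocalize.
* The protein channel realizes a phenotype by exact stratified pixel
  placement: of n = aggregation_level · |DNA mask| foreground pixels,
  a coloc_level fraction is placed inside DNA foreground, a
  cytoplasm_fraction outside the nucleus, the remainder in
  chromatin-poor nucleoplasm. Placement weights shape the phenotypes:
  smooth random fields (diffuse granularity), chromatin-following
  (DNA cage), compact blobs kept at a distance from chromatin
  (anti-DNA aggregates), or tight punctae (condensates). Because the
  stratum counts are exact, the truth overlap fraction is exact by
  construction and recomputable by direct pixel counting.
* Intensities are crisp two-level renders (no optics/PSF model —
  deliberately out of scope) plus a smooth low-amplitude texture field
  per channel, representing chromatin/expression heterogeneity. The
  texture keeps histogram modes at finite width even at zero detector
  noise, which the Minimum method's mode-merging requires; white
  detector noise (default sd 0.02 on a [0, 1] scale) is added on top.
  Intensity levels (background 0.10, nucleoplasm 0.16, heterochromatin
  +0.58, protein foreground +0.65) were chosen so that all four
  threshold algorithms recover the generative masks; with them, the
  three ratio statistics recover generator truth to within ±0.02 in the
  mean on noiseless images and ±0.05 at default noise.

What passing these tests shows is internal consistency of the
measurement chain, not robustness to everything real micrographs do:
there is no depth structure, no saturation, no chromatic misregistration,
and a single nucleus per frame. Phenotype presets (e.g. DNA-cage
coloc 0.85 vs diffuse 0.40) encode the qualitative contrasts observed
between variant classes, with the diffuse preset's colocalization pinned
at the DNA-foreground area fraction (chance level, no enrichment).

## FRAP

The simulator produces a pre-bleach plateau, an instantaneous bleach drop
to (1 − bleach_depth) of the plateau, and recovery
I(t) = I_b + m·(I_pre − I_b)(1 − e^(−kt)), with photofading e^(−ρt)
multiplying both the ROI and the unbleached bleach-control trace,
a constant background offset, and white noise. Defaults (10 pre-bleach +
135 post-bleach frames at 0.5 s; mobile fraction 0.85; bleach depth 0.7)
reflect a 145-frame confocal series. Applying the fade identically to ROI
and control makes the bleach-control division cancel it exactly, which is
what makes the correction testable to machine precision.

Normalization is double normalization with full-scale anchoring:
framewise background subtraction, division by the bleach-control trace,
then y = 100·(x − x_bleach)/(x̄_pre − x_bleach). The bleach frame anchors
0% by itself (no smoothed minimum), the pre-bleach mean anchors 100%, and
both anchors hold exactly for every valid recording. When no bleach index
is supplied it is detected as the global minimum of the
background-subtracted ROI trace (earliest on ties).

The recovery model is the two-parameter single exponential
y(t) = A(1 − e^(−kt)) on post-bleach frames, t = 0 at the bleach frame
and y(0) = 0 through the model (the bleach frame is included in the fit;
it is consistent with the model at t = 0 by the anchoring). Fitting uses
bounded trust-region least squares (k > 0; parameter/function tolerances
1e−8; 10,000 evaluation cap), initialized with A₀ = mean of the last 10%
of frames and k₀ = ln 2 / (time of first half-A₀ crossing). On a
full-scale normalized curve the plateau A is the mobile fraction in
percent, and t½ = ln 2/k exactly by construction. A non-converged solver
returns its best iterate flagged `converged=False`. Recovery validation:
noiseless recordings reproduce k to < 1e−6 relative error; at 2% noise
the median t½ across 60 recordings stays within 10% of truth, and the
RMSE of k decreases monotonically with the noise level.

## Dual-luciferase reporter

Per replicate, activity is the firefly/*Renilla* ratio; relative activity
divides by the *mean* ratio of the empty-vector control (unpaired, since
conditions are independent transfections — the data do not identify a
pairing). The control's mean relative activity is therefore 1 by
construction, and relative activities are invariant to rescaling either
luciferase globally. The simulator draws both counts with mean-preserving
multiplicative log-normal noise (σ² = ln(1+cv²)), so a condition's
expected relative activity equals 1 − mean_repression; at cv = 0 the
recovery is exact (e.g. 0.250 at 75% repression).

Repression calls compare each variant's replicate-level relative
activities to wild type (not to the empty vector) with Dunnett's test:
significantly higher activity → reduced repression; significantly lower →
increased repression; otherwise retained. α = 0.05 two-sided,
configurable. Degenerate (zero-variance) families are uncallable (NA).
Calls are kept separate per reporter construct (Ctip2-MAR, Nr4a2-MAR);
they are only combined at the classification stage.

## ANOVA and Dunnett's test

The ANOVA is the standard fixed-effects decomposition with the F
distribution; zero within-group variance (up to a relative 1e−12
round-off guard) flags the result degenerate rather than producing a
spurious p.

Dunnett's adjusted p-values are computed by Monte-Carlo rather than
closed-form tables: with pooled within-group df ν and weights
λ_i = n_i/(n_i + n_ref), the null statistics are equicorrelated
multivariate t with ρ_ij = √(λ_i λ_j) (½ when balanced). The sampler
draws a shared control normal, independent group normals and a shared
chi factor — dimension-agnostic, testable against the two-group closed
form, and bit-reproducible given the recorded seed. Default 1e5 draws;
each p-value is reported with its Monte-Carlo standard error and clipped
from below at the unadjusted pooled-t p (the exact family-wise
probability can never be smaller than the marginal one, so Monte-Carlo
noise is not allowed to violate that bound; this also makes the k = 1
case agree exactly with the pooled two-sample t). Calibration: the
family-wise error rate under the global null (k = 5, n = 20/group,
1,000 simulations) sits at 0.05 ± 0.015, and three-group adjusted
p-values agree with an independent implementation (scipy's Dunnett, used
only as a cross-check) to within Monte-Carlo error. Comparison families
are defined per assay type per reporter construct.

## Classification

No formal decision rule is published for the functional subgroups; the
rule table here operationalizes the verbal criteria and is versioned
(`v1`) so alternative operationalizations can be compared:

1. `condensate_class` — HOX-domain variant or condensate localization
   pattern (kept apart from CUT-domain partial LoF even though repression
   is also reduced);
2. `increased_function` — colocalization call *increased* and no
   reporter shows reduced repression (reduced mobility supports but is
   not required; requiring "not reduced" on *both* reporters is the
   deliberate, configurable reading of "maintained or increased"
   activity);
3. `partial_LoF` — reduced repression on ≥ 1 reporter without increased
   colocalization;
4. `unclassified` — anything else.

Assignment is a pure function of the call fields; a profile can never be
simultaneously increased-function and partial-LoF. Every call in a built
profile traces to a Dunnett-adjusted p-value and effect direction. The
packaged 31-variant reference cohort encodes the reported outcome
pattern of the etiological screen (8 named increased-function variants,
13 named partial-LoF CUT variants, 3 HOX condensate variants, and 7
further partial-LoF CUT variants under synthetic placeholder ids, since
their individual rows are not enumerated in the published text); its
subgroup summary reproduces the 8/31 ≈ 25% increased-function fraction.

## Problem sizes and numerical conventions

Default problem sizes were chosen to keep the full validation fast on a
single CPU while retaining statistical resolution: 128×128 px nuclei
(20 per variant group), 60 FRAP recordings per condition, 8 reporter
replicates per plate, 1e5 Monte-Carlo draws per Dunnett family, and
1,000 simulated plates/simulations for the calibration suites. All
randomness flows through one seeded NumPy generator per call, every seed
surfaces in the API and CLI, and a full pipeline run from a fixed config
reproduces every output file hash.

## Known limitations

* The synthetic DNA-foreground truth is the bright AT-rich chromatin
  fraction, not the whole nucleus; on real wide-field data the
  Li/Otsu nuclear-fraction statistic segments whole nuclei against a
  dark background, a regime the single-nucleus generator only
  approximates by its background region.
* No nucleus segmentation or instance detection: images are assumed to
  contain a single nucleus (or pre-segmented fields).
* Single-component FRAP only; reaction–diffusion or two-component
  recovery is out of scope, as are image-based ROI extraction and
  saturation/border exclusions.
* No plate-effect or batch-correction modeling in the reporter analysis.
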
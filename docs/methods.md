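# Methods

## Imaging model and quantification

### Volume convention

Wide-field images are 2-D; "volume" throughout means segmented area (μm²)
times a nominal unit depth of 1 μm, reported in μm³. This keeps the
log_e(volume) scale of the eleven-bin size distribution meaningful: the
fixed integer-edged grid [−6, −5), …, [4, 5) covers the plausible range of
aggregate log-volumes (roughly −5.5 to 4.1) and values outside it raise an
error rather than being silently clipped.

### Detection operating point

Defaults are the published operating point: cells are connected components of
`gaussian(I, σ=0.2 μm) > 30`, spots are connected components of
`gaussian(I, σ=0.1 μm) − gaussian(I, σ=0.5 μm) > 80`, the 20% intensity
quantile is the background estimate, and spots below 10⁻⁵ μm³ are discarded.
Thresholds are interpreted on the raw intensity scale of the input (an 8-bit
convention: background ≈ 10 AFU, diffuse cell signal ≈ 60 AFU, spot peaks
several hundred AFU); the image bit depth is a simulator/config parameter,
not a fixed assumption. Connected components use 8-connectivity; quantiles
use linear interpolation between order statistics.

Background subtraction feeds intensity quantities only (integrated spot
intensity, the per-image eGFP estimate). The detection masks use the stated
filter + threshold rules on the raw data; the source procedure lists the two
without sequencing them, and applying the quantile subtraction before
thresholding would silently shift both fixed thresholds by the background
level.

### Spot volume measurement

The DoG threshold decides *where* spots are; it deliberately does not decide
*how big* they are. The area of the `DoG > 80` component depends strongly on
spot amplitude and scale (for Gaussian spots the component radius at a fixed
absolute threshold is biased tens of percent in either direction across the
realistic size range), so each detected spot's volume is instead measured as
the area of the region above half-maximum amplitude on the
background-subtracted image: the local baseline is the median of the boundary
ring of a padded window around the component, the peak is the maximum inside
the component, and only the connected region containing the peak is counted.
This makes the measured volume match the half-maximum-area convention that
defines ground-truth volume in the simulator (for an isotropic Gaussian of
scale s, area above half maximum = 2π ln 2 · s²), independent of brightness.
On simulated images (spot peaks ≈ 800 AFU, pixel noise 5 AFU, 0.1 μm pixels)
this yields recall and precision of 1.0 and a median volume error of ~4%.

### Per-image expression and kinetics

eGFP-Htt expression per image is the sum of background-subtracted intensities
over the whole raster divided by the combined cell volume (AFU/μm³); it is an
error, not NaN, when no cell is present. Per-bin aggregate counts are divided
by the same cell volume; time-point summaries average densities across images
(the per-image table is retained so pooled counts can be recomputed) and
summarize eGFP by the median. Fewer than four images per time point triggers
a warning, matching the experimental floor.

## Expression model

### Pre-processing

Each channel of each array is background-corrected with the normexp model:
observed intensity X = B + S with B ~ N(μ, σ²), S ~ Exp(α). The parameters
are fitted by maximum likelihood (L-BFGS-B with an analytic gradient on
(μ, log σ, log α), started from method-of-moments and quantile-based
initializations, keeping the better optimum) and the corrected value is
E[S | X] + 20. The offset shrinks log-ratios of weak probes toward zero. The
conditional expectation is evaluated with an erfcx-based hazard ratio that is
stable in both tails, so σ → 0 (a noise-free channel, e.g. a pooled-reference
channel simulated without measurement noise) degenerates cleanly to
X − μ + offset; the subtract-the-minimum fallback is reserved for genuinely
degenerate inputs (zero variance, failed fit) and warns. At 10⁵ probes the ML
fit recovers generative (μ, σ, α) within ~2%.

M = log₂(Cy3/Cy5) is normalized per array by subtracting a loess fit of M on
A (span 0.3, locally linear, 3 robustifying iterations; the span and degree
are config — the source procedure does not state them). Probes of a gene are
summarized by Tukey median polish (alternating removal of row and column
medians, tolerance 10⁻⁶ on the residual row/column medians, 10 sweeps by
default — ample for 1–4-probe blocks; wide blocks may need more sweeps to
reach the tolerance and the function accepts a higher cap); the gene value
per array is overall + column effect.

### Linear models and moderation

Per gene, ordinary least squares on a design with an 18-level condition
factor (cell line × time, reference C₀) plus a slide factor (first slide as
baseline; slide columns aliased with condition are dropped with a warning).
Contrasts per post-induction time t: C_t − C₀, HD_t − HD₀ and the
disease-specific double difference (HD_t − HD₀) − (C_t − C₀), which cancels
responses shared by both lines (doxycycline exposure, culture time) and all
baseline differences between the lines.

Gene-wise variances are moderated with a scaled-F prior estimated by moments
on log s²: with e_g = log s²_g − ψ(d/2) + log(d/2), solving
ψ′(d₀/2) = var(e) − ψ′(d/2) gives the prior df (trigamma inversion by Brent's
method) and the prior variance follows from mean(e). Posterior variances are
s̃² = (d₀s₀² + d·s²)/(d₀ + d); moderated t uses d + d₀ df; the overall
moderated F across the eight double-difference contrasts is
b′V⁻¹b/(8·s̃²) with V = C′(X′X)⁻¹C. var(e) ≤ ψ′(d/2) gives d₀ = ∞, the
no-moderation limit (handled by a large-d₀ cap in the t/F reference
distributions). The whole moderated path is cross-checked in the test suite
against Bioconductor limma on a shared dataset and agrees to ~10⁻⁶ in d₀,
s₀², logFC, t, p and F.

BH adjustment is applied within each contrast family separately (each time
point of each family, and the overall-F family on its own), matching
per-contrast reporting; a config flag could pool families, but per-family is
the default and the tested behaviour.

Thresholds: per-time-point DE counting at adjusted p < 0.05; the
disease-specific set at overall-F adjusted p < 0.1; the early-response set at
nominal double-difference p < 0.2 at all of 4, 8 and 24 h.

### Slide correction for PCA and clustering

Hypothesis tests keep the slide factor inside the linear model. For PCA and
clustering inputs, slide effects are estimated per gene by least squares
*jointly* with condition effects and the slide component is subtracted. This
is a fixed-effect analogue of empirical-Bayes batch correction (ComBat);
with ≥ 12 arrays per slide the shrinkage ComBat adds is immaterial, and the
joint fit guarantees condition contrasts are untouched (corrected condition
means equal the fitted condition effects exactly, because OLS residuals sum
to zero within each condition). Confounding between slide and condition is
detected and raised as an error on this path.

Profile clustering standardizes each selected gene's replicate-averaged
temporal profile to mean 0 / sd 1 and applies average-linkage hierarchical
clustering with Pearson-correlation distance, cut at a configurable cluster
count (default 2, reflecting the dominant up/down pattern pair). Cluster
labels are canonicalized by decreasing size so they do not depend on gene
input order. This is a deliberately simple stand-in for graph-based
clustering of expression patterns; it recovers well-separated monotone
families but will not reproduce fine cluster structure.

## Synthetic data: what it emulates and what it does not

The image simulator renders smooth-edged disk cells with diffuse signal on a
flat background and isotropic Gaussian aggregates whose half-max area defines
their true volume; kinetic trajectories control per-time aggregate counts and
the log-volume distribution (default: none before 24 h, counts peaking at
48–72 h, sizes shifting upward through 120 h). It does not model a realistic
PSF, 3-D structure, photobleaching, cell motion or aggregate overlap beyond a
minimum-separation rule, so detection metrics on it bound what clean data
allow rather than what difficult data deliver.

The array simulator draws probe affinities from an exponential (matching the
normexp assumption), uses a pooled-mean common reference (noiseless by
default to isolate test-channel behaviour; a noise toggle exists), and plants
slide offsets, polynomial intensity-dependent dye bias, log₂ noise
(default sd 0.2) and piecewise-linear temporal profiles that are zero at the
pre-induction state, in the disease line only or shared by both lines. Real
two-colour data add spatial artefacts, print-tip effects and probe-sequence
biases that are not simulated; passing tests demonstrate correctness of the
computations, not robustness to those artefacts.

Default sizes keep the test suite and the acceptance script fast while
retaining statistical resolution: detection is evaluated on 20 images
(~120 spots), null FDR control on 100 Monte-Carlo datasets of 2,000 genes on
the full 108-array design, and planted-effect recovery on an 800-gene panel
with 80 disease-specific, 40 shared and 30 early-response genes. The
realized false-discovery proportion is averaged over every BH-adjusted
family the pipeline produces (24 per-time-point contrasts plus the overall
F); under a global null the per-family FDP is a 0/1 indicator, so averaging
across families measures the same error rate with far lower Monte-Carlo
variance than any single family.

## Numerical choices and edge cases

- Quantiles: linear interpolation between order statistics everywhere.
- Connected components: 8-connectivity.
- Trigamma inversion: Brent bracketing on [10⁻⁸, 10⁸]; d₀ = ∞ capped at 10¹⁰
  when used as degrees of freedom.
- Zero contrast vectors (self-contrasts such as HD₀ − HD₀) return
  logFC = 0, t = 0, p = 1 exactly rather than 0/0.
- Empty images give empty masks and zero cell volume; eGFP estimation on zero
  cell volume raises.
- Sub-pixel smoothing scales (σ < 0.3 px) warn about implausible calibration.
- Generators derive per-image/per-array substreams from one global seed, so
  subsets are reproducible; identical seed + config is bit-identical, and the
  CLI manifest (SHA-256 per artifact) verifies this end to end.

## Known limitations

- Detection accuracy figures hold in the simulated regime (peaks ≫ threshold,
  spots ≥ 4 px, separation ≥ 2 μm); dense fields of overlapping aggregates
  will merge.
- The log₂-fold-change RMSE on planted profiles (~0.14–0.20 across seeds at log₂ noise
  sd 0.2 with 2–4 probes per gene) is dominated by sampling noise of the
  double-difference estimator plus occasional genes represented only by
  weak probes, whose log-ratios the normexp offset deliberately shrinks
  toward zero; it scales with noise, probe strength and replicate number,
  not with implementation accuracy (bias ≈ 0).
- Probe reannotation, functional enrichment, promoter/motif analysis and
  interaction networks are out of scope; gene identifiers are taken as given.
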
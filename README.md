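# polyqtc

Time-resolved quantification of polyQ-huntingtin aggregate formation from
fluorescence microscopy images, combined with a two-channel time-course
differential-expression analysis — the paired readouts used to relate protein
aggregation kinetics to transcriptional change in inducible polyQ cell models
(e.g. tet-on PC12 lines expressing an eGFP-tagged N-terminal Htt fragment
with an expanded CAG repeat).

## Who this is for

Groups running induction time courses in aggregation-prone cell models who
need (i) reproducible, calibrated aggregate size distributions from wide-field
images and (ii) a disease-specific differential-expression analysis that is
robust to baseline differences between cell lines. Every stage is driven and
validated by synthetic-data generators with exact ground truth, so the whole
pipeline is testable without any external data.

## What it computes

**Imaging** (`polyqtc.imagequant`, `polyqtc.kinetics`)

- Cell segmentation: Gaussian blur (σ = 0.2 μm) + intensity threshold (30 AFU);
  the combined cell volume uses a unit-depth convention,
  volume = area(μm²) × 1 μm.
- Aggregate detection: difference of Gaussians, DoG = G(σ=0.1 μm) − G(σ=0.5 μm),
  thresholded at 80 AFU; spots smaller than 10⁻⁵ μm³ are discarded as noise.
- Background: the 20% intensity quantile, subtracted for all intensity
  quantification.
- Per-image eGFP-Htt expression: total background-corrected fluorescence
  divided by the combined cell volume.
- Kinetics: aggregates binned by log_e(volume) into eleven unit-width bins
  with integer edges −6 … 5; per-bin counts divided by the image's cell
  volume; time points summarized over ≥ 4 images, eGFP by the median.

**Expression** (`polyqtc.expression`)

- normexp background correction per channel per array (maximum-likelihood fit
  of observed = N(μ, σ²) background + Exp(α) signal; corrected value
  E[signal | observed] + offset 20).
- Within-array loess normalization of M = log₂(Cy3/Cy5) on
  A = ½·log₂(Cy3·Cy5).
- Tukey median polish over each gene's probes × arrays block → one log-ratio
  per gene per array.
- Gene-wise linear models with a cell-line × time condition factor
  (18 levels, reference C₀) and a slide factor; empirical-Bayes variance
  moderation (F-prior fitted by moments on log s²); contrasts per time point
  t: C_t − C₀, HD_t − HD₀, and the disease-specific double difference
  (HD_t − HD₀) − (C_t − C₀); an overall moderated F across the eight
  double-difference contrasts; Benjamini–Hochberg FDR within each family.
- Gene sets: disease-specific (overall-F adjusted p < 0.1), early response
  (nominal double-difference p < 0.2 at all of 4, 8, 24 h), per-time-point
  up/down counts (adjusted p < 0.05); PCA QC and correlation-distance profile
  clustering on slide-corrected data.

**Simulators** (`polyqtc.simdata`) generate calibrated images (diffuse cells +
Gaussian aggregates of known volume, kinetic trajectories over 4–120 h) and
probe-level two-channel arrays (2 lines × 9 time points × 6 replicates = 108
arrays on 9 slides of 12, slide batch effects, intensity-dependent dye bias,
multiple probes per gene, planted temporal profiles), each with ground truth.

## Worked example

```python
import warnings
from polyqtc.simdata import (ImageSimConfig, gen_image, ArraySimConfig,
                             ProfileSpec, gen_array_data)
from polyqtc.imagequant import quantify_image
from polyqtc.kinetics import logvol_bins, density_per_cell_volume
from polyqtc.expression import (preprocess_arrays, build_design, fit_models,
                                moderate_and_test, select_hd_specific)

img, truth = gen_image(ImageSimConfig(seed=42))
res = quantify_image(img)
print("planted aggregates:", len(truth.aggregates), "| detected:", len(res.spots))
print("total cell volume: %.1f um^3 | eGFP expression: %.1f AFU/um^3"
      % (res.segmentation.total_cell_volume, res.egfp_expression))
hist = logvol_bins(res.spots.volumes)
dens = density_per_cell_volume(hist, res.segmentation.total_cell_volume)
print("bin counts:", hist.counts.tolist())

profiles = {"g00000": ProfileSpec("up", onset_h=8, peak_h=72, max_abs_log2fc=1.0)}
long, gt = gen_array_data(ArraySimConfig(n_genes=120, planted_profiles=profiles, seed=42))
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    expr, meta = preprocess_arrays(long)
result = moderate_and_test(fit_models(expr, build_design(meta)))
row = result.table("DD", 72.0).loc["g00000"]
print("g00000 (HD_72-HD_0)-(C_72-C_0): logFC=%.3f t=%.2f adj_p=%.2e"
      % (row["logFC"], row["t"], row["adj_p"]))
print("disease-specific set:", sorted(select_hd_specific(result)))
```

Output:

```
planted aggregates: 6 | detected: 6
total cell volume: 248.5 um^3 | eGFP expression: 11318.3 AFU/um^3
bin counts: [0, 0, 0, 0, 0, 1, 5, 0, 0, 0, 0]
g00000 (HD_72-HD_0)-(C_72-C_0): logFC=0.996 t=6.84 adj_p=8.44e-08
disease-specific set: ['g00000']
```

All six planted aggregates are recovered; their log-volumes fall in the
[−1, 0) and [0, 1) bins of the fixed eleven-bin grid. The single gene planted
with a disease-specific log₂ fold change of 1 peaking at 72 h is estimated at
0.996 and is the only gene selected into the disease-specific set at
adjusted p < 0.1 — none of the 119 null genes leak in.

## Command line

```bash
polyqtc run-all --seed 1 --out out/demo          # simulate → quantify → kinetics → DE
polyqtc simulate-images --seed 1 --out out/img   # individual stages
polyqtc quantify --in out/img --out out/quant
polyqtc kinetics --in out/quant --out out/kin
polyqtc simulate-arrays --seed 1 --out out/arrays
polyqtc de --in out/arrays/probe_intensities.tsv --out out/de
```

Every run writes its resolved configuration and a manifest with SHA-256
checksums; identical config + seed reproduces the manifest bit for bit.

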
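# cartt2

Quantitative MRI of knee cartilage for early-osteoarthritis research:
noise-corrected T2 relaxometry, GLCM texture analysis, WORMS-style
morphologic scoring, reliability metrics and covariate-adjusted group
statistics — with a seeded synthetic cohort generator standing in for
restricted clinical imaging data.

## Who this is for

Imaging scientists studying subjects *at risk* of knee osteoarthritis, where
cartilage biochemistry (water mobility, collagen organization) changes before
any radiographic or morphologic damage appears. The transverse relaxation
time T2 is sensitive to those changes, and its *spatial distribution* —
quantified by grey-level co-occurrence matrix (GLCM) texture — carries
information that the mean alone masks.

## The models at the core

**Relaxometry.** Magnitude MR data are Rician; the expected squared signal of
a spin-echo decay is

```
S(TE)² = S0² · exp(−2·TE/T2) + B²
```

with B² the Rician noise floor. `fit_pixel`/`fit_map` fit (S0, T2, B) per
pixel by least squares on the squared signals of echoes 2–7 (TE 20–70 ms;
the first echo is excluded against stimulated-echo bias). This stays
unbiased at low SNR where the classical log-linear fit inflates T2.

**Texture.** Per cartilage compartment and slice, T2 maps are quantized to
integer milliseconds and co-occurrence matrices P(i,j) accumulated at a
one-pixel offset in four orientations (0°, 45°, 90°, 135°), counting only
pairs fully inside the ROI. Features:
entropy = Σ P·(−ln P), contrast = Σ P·(i−j)², variance = Σ P·(i−μ)².

**Cohort analysis.** Ordinal WORMS scores (cartilage 0–6 with half grade
2.5, meniscus 0–4, bone-marrow lesions 0–3) yield per-tissue prevalence and
per-subject maxima; group contrasts use OLS/logistic models adjusted for
age, sex and BMI, partial correlations, standardized differences and a
Pearson chi-square. Reliability is summarized by RMS CV, ICC(2,1) and
quadratic-weighted kappa.

## Worked example

```sh
python examples/02_fit_t2_map.py
```

```
subject INC0001: stack shape (3, 48, 48, 7), echo times [10. 20. 30. 40. 50. 60. 70.] ms
fitted pixels: 1245, median noise term B = 0.00 (true Rician floor sqrt(2)*sigma = 0.71)
compartment      true mean fitted mean
patella              33.81       33.67
medial_femur         40.30       40.18
medial_tibia         33.04       32.96
lateral_femur        34.45       34.35
lateral_tibia        29.56       29.47
```

One synthetic subject's multi-echo stack is rendered with Rician noise and
fitted; the per-compartment means of the fitted map agree with the subject's
true compartment means to ~0.1 ms. The other examples cover cohort
simulation (`01`), texture (`03` — raising the spatial heterogeneity dial
from 4 to 8 ms roughly quadruples GLCM contrast), adjusted group statistics
and prevalence odds ratios (`04`), and reliability metrics (`05`).

A thin CLI mirrors the pipeline stages
(`cartt2 simulate|fit|texture|score|analyze|reliability|run`), e.g.

```sh
cartt2 run --seed 21 --outdir scratch/demo_run
```

writes NIfTI stacks/masks/maps, cohort and comparison CSVs, a prevalence
JSON and a manifest.

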
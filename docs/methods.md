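# Methods

This note documents the models, conventions and numerical choices behind
`morphoclone`, the assumptions of its synthetic data, and what passing
tests do and do not establish about real microscope data.

## Study design being modelled

A cohort of ~15 single-cell-derived MSC clones is imaged at the P1 stage
in one well each: 64 tiled phase-contrast fields of view (FOVs) per well,
every 6 h from 6 h to 90 h after seeding (15 time points). Each clone's
target label is its serial-passage limitation number — the passage index
at which repeated sub-culture from the P3 bank arrests — spanning 7–13
passages. Per-well populations range from ~300 cells just after seeding
to tens of thousands late in the course. One frame covers 0.25 mm² at
1000×1000 px, giving the default calibration of **0.5 µm/pixel**
(16 mm² / 64 tiles); all µm-valued descriptors use this factor, and it is
an assumption wherever the original acquisition settings are unknown.

## Segmentation (eight steps)

Raw phase-contrast frames are flattened by subtracting a large-window
local-median background (101 px window, computed on a 4× block-averaged
grid and resampled back — the standard practical form at this window
size). Texture is then enhanced with a 7-px local-standard-deviation
filter: adherent cells carry strong local intensity texture under phase
contrast while the background is smooth, so cells become bright in the
enhanced image. Binarization is Otsu's threshold (plus a configurable
offset); a constant enhanced image (blank frame) yields an empty mask
with a warning rather than an error. Objects smaller than 64 px are
removed, the mask is eroded by a 1-px-radius disk, small objects are
removed again, holes are filled, and finally any object with a pixel on
the outermost 1-px frame ring is discarded. Components use
8-connectivity; labels are kept consecutive after every removal.

Two choices deserve note. The two small-object thresholds default equal
(64 px) but are independent settings, since nothing fixes them to be the
same. Erosion treats out-of-frame pixels as foreground
(`border_value=1`): otherwise a cell straddling the frame edge would
retract from the ring during erosion and escape the frame-touching
removal that exists precisely to drop such partially observed cells.
Touching cells are deliberately not split (no watershed); the analysis
operates on population statistics of whatever regions the pipeline
yields.

All step parameters are config-exposed (`SegmentationParams`) so
published or tuned values can be substituted without code changes.

## Descriptors

Twelve descriptors per segmented region: Area (µm², with the raw pixel
count kept alongside), Perimeter, Length and Breadth (major/minor axis of
the best-fit ellipse; a maximum-Feret option exists because the
convention is genuinely ambiguous), AspectRatio, Compactness
= Perimeter²/(4π·Area), Roundness = 1/Compactness, Solidity,
IntensityMean, IntensitySD, and the GLCM texture statistics Correlation
and Energy. Perimeter uses the Crofton estimate, whose digitization and
rotation bias is a few percent for cell-sized regions (a digital disk
measures within ~2% of 2πr), versus ~5–8% for the chain-code estimate.

The GLCM is computed on in-mask pixels only: intensities are quantized to
32 levels over the patch's min–max range, pairs at distance 1 in four
directions (0°, 45°, 90°, 135°) are accumulated symmetrically *only when
both pixels belong to the region*, each direction's matrix is normalized,
and the four are averaged. Energy = ΣP², Correlation is the standard
normalized covariance of the two marginals. Degenerate regions (single
pixel, zero intensity variance, or a zero-variance marginal) receive the
defined values Energy = 1, Correlation = 0 and are flagged; profiling
excludes flagged cells.

## Profiles

A profile is the pooled population summary over the selected FOVs: for
each time point in the window and each descriptor, the mean and the
sample SD (n−1 denominator — the convention had to be fixed; with ≥300
cells the alternative is negligible) over the *concatenated* cells, never
an average of per-FOV summaries. Parameters are named
`"<Descriptor>_<mean|SD> (<T> h)"` and ordered time-major, so a shorter
window's parameter vector is a prefix of a longer one. Windows always
start at 6 h and shorten from the far end in 6-h steps: 6–90 h gives
12 × 2 × 15 = 360 parameters, a single time point 24.

Bootstrap resampling draws k FOVs **with replacement** (a FOV drawn twice
contributes its cells twice) B times per clone; 15 clones × B = 50 gives
750 training samples. Implementation is exact via per-(time, FOV)
sufficient statistics (n, Σx, Σx²), which makes repeated resampling
cheap. Raw (non-bootstrap) profiles carry replicate id 0 and are never
mixed with bootstrap replicates in one fit.

## Models and validation

**LASSO.** Profiles are z-scored; the L1 penalty is selected by an inner
leave-one-clone-out CV on the training fold (the selection rule was an
open choice; per-clone grouping keeps the inner criterion honest on
bootstrap data). The final coefficients at the selected penalty are
computed by LARS, the exact piecewise-linear path solution, which
guarantees at most n_samples active parameters. Selected parameters are
those with nonzero coefficients.

**Random forest.** 500 trees, one third of the parameters per split,
seed-controlled; parameter ranking by impurity-decrease importance.

**Validation.** Leave-one-clone-out CV scored by RMSE of held-out
predictions. With bootstrap replicates, *all* replicates of the held-out
clone leave together and the standardization statistics are refitted on
each training fold — no replicate of a test clone can leak into its
training data. This grouping is the defensible reading wherever the
expansion to 750 samples is followed by cross-validation; an ungrouped
LOOCV over bootstrap replicates would be optimistically biased.

The data-usage grid evaluates this RMSE for every requested (window end,
FOV count): in raw mode each cell uses one random without-replacement FOV
draw derived from the master seed (recorded in the grid provenance); in
bootstrap mode each cell uses B with-replacement draws per clone.
Failures (e.g. an empty FOV draw at some time point) are recorded in the
grid table, never raised. RMSE < 1.0 passage is the conventional
"good model" threshold and is config-exposed. Model-structure similarity
between two fits is the Pearson correlation of their weight vectors
aligned on the union of parameter names (absent = 0); a zero-variance
vector yields a flagged missing entry.

## Synthetic cohorts

The generator's defaults are the study conditions: 15 clones, potencies
assigned round-robin over 7–13 and shuffled (guaranteeing the range is
covered), 64 FOVs, time points 6–90 h, per-well populations within
300–100,000 cells. Cells are assigned to FOVs uniformly; counts grow
geometrically at a per-clone fold-change drawn with weak potency coupling
solved in closed form so the population growth-vs-potency R² equals its
target (default 0.09, so "growth alone cannot predict potency" is
reproducible); draws are clipped to [1.05, 8] and the mean fold (4.8)
puts roughly 12 of 15 clones above fourfold growth.

Each clone carries a *proliferating* subpopulation of small, bright,
round cells whose prevalence rises linearly with potency (4% at potency 7
to ~11% at 13). These cells sit mostly below the 200-px area filter used
by the size-distribution analysis, and they make the mean-intensity
channel an emergent potency signal — which the fitted models legitimately
discover.

Four descriptors are *statistically controlled*: Length, Compactness,
Correlation, Energy. Their per-cell values are drawn from truncated
normals (±3.5 SD, with class offsets for proliferating cells) and then
affinely rescaled per clone × time point so the pooled sample mean and SD
exactly equal affine-in-potency targets. Default coupling (per passage,
at 6, 12 and 18 h): Correlation_SD +0.007, Energy_SD +0.006,
Correlation_mean −0.015, Length_SD −0.7 µm, Compactness_SD −0.012 —
texture spreads widen and shape spreads tighten with potency, with the
mean texture correlation falling. Clone-level noise on each target is
`noise_sd` × a reference scale (the coupling coefficient itself for
coupled statistics, i.e. noise_sd = 1 is one-passage-equivalent noise per
predictor; 5% of the base value for uncoupled ones). At noise_sd = 0 the
coupled population statistics are therefore *exact* affine functions of
potency, giving model-recovery tests a sharp ground truth; full-FOV
profiles carry no sampling noise on the controlled statistics, so FOV
subsampling is the only source of profile noise beyond the clone-level
jitter — mirroring how the FOV sweep is meant to behave. The magnitudes
were calibrated once so the default cohort sits in the regime where a
well-specified linear model reaches RMSE < 1.0, and then frozen.

The remaining descriptors follow a structural model (ellipse geometry
with jitter, so Breadth ≤ Length, Perimeter = √(C·4πA), Roundness = 1/C
hold by construction). Proliferating cells' Area, AspectRatio and
intensity are class-specific, but their Length/Compactness pass through
the same pooled rescaling — statistically controlled rather than
geometrically literal. The image tier is the geometric ground truth:
frames rasterize each cell as a textured ellipse (or a bright disk for
proliferating cells, matching their phase-contrast appearance) on a
vignetted noisy background, with non-overlap enforced by rejection
sampling (a `DensityError` is raised when the requested density cannot be
placed) and border-touching cells flagged in the ground-truth mask.

**What the synthetic tier does not emulate:** phase-halo optics, cell–cell
contact and overlap, debris, illumination drift, mitotic shape dynamics,
or any real correlation structure between descriptors beyond the one
imposed. Passing tests therefore establish that the *pipeline* is correct
and that the *modeling claims hold under the stated statistical
structure* — not that real clones of any particular lab are predictable
at these error levels.

## Problem sizes and numerical choices

Tests run on reduced cohorts (15 clones at ~300–800 cells/well, 16 FOVs)
chosen to exercise the full structure; the acceptance script runs the
full default conditions (~2M cells). KDE bandwidth is Silverman's rule on
log₁₀ data with a 512-point grid spanning the data ± 3 bandwidths; the
area filter is applied in pixel units (> 200 px, i.e. 50 µm² at
0.5 µm/px). PCA z-scores parameters, drops constant columns with a
warning, and fixes each component's sign so its largest-magnitude loading
is positive; axes can be fitted on a merged dataset and subsets projected
onto them. Ties and degenerate inputs raise typed, named errors
(`InsufficientPopulationError`, `MissingTimePointError`,
`SpecValidationError`, `DensityError`) rather than producing silent NaNs.

## Known limitations

- Exact segmentation operator parameters for the original acquisition
  hardware are unknown; the defaults are standard choices and every one
  is configurable.
- "Length" as ellipse major axis vs. maximum Feret diameter is ambiguous;
  both are implemented, ellipse is the default.
- The stock descriptor-coupling set supports the four controlled
  descriptors only; coupling other descriptors raises a validation error
  rather than silently producing uncontrolled statistics.
- Per-clone potency values of any real cohort are not reconstructable
  from published summaries; the generator samples potencies rather than
  replaying a table.
- The renderer's non-overlap constraint caps achievable density well
  below confluency; image-tier benchmarks are low-density by design.
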
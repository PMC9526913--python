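# morphoclone

Noninvasive, morphology-based prediction of **serial-passage potency** for
clonal mesenchymal stem cells (MSCs), implemented as a tested, end-to-end
Python pipeline.

## The problem

Single-cell-derived MSC clones destined for cell banks differ widely in how
many passages they survive before growth arrest — their *serial-passage
limitation number* (counted from the P3 primary bank; here 7–13 passages
across a 15-clone cohort). Measuring this number directly takes months of
serial culture. Growth rate at the early (P1) imaging stage does not predict
it (R² ≈ 0.09). The pipeline in this package instead predicts it from
label-free phase-contrast imaging of the cell population:

1. **Segmentation** — an eight-step pipeline (background adjustment →
   texture enhancement → Otsu binarization → small-object removal →
   erosion → small-object removal → hole filling → removal of
   frame-touching objects) converts each field of view (FOV; 64 per well,
   every 6 h from 6 h to 90 h) into a labelled cell mask.
2. **Descriptors** — 12 per-cell morphological descriptors: Area, Perimeter,
   Length, Breadth, AspectRatio, Compactness = P²/(4πA), Roundness,
   Solidity, IntensityMean, IntensitySD, and the GLCM texture statistics
   Correlation and Energy, computed on the in-mask pixels only.
3. **Profiling** — a clone's *morphological profile* is the pooled
   population mean and SD of each descriptor at each time point:
   12 descriptors × {mean, SD} × 15 time points = **360 parameters**
   per clone (24 for a single time point).
4. **Modeling** — LASSO (with inner leave-one-clone-out penalty selection)
   and random-forest regressors of potency on profiles, scored by grouped
   leave-one-clone-out RMSE; RMSE < 1.0 passage marks a well-performing
   model. A *data-usage grid* sweeps time-window end × FOV count, and a
   50-repeat FOV bootstrap (15 clones → 750 samples) probes robustness
   to image-sampling bias.
5. **Exploration** — log₁₀-area kernel density estimates (area > 200 px
   filter), PCA of profiles with fixed axes for bootstrap clouds, scalar
   R², two-sample t-tests.

Because no raw image set is publicly deposited for this kind of study, the
package ships a first-class **synthetic cohort generator** whose population
statistics are calibrated to the study conditions (potency-coupled texture
and shape spreads, a potency-coupled proliferating subpopulation of small
bright round cells, growth only weakly coupled to potency). It provides a
fast tabular tier for modeling and a rendered-image tier with ground-truth
masks for segmentation benchmarks.

## Worked example

```python
import morphoclone as mc

spec = mc.SyntheticCohortSpec(seed=0)          # 15 clones, potencies 7-13
clones = mc.generate_cohort(spec)
cells = mc.cohort_cells(clones)
labels = mc.cohort_labels(clones)

dataset = mc.build_dataset(cells, labels, window_end_h=90)  # all 64 FOVs
cv = mc.loocv(dataset, "lasso")
print(f"profiles: {len(dataset.profiles)} x {len(dataset.parameter_names)} parameters")
print(f"grouped LOOCV LASSO RMSE = {cv.rmse:.2f} passages")

fit = mc.fit_lasso(dataset)
print(fit.weights.abs().sort_values(ascending=False).head(3).to_string())

r2 = mc.scalar_r2(labels["growth_rate"], labels["potency"])
print(f"growth-rate R^2 against potency = {r2:.2f}")
```

prints

```
profiles: 15 x 360 parameters
grouped LOOCV LASSO RMSE = 0.09 passages
IntensityMean_mean (60 h)    0.779457
IntensityMean_mean (66 h)    0.439406
IntensityMean_mean (90 h)    0.232941
growth-rate R^2 against potency = 0.04
```

The full 360-parameter profile predicts potency to within a fraction of a
passage, while the clone growth rate alone carries almost no signal — the
morphological population structure, not proliferation speed, is what is
informative. Here the model keys on the mean-intensity channel, which
tracks the prevalence of bright, round proliferating cells. The
`data_usage_grid` function repeats this evaluation over every
time-window × FOV-count combination, and `bootstrap_profiles` quantifies
how FOV sampling noise degrades it.

A CLI mirrors the stages:

```bash
morphoclone simulate --n-clones 15 --seed 0 --out cohort/
morphoclone profile --cells cohort/ --window-end 90 --fovs 64 --out profiles.csv
morphoclone fit --profiles profiles.csv --labels cohort/labels.csv --model lasso --out fit.json
morphoclone grid --cells cohort/ --labels cohort/labels.csv --windows 6:90:6 --fovs 1,4,16,64 --out grid.csv
```

## Layout

- `src/morphoclone/synthetic.py` — cohort generator (tabular + image tiers)
- `src/morphoclone/segmentation.py` — eight-step segmentation pipeline
- `src/morphoclone/descriptors.py` — 12 descriptors incl. masked GLCM
- `src/morphoclone/profiling.py` — profiles, FOV subsampling, bootstrap
- `src/morphoclone/modeling.py` — LASSO/RF estimators, grouped LOOCV, grid
- `src/morphoclone/exploration.py` — KDE, PCA, R², t-tests
- `docs/methods.md` — model assumptions, parameter choices, limitations
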
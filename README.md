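# icgdyn

Dynamic indocyanine-green (ICG) perfusion analysis for fluorescence-guided
liver surgery.

After an intravenous ICG bolus (0.05 mg/kg), colorectal liver metastases
(CRLM) and healthy liver parenchyma show opposite dynamic signatures on
near-infrared (NIR) video: a metastasis enhances fast and washes out fast,
while healthy liver — which actively concentrates ICG — rises slowly,
peaks late (~80 s) and retains signal. `icgdyn` turns 90-second
dual-channel surgical recordings (white-light RGB for tracking + 8-bit NIR
for signal) into quantitative tissue characterization:

- **Trace extraction** — normalized cross-correlation tracking of annotated
  regions of interest (ROIs) on the white-light channel, with synchronous
  mean-intensity extraction from the NIR channel at 30 fps. Overlay-only
  systems (green ICG overlay burned into the RGB image) are handled by
  green-channel conversion with a fixed ROI.
- **Milestone features** — twelve curve milestones per ROI: time to peak
  `Tmax`, peak intensity `Fmax`, end intensity, upslope, time ratio
  `T½/Tmax`, the peak→peak+10 s intensity change and the 10/20/60 s
  post-peak slopes, value-distribution skew and excess kurtosis, and the
  intensity-weighted centre of mass (COM). Healthy curves have no early
  peak, so their outflow slopes are anchored at the mapped lesion peak time
  (the mean lesion `Tmax` of the same recording).
- **Classification** — an "optimisable tree": exhaustive decision-tree
  hyperparameter search scored by 10-fold cross-validation, 80:20
  stratified split, reported as a confusion matrix with accuracy, lesion
  PPV and per-class TPR/FNR.
- **Whole-field 2D heatmaps** — thin-plate-spline video stabilization from
  matched landmarks (7 fps post-processing), per-pixel curves, COM and
  outflow-slope maps, and unsupervised k-means clustering of
  piecewise-constant profile approximations to delineate lesions.
- **Cohort statistics & microscopy** — Shapiro–Wilk screening and
  Mann–Whitney U group tables; signal-per-area quantification of
  fresh-frozen section images and the H&E staining attenuation ratio.
- **Synthetic angiograms** — since surgical recordings cannot be shipped, a
  first-class generator renders dual-channel scenes and ROI-trace cohorts
  with known ground truth, calibrated so the extracted milestones reproduce
  published per-class milestone statistics (see `icgdyn.reference`).

## Worked example

```python
import warnings
from icgdyn.synth_scene import simulate_cohort
from icgdyn.perfusion_features import compute_feature_table
from icgdyn.cohort_stats import build_table, format_table
from icgdyn.roi_classifier import split, optimize_tree, evaluate

traces = simulate_cohort(seed=1)            # 132 CRLM / 24 healthy / 6 cyst ROIs
table = compute_feature_table(traces)       # 12 milestones per ROI
print(format_table(build_table(table)))

train, test = split(table, 0.2, seed=1)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")         # 6 cysts < 10 folds notice
    clf = optimize_tree(train, folds=10, seed=1)
print(evaluate(clf, test).summary())
```

prints (abridged):

```
Tmax (time to peak intensity) (s)      23.869 ± 12.480    83.987 ±  3.627  p=<0.001*
Fmax (peak intensity) (g.u.)          129.264 ± 46.683   193.066 ± 39.759  p=<0.001*
Intensity change: peak to peak+10 s   -24.188 ±  6.796     9.430 ± 17.614  p=<0.001*
Slope 10 s from peak (g.u./s)          -2.419 ±  0.680     0.943 ±  1.761  p=<0.001*
Centre of mass (s)                     47.826 ±  2.500    69.124 ±  4.767  p=<0.001*
...
                      crlm      healthy  benign_cyst
         crlm           26            0            0
      healthy            0            5            0
  benign_cyst            0            0            1
accuracy 100.0 %  PPV(crlm) 100.0 %
```

The lesion column reproduces the published milestone statistics the
generator is calibrated to (mean `Tmax` ≈ 23.9 s, `Fmax` ≈ 124 g.u., 10 s
intensity change ≈ −24.5 g.u.); healthy tissue peaks late with positive
mapped-peak slopes, and the optimized tree separates the three tissue
classes on the held-out split.

The command-line interface mirrors the library:

```bash
icgdyn simulate --out scene/ --seed 4                      # synthetic recording
icgdyn extract  --video w.tif --nir n.tif --rois rois.json --out traces/
icgdyn features --traces traces/ --out features.csv
icgdyn classify train --features features.csv --out model.json --seed 1
icgdyn map      --video w.tif --nir n.tif --out maps/      # COM/slope/cluster PNGs
icgdyn stats    --features features.csv --out table.csv
```

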
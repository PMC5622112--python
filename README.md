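# morphoscreen

Label-free quantification of drug-induced morphological change in single
cells, for people building or evaluating image-based phenotypic screens
without fluorescent labels. The package implements the full analysis chain
of a bright-field imaging-flow-cytometry screen — and, because such screens
rarely publish raw images, a synthetic-data generator that reproduces their
statistical structure end to end.

The pipeline:

1. **Simulate** single-cell bright-field frames (or a fast parametric
   feature-table surrogate) for a negative control plus a 10-fold dilution
   series (1 nM – 10 µM), two treatment durations (12 h, 24 h) and two
   experimental repeats. The morphological effect follows a Hill curve in
   dose, peaks near 1 µM and partially rolls back at 10 µM.
2. **Reconstruct** 2D frames from 1D line-scan waveforms (line-scan
   instruments emit one intensity profile per laser pulse) and **segment**
   one cell per frame.
3. **Extract** a fixed 548-feature morphological profile per cell:
   43 geometry (indices 1–43), 10 granularity (44–53), 43 intensity
   (54–96) and 452 texture features (97–548).
4. **Classify** treated vs control populations with a linear SVM. The
   decision score is *Y* = **w**·**x** + *b*, where **w** is the normal
   vector to the separating hyperplane and *b* the bias; accuracy is
   *A* = (*X*₁ + *X*₂)/*N*, the correctly assigned incidences of the two
   classes over the test size (50% = chance, 100% = perfect), estimated by
   stratified 10-fold cross-validation with four control×treated trial
   pairings per dose.
5. **Quantify** the distributional distance with the unbiased empirical
   squared maximum mean discrepancy under a Gaussian kernel,

   MMD²[ℋ, X, Y] = 1/(m(m−1)) Σ_{i≠j} k(xᵢ,xⱼ) + 1/(n(n−1)) Σ_{i≠j} k(yᵢ,yⱼ)
   − 2/(mn) Σ_{i,j} k(xᵢ,yⱼ),

   whole-space and per feature, rank features by their MMD score
   √max(0, MMD²), and trace classification accuracy as low-MMD features
   are eliminated. Single models trained at one condition are transferred
   across doses and repeats.

## Worked example

```python
import pandas as pd
from morphoscreen import RunConfig, run_pipeline

config = RunConfig(n_per_condition=500, seed=7)
report = run_pipeline(config, outdir="demo")

curve = pd.DataFrame(report["dose_response"])
curve["dose_M"] = curve["dose_M"].map("{:.0e}".format)
print(curve.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print("MMD argmax dose per experiment:", report["mmd_argmax_dose"])
print("top-decile per-feature MMD correlation between repeats:",
      round(report["per_feature_mmd_top_decile_r"], 3))
```

prints

```
 duration_h dose_M  accuracy  se_trials  mean_cv_se  n_trials
         12  1e-09     0.503      0.007       0.015         4
         12  1e-08     0.504      0.014       0.016         4
         12  1e-07     0.593      0.004       0.015         4
         12  1e-06     0.650      0.007       0.013         4
         12  1e-05     0.575      0.006       0.014         4
         24  1e-09     0.491      0.011       0.015         4
         24  1e-08     0.504      0.008       0.019         4
         24  1e-07     0.695      0.007       0.014         4
         24  1e-06     0.808      0.010       0.011         4
         24  1e-05     0.684      0.009       0.013         4
MMD argmax dose per experiment: {'1': 1e-06, '2': 1e-06}
top-decile per-feature MMD correlation between repeats: 0.961
```

Reading the output: at 1 nM the treated population is indistinguishable
from control (accuracy ≈ 0.5, chance); separability rises with dose, peaks
at 1 µM, and drops again at 10 µM, with the 12 h curve uniformly below the
24 h curve — the configured rise–peak–rollback structure, recovered by the
classifier. The unsupervised MMD identifies the same peak dose in both
repeats, and the per-feature MMD scores of the two independent repeats
correlate strongly in their top decile, i.e. both repeats agree on *which*
features carry the morphological change.

The same stages are available from the shell:

```bash
morphoscreen simulate --n 500 --seed 7 --out table.csv
morphoscreen classify curve table.csv --out curve.csv
morphoscreen mmd per-feature table.csv --out ranking.csv
morphoscreen run --seed 7 --outdir results/
```

## Layout

```
src/morphoscreen/
  synthetic.py     dose-response model, phenotype sampling, rendering,
                   line-scan streams, parametric feature tables
  reconstruct.py   waveform stacking, frame detection, segmentation
  features/        548-feature registry + geometry, granularity,
                   intensity, texture extractors
  classify.py      linear SVM, accuracy, cross-validation, dose-response
                   curves, transfer matrices, score histograms
  mmd.py           unbiased MMD^2, median-heuristic bandwidth, per-feature
                   ranking, elimination curves
  pipeline.py      end-to-end orchestration and reporting
  cli.py           `morphoscreen` console entry point
```

See `docs/methods.md` for the model, the numerical choices and the known
limitations.
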
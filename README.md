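# embryo3d

A two-stage pipeline for predicting blastocyst implantation from tomographic
time-lapse stacks plus clinical factors:

1. **Background elimination** — a compact U-style encoder–decoder segments
   the blastocyst out of each of the 11 focus-plane slices (364 × 364 px,
   10 µm pitch), removing the culture-well frame and background clutter.
2. **3-D reconstruction** — masked slices are area-resampled to 111 × 111,
   stacked bottom→top and min–max normalized into an `11 × 111 × 111` volume.
3. **CEE encoding** — nine clinical/morphological factors (maternal age,
   transfer count, AMH, day-3 blastomeres, day-3 grade, cryopreservation
   day, ICM grade, TE grade, mean diameter) are each mapped to a
   probability-like scalar through a fitted univariate regression function
   (logistic / scaled-logistic / scaled-Gaussian / linear families; the
   bundled coefficient set ships in `embryo3d/data/regression_specs.json`).
4. **Fusion classifier** — a small 3-D CNN encodes the volume; its feature
   vector is catenated with the nine CEE scalars and a 2-class softmax head
   emits the implantation confidence score. Variants: `fusion3d`,
   `single_image` (center slice only), `no_background` (no masking).
5. **Evaluation** — ROC/AUC with DeLong SE and paired test, Wald 95% CI,
   Youden cut-off, confusion statistics, Mann–Whitney U, balanced two-way
   ANOVA over (L2 × augmentation) grids, and SART age-band subgroup AUCs.

Everything runs on one CPU. The neural networks are implemented on a small
numpy layer core in `embryo3d/_nn` (no GPU frameworks required), and a
seeded synthetic phantom generator (`embryo3d.synthetic_data`) produces
blastocyst-like stacks with ground-truth masks and matching clinical tables
so the full pipeline is testable offline.

## CLI

```bash
# full synthetic demo: synthesize -> segment -> reconstruct -> train -> evaluate
embryo3d demo --n 60 --seed 1 --out run/

# individual stages (share one run directory; stages are cached by config hash)
embryo3d synthesize --n 60 --seed 1 --out run/
embryo3d segment    --out run/ --seed 1
embryo3d reconstruct --out run/ --variant fusion3d
embryo3d train      --out run/ --variant fusion3d --l2 0.02 --augment 10 --seed 1
embryo3d evaluate   --scores run/scores.csv --out run/metrics.json
embryo3d report     --run-dir run/
```

`evaluate` accepts any CSV with `score,label[,age]` columns and writes a
metrics JSON (AUC ± DeLong SE, CI, Youden cut-off, confusion statistics,
per-age-band AUCs) plus a `roc_curve.tsv`.

## Layout

```
src/embryo3d/
  _nn/              numpy layer core (conv2d/3d, batchnorm, pooling, Adam)
  synthetic_data.py seeded phantom stacks + clinical tables + outcome model
  segmentation.py   SliceStack, U-style segmenter, IOU/mIOU
  reconstruction.py Volume3D, area resize, rotation augmentation
  cee_features.py   regression families, fitting, multicollinearity screen
  classifier.py     fusion model, nested-CV plan, training, ablation variants
  evaluation.py     DeLong ROC, Youden, confusion, Mann–Whitney, ANOVA
  io_utils.py       TIFF/PNG/CSV/JSON readers and writers
  pipeline.py/cli.py  staged orchestration and the click CLI
```
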
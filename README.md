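# cystseg

Automated cyst quantification for **engineered polycystic kidney tubules**.

Autosomal dominant polycystic kidney disease (ADPKD) is studied in vitro by
seeding patient-derived epithelial cells into 3D-printed scaffold channels;
the resulting engineered tubules form cysts whose number and size measure
disease progression and drug response. Quantifying those cysts from RGB
immunofluorescence images (red = tissue, blue = nuclei, green = irrelevant
markers/noise) by hand does not scale. `cystseg` implements the full
evaluation pipeline for automating it:

* **no-G preprocessing** — muting the green channel while keeping a
  3-channel layout, plus the standard training-time augmentations
  (flip, ±90° rotation, brightness/contrast/gamma, CLAHE, ImageNet
  normalization);
* **pluggable segmentation backends** — anything mapping an image to a
  per-pixel cyst probability map, binarized at 0.5. A compact
  CPU-trainable encoder–decoder reference net (pure numpy) ships with the
  standard recipe: BCE loss, Adam at lr 10⁻⁴, batch 8, cosine annealing
  with warm restarts (T₀ = 10, T_mult = 2), early stopping on validation
  IoU with patience 10;
* **postprocessing** — flood-fill hole filling, optional opening/closing
  with a circular structuring element of expert-chosen size *k*;
* **pixel-wise and cyst-wise metrics** — with per-object matching into
  detected (DT), missed (MS) and wrong (WR) cysts;
* **leave-one-tubule-out (LOTO) cross-validation** and micro/macro
  aggregation by tubule, treatment, experiment and cyst-size zone;
* **a synthetic scene generator** — tubule-like fluorescence images with
  exact ground truth, and a perturber that corrupts ground truth into
  "predictions" with known DT/MS/WR outcomes, so the whole pipeline is
  testable without microscope data.

## The metrics

With per-pixel counts TP/FP/FN,

    IoU = TP / (TP + FP + FN),  Pr = TP / (TP + FP),  Re = TP / (TP + FN).

Pixel metrics over-weight large cysts, so the same formulas are lifted to
the object level. Connected components of prediction and ground truth are
matched one-to-one (greedily by descending pairwise IoU); a ground-truth
cyst overlapping ≥ 1 pixel of a matched prediction is **detected** (DT),
an unmatched ground-truth cyst is **missed** (MS), an unmatched prediction
is **wrong** (WR). Several predictions on one cyst resolve to one DT plus
WRs; one prediction spanning N cysts to one DT plus N−1 MS. Then

    IoU_cyst = DT / (DT + MS + WR),  Pr_cyst = DT / (DT + WR),  Re_cyst = DT / (DT + MS).

Object-level results are stratified into six equal-cardinality cyst-area
zones (default boundaries 34.7 / 53.3 / 78.7 / 120.9 / 207.5 µm²).

## Worked example

```sh
cystseg generate --out demo --n-tubules 4 --images-per-tubule 2 --seed 0
cystseg evaluate --catalog demo/catalog.csv --gt-as-pred --out demo/report
python -c "import json; print(json.load(open('demo/report/summary.json'))['totals'])"
```

prints

```
{'tp': 12859, 'fp': 0, 'fn': 0, 'dt': 31, 'ms': 0, 'wr': 0}
```

— evaluating the ground truth against itself: all 12 859 cyst pixels are
true positives and all 31 cysts are detected, so all six metrics are 1.0
(see `summary_over_tubules` in the same file). Replacing `--gt-as-pred`
with `--pred-dir <masks>` or `--checkpoint <model.npz>` evaluates real
predictions; `--post close --k 5` applies closing, which merges
over-segmented fragments of a single cyst and reduces WR.

Training and prediction from the same catalog:

```sh
cystseg train --catalog demo/catalog.csv --out demo/run --max-epochs 10 --seed 1
cystseg predict --catalog demo/catalog.csv --checkpoint demo/run/checkpoint.npz --out demo/pred
cystseg evaluate --catalog demo/catalog.csv --pred-dir demo/pred --out demo/report2
```

The same operations are available as a library; see the estimator
`cystseg.CystSegmenter` (scikit-learn style `fit` / `predict_proba` /
`predict`) and the functions re-exported from `cystseg`.

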
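# mammofuse

Classification of breast masses on mammography as benign or malignant, from
rectangular regions of interest (ROIs) cropped around the mass. The package
implements a fusion pipeline that combines three kinds of evidence per ROI:

1. **Hand-crafted radiomics features** — a 455-dimensional texture/shape
   vector: first-order histogram statistics, Hu moment invariants, gray-level
   co-occurrence (GLCM, 14 Haralick descriptors × 4 directions), gray-gradient
   co-occurrence (GLGCM), gray-level difference statistics (GLDS), gray
   run-length matrices (GLRLM, 11 descriptors × 4 directions), local binary
   patterns (LBP), Gaussian Markov random field coefficients (GMRF), and a
   20-filter Gabor bank.
2. **Deep features** — a dual-backbone fusion network (VGG16-style stack
   pooling to 512 channels + Inception-V3-style stack pooling to 2048, global
   max pooling, FC head 2560 → 2048 → 1024 → 2); the activation of the second
   fully connected layer is the 1024-d deep feature.
3. **Clinical parameters** — five ordinally coded covariates: mass shape
   (1 round / 2 oval / 3 irregular), margin type (1 clear … 5 spiculated),
   breast composition (1 fatty … 4 extremely dense), age in years, and mass
   size measured as the ROI diagonal in pixels.

The blocks are reduced by minimal-redundancy–maximal-relevance (mRMR) ranking
(455 → 30 hand-crafted, 1024 → 27 deep), min-max scaled to [0, 1] on
training-set extrema, concatenated (27 + 30 + 5 = 62 values) and classified by
a linear-kernel SVM whose penalty C is chosen by stratified 10-fold
cross-validated grid search. Evaluation reports the confusion matrix,
sensitivity/specificity/accuracy/precision/F1, the ROC curve with trapezoidal
AUC, and DeLong's paired test for comparing two models' AUCs on the same
samples. Sensitivity always means the malignant detection rate (positive
class = malignant).

Because clinical mammography datasets cannot be redistributed, the package
ships a seeded synthetic-data generator (`mammofuse.synthdata`) producing
16-bit mass ROIs with class-dependent morphology — smooth elliptical benign
masses versus spiculated, irregular, high-contrast malignant masses — plus a
clinical table whose covariates correlate with the class label. Every pipeline
stage is testable end to end without downloading anything.

Intended users: medical-image-analysis researchers who want a reproducible,
dependency-light reference implementation of a hybrid (hand-crafted + deep +
clinical) mass-classification pipeline, or who need the individual stages
(masked texture features, mRMR, DeLong test) as building blocks.

## Worked example

```python
from mammofuse.synthdata import SyntheticSpec
from mammofuse.pipeline import run_pipeline

spec = SyntheticSpec(n_benign=30, n_malignant=30, seed=7)
res = run_pipeline(spec, arms=("Hcr", "Clinical", "Hcr+Clinical"), seed=7,
                   delong_pairs=(("Clinical", "Hcr+Clinical"),))
for name, arm in res.arms.items():
    r = arm.report
    print(f"{name:13s} AUC={r.auc:.3f} acc={r.accuracy:.3f} "
          f"sens={r.sensitivity:.3f} spec={r.specificity:.3f}")
p = res.delong[("Clinical", "Hcr+Clinical")].p_value
print(f"DeLong Clinical vs Hcr+Clinical: p = {p:.3f}")
print("top hand-crafted features:", res.hcr_selection.ranked_names[:5])
```

prints

```
Hcr           AUC=1.000 acc=1.000 sens=1.000 spec=1.000
Clinical      AUC=1.000 acc=1.000 sens=1.000 spec=1.000
Hcr+Clinical  AUC=1.000 acc=1.000 sens=1.000 spec=1.000
DeLong Clinical vs Hcr+Clinical: p = 1.000
top hand-crafted features: ['hist.mean', 'hist.minimum', 'glgcm.gradient_mean', 'gabor.s8_o36_energy', 'glrlm.srlge.d45']
```

Held-out metrics are all 1.000 here because the default synthetic classes are
strongly separable by design (spiculation, texture correlation length and the
clinical covariate distributions all differ); `spec.null()` produces the
no-signal control where held-out AUC drops to chance. Each model arm is one of
seven presets (`Hcr`, `Clinical`, `Hcr+Clinical`, `Deep27`, `Deep27+Hcr`,
`Deep27+Clinical`, `Deep27+Clinical+Hcr`) naming which feature blocks are
fused.

The same workflow is available as composable shell commands:

```bash
mammofuse --workdir run simulate
mammofuse --workdir run preprocess
mammofuse --workdir run extract-hcr
mammofuse --workdir run extract-deep
mammofuse --workdir run select
mammofuse --workdir run train --arm Hcr+Clinical
mammofuse --workdir run evaluate --arm Hcr+Clinical
mammofuse --workdir run compare --arms Hcr,Clinical,Hcr+Clinical --delong Clinical:Hcr+Clinical
```

Each command reads its upstream artifacts (CSV/JSON) from the working
directory and fails with an actionable message naming the missing producer if
run out of order.

## Layout

- `mammofuse.preprocess` — ROI loading (DICOM/PNG/TIFF), background crop,
  min-max normalization, aspect-preserving 224×224 zero-pad resize, cohort
  splitting, dihedral augmentation.
- `mammofuse.handcrafted` — the 455-feature extractor (content-masked).
- `mammofuse.deepfeat` — fusion network, VGG16-style baseline, SGD fine-tuning
  of the FC head, 1024-d feature extraction.
- `mammofuse.select` — mutual information and mRMR ranking (MID/MIQ).
- `mammofuse.classify` — clinical encoding, min-max fusion, linear SVM with
  grid-searched C.
- `mammofuse.evaluate` — metrics, ROC/AUC, DeLong's paired test.
- `mammofuse.synthdata` — seeded synthetic ROIs and clinical tables.
- `mammofuse.cli` / `mammofuse.pipeline` — command-line interface and
  end-to-end orchestration.

See `docs/methods.md` for the modelling choices, parameter defaults and known
limitations.
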
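# vmi-radstab

Radiomic feature stability and classification across virtual monoenergetic
CT images, on fully synthetic phantoms.

Dual-energy CT can reconstruct virtual monoenergetic images (VMI) at many
energies from one acquisition. Radiomic features — quantitative intensity,
shape and texture descriptors of a segmented region — are only useful if
they are stable: repeatable when the scan is repeated, reproducible when the
energy, radiation dose or scanner changes. This package implements the full
analysis chain for that question, driven by a synthetic multi-energy phantom
generator so no scan data is required:

1. **Simulation** — a phantom of 16 ellipsoidal objects in 4 texture classes
   (attenuations spanning fat- to soft-tissue-like HU), imaged at 5 VMI
   energies (40–190 keV), 2 dose levels (5/15 mGy), 2 scanner modes
   (dual-source vs split-filter), with a rigidly repositioned retest scan.
2. **Feature extraction** — an IBSI-style catalogue of 51 features in seven
   families (first order, shape, GLCM, GLRLM, GLSZM, NGTDM, GLDM) after
   isotropic Lagrange resampling, in-mask z-rescaling (×500) and
   fixed-bin-width discretization (width 25).
3. **Stability screening** — per-feature agreement via Lin's concordance
   correlation coefficient, CCC = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²), and
   the normalized dynamic range, DR = 1 − mean|xᵢ−yᵢ| / range(x∪y).
   *Repeatable*: CCC ≥ 0.9 ∧ DR ≥ 0.9 (test–retest); *reproducible*:
   CCC ≥ 0.9 (across conditions). Percentages are compared with one-way
   ANOVA + Tukey HSD.
4. **Classification evaluation** — tournament-leave-pair-out
   cross-validation: every pair of objects is held out once, the pair member
   with the higher predicted class probability wins; win counts give
   one-vs-rest Mann–Whitney AUCs, pooled probabilities give the multiclass
   Brier score BS and its scaled form R² = 1 − BS/BSmax against a
   class-frequency benchmark. Random hyperparameter search over elastic-net
   logistic regression and random forests is debiased with bootstrap bias
   correction (select in-bag, score out-of-bag).

Intended users: imaging scientists who want a tested, deterministic
reference implementation of these statistics, and a controllable sandbox in
which the ground truth (target CCC per feature, class effects, noise levels)
is known exactly.

## Worked example

Extract features from the default phantom at 75 keV (dual-source, 15 mGy),
screen them against the retest scan, and classify the four object classes
with each feature subset:

```python
import pandas as pd
from vmi_radstab.synthetic import (
    AcquisitionCondition, default_phantom_spec, generate_phantom_volume,
)
from vmi_radstab.features import extract_all, FEATURE_NAMES
from vmi_radstab.stability import repeatability_analysis
from vmi_radstab.classify import feature_subsets, run_tournament, ranking_auc

spec = default_phantom_spec(seed=0)
labels = pd.Series({o.object_id: o.class_label for o in spec.objects})

tables = {}
for repeat in (0, 1):
    cond = AcquisitionCondition(energy_kev=75, dose_mgy=15,
                                scanner="DSDE", repeat_id=repeat)
    volume, masks = generate_phantom_volume(spec, cond)
    rows = {oid: extract_all(volume, mask) for oid, mask in masks.items()}
    tables[repeat] = pd.DataFrame.from_dict(rows, orient="index")[list(FEATURE_NAMES)]

records, pct = repeatability_analysis(tables[0], tables[1])
print(f"repeatable features (CCC and DR >= 0.9): {pct:.1f}%")

subsets = feature_subsets(records)
for name in ("all", "repeatable", "non_repeatable"):
    result = run_tournament(tables[0], labels, subset=subsets[name])
    per_class, mean_auc = ranking_auc(result, labels)
    print(f"{name:>14}: {len(subsets[name]):2d} features, "
          f"mean one-vs-rest AUC = {mean_auc:.3f}")
```

prints

```
repeatable features (CCC and DR >= 0.9): 51.0%
           all: 51 features, mean one-vs-rest AUC = 1.000
    repeatable: 26 features, mean one-vs-rest AUC = 1.000
non_repeatable: 25 features, mean one-vs-rest AUC = 0.917
```

About half the catalogue survives the test–retest screen at this condition
(z-rescaling deliberately sacrifices location/scale features; noise-grain
features fail on their own). The four classes are separated perfectly with
all or with repeatable features; restricting to the *non*-repeatable
features degrades both discrimination and calibration.

The same analysis runs from the shell:

```bash
vmi-radstab run --config examples/experiment.yaml --out results/
vmi-radstab simulate-images --seed 0 --out volumes/    # NRRD volumes + masks
vmi-radstab validate --config examples/experiment.yaml
```

`run` writes per-condition feature CSVs, stability records, the
cross-energy reproducibility matrix, the group ANOVA summary and the
classification grid, plus a manifest with the configuration hash and all
seeds; re-running the same configuration reproduces every table
byte-identically and reuses the cached extraction stage.

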
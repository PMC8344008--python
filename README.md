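# psmavol

Whole-body tumor-volume quantification on PSMA PET, and the survival
analysis that asks whether that volume — and its change under
[¹⁷⁷Lu]-PSMA radioligand therapy — predicts overall survival in metastatic
castration-resistant prostate cancer (mCRPC).

The package is aimed at quantitative-imaging researchers who want a tested,
scriptable implementation of the liver-referenced segmentation workflow and
its downstream statistics, exercised end-to-end on synthetic PET phantoms
and simulated cohorts (no patient data required).

## What it computes

**Segmentation.** All tracer foci with SUVmax above a liver-referenced
adaptive threshold

```
threshold = (4.3 / SUVmean_liver) × (SUVmean_liver + SUVsd_liver)
```

are detected as 26-connected components; foci dominated by physiological
uptake (liver, spleen, kidneys) are removed (reviewer include/exclude lists
replace the interactive check); each retained metastasis is delineated by
the connected 50%-of-local-SUVmax isocontour around its hottest voxel.

**Per-scan burden metrics.**

- `PSMA-TV` = Σ lesion volumes (ml) — whole-body tumor volume;
- `TLQ` = Σ (volume / SUVmean) per lesion — up-weights bulky, low-uptake disease;
- `meanSUVmax` = unweighted mean of per-lesion SUVmax — average PSMA expression.

**Response and expression flags** (strict boundaries): volumetric response
= PSMA-TV decline > 30%; biochemical response = best PSA decline > 50%;
low PSMA expression = baseline meanSUVmax ≤ 14.3.

**Survival plan.** Log-transformed uni-/multivariable Cox regression (Efron
ties, via lifelines), Kaplan–Meier with median or maximally-selected-rank
binarization, log-rank tests, Breslow-baseline Martingale residuals,
Spearman/Wilcoxon comparisons — including the expression-confounding
contrast: volumetric response evaluated in the full cohort versus after
excluding low-expression patients, whose apparent volume loss can reflect
antigen loss rather than tumor kill.

## Worked example

```python
import numpy as np
from psmavol import (default_body_phantom, generate_phantom, segment_scan,
                     aggregate_scan, classify_tv_response)

phantom = generate_phantom(default_body_phantom(seed=7))   # torso + 3 lesions
lesions = segment_scan(phantom.volume, phantom.organ_masks)
for les in lesions:
    print(f"lesion {les.lesion_id}: {les.volume_ml:.2f} ml, "
          f"SUVmax {les.suv_max:.1f}, TLQ {les.tlq_lesion:.3f}")
scan = aggregate_scan(lesions)
print(f"PSMA-TV = {scan.psma_tv_ml:.2f} ml, meanSUVmax = {scan.mean_suv_max:.1f}")
```

prints

```
lesion 0: 5.91 ml, SUVmax 10.0, TLQ 0.591
lesion 1: 3.11 ml, SUVmax 15.0, TLQ 0.207
lesion 2: 1.43 ml, SUVmax 20.0, TLQ 0.072
PSMA-TV = 10.46 ml, meanSUVmax = 15.0
```

On this noise-free, blur-free phantom the three recovered volumes equal the
ground-truth lesion volumes voxel-exactly (5.91 / 3.11 / 1.43 ml); each
lesion's TLQ is its volume divided by its SUVmean, and the scan total sums
them.

The same stages run from the shell:

```bash
psmavol simulate --seed 1 --out-dir sim        # cohort CSV + demo phantom
psmavol segment  --pet sim/phantom_pet.nii.gz --organs sim/phantom_organs.nii.gz
psmavol analyze  --cohort sim/cohort.csv --out-dir analysis
psmavol run      --config config.yaml --seed 1 --out-dir out   # full pipeline
```

`analyze` writes `report.json` plus `cox_results.csv`, `cutoffs.csv`,
`martingale.csv`, `km_curves.csv` and Kaplan–Meier plots.

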
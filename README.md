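# srfseg — automatic split renal function from PSMA PET/CT

PSMA-targeted PET tracers ([18F]PSMA-1007, [68Ga]Ga-PSMA-11) accumulate
physiologically in the renal cortex, so the left/right split of renal
uptake tracks split renal function (SRF) as measured by MAG3 renography or
DMSA scintigraphy. Measuring it manually means segmenting both kidneys in
3D — slow enough to be impractical. `srfseg` automates the measurement for
nuclear-medicine researchers: a trainable 3D U-Net labels left and right
kidneys from the paired CT (Hounsfield units) and PET (SUV) volumes, and
the package reports the left renal function percentage

    LRF% = 100 · Σ SUV(left kidney) / [Σ SUV(left) + Σ SUV(right)]

together with kidney volumes, plus the full multi-reader agreement
analysis (Dice–Sørensen coefficients, volume and LRF% differences,
Spearman correlations, Bland–Altman bias and limits of agreement).

Because clinical PET/CT with expert annotations cannot ship with a
package, `srfseg` includes a synthetic abdominal phantom simulator with
*analytically known* ground truth — body outline, spine, organs, cortex +
pelvis kidneys, bladder, optional distractor lesions, PSF blur and noise —
so the entire pipeline (training recipe, postprocessing, statistics) is
testable on any desktop. See `docs/methods.md` for the model and phantom
details.

## What's inside

| module | purpose |
|---|---|
| `srfseg.volumes` | NIfTI I/O in a fixed anatomical convention, grid resampling |
| `srfseg.phantom` | phantom specs, cohort generator, surrogate readers |
| `srfseg.augment` | paired spatial + HU-intensity augmentation |
| `srfseg.nn` | NumPy 3D U-Net, weighted deep-supervision cross-entropy, Nadam |
| `srfseg.training` | patch sampler, lr schedule, `fit()` → `TrainingResult` |
| `srfseg.measure` | argmax decoding, largest-26-connected-component cleanup, LRF% |
| `srfseg.agreement` | Dice / Bland–Altman / Spearman, Table-style reports |
| `srfseg.cli` | `srf simulate | train | segment | measure | evaluate` |

The training recipe follows the clinical setup: two-channel input on a
2.73 × 2.73 × 2.79 mm grid, 160³ same-padding patches, class weights 5/5/1
(left/right kidney/background), deep supervision, Adam with Nesterov
momentum at lr 5e-5 decayed 1.5% per epoch, 10,000 samples × 100 epochs
(`--profile full`). A `desk` profile (32³ patches, 2-level net, 200
samples × 20 epochs) runs the same machinery at laptop scale.

## Worked example

```sh
srf simulate -n 24 --seed 7 -o cohort/            # 64³ phantoms + manifest
srf train --cohort cohort/ --profile desk --seed 7 -o run/
srf segment --ct cohort/case_016/ct.nii.gz --pet cohort/case_016/pet.nii.gz \
            --model run/model.npz --out-mask mask.nii.gz --out-json srf.json
srf evaluate --cohort cohort/ --model run/model.npz --readers 2 -o report/
```

`srf measure --pet … --mask …` skips inference and measures LRF% from any
existing mask (e.g. a manual segmentation).

A run of the same experiment through the reproduction script below
(seed 1) prints, for the 8 held-out phantoms:

```
"median_heldout_kidney_dsc":        0.9351
"min_heldout_kidney_dsc":           0.8687
"median_abs_lrf_error_ppt":         1.204
"max_abs_lrf_error_ppt":            1.554
"min_model_vs_reader_spearman_lrf": 0.905
"max_pipeline_mirror_asymmetry_ppt": 1.4e-14
"first_epoch_mean_loss":            1.0986
"final_epoch_mean_loss":            0.0794
```

Read: the desk-trained model overlaps the true kidney masks at a median
Dice of ~0.94 (worst kidney 0.87), its LRF% stays within ~1.5 percentage
points of the phantom's analytic truth on every held-out case, its LRF%
ranking agrees strongly with surrogate readers, and mirroring a case flips
the measurement to its exact complement. The training loss starts at
ln 3 ≈ 1.099 (uninformed three-class prediction) and descends by an order
of magnitude.

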
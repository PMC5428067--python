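# wmgm4d — white-matter / gray-matter segmentation in 4D CT of the brain

Time-resolved (4D) CT captures the passage of a contrast bolus through the
whole brain, combining anatomy with perfusion in a single acquisition.
Segmenting white matter (WM) and gray matter (GM) directly in 4D CT enables
tissue-dependent perfusion analysis, volumetry and pathology detection — but
soft-tissue contrast in CT is small (≈10 HU between WM and GM), so the
segmentation must squeeze information out of both the averaged anatomy and
the contrast dynamics. This package implements such a pipeline end to end,
for image-analysis researchers working on CT brain segmentation, together
with a synthetic 4D digital head phantom that provides exact voxel truth for
validation.

## Method

1. **Weighted temporal average (WTA).** The N volumes of the 4D series are
   averaged with weights ω_i = E_i / ΣE_i (exposure E_i in mAs). Because
   quantum noise obeys σ ∝ 1/√E, these are the reciprocal-variance weights
   minimising σ²_WTA = Σ ω_i²σ_i², giving σ²_WTA = 1/Σ σ_i⁻² — a 3D image
   whose noise depends only on the *total* exposure.
2. **Intracranial segmentation.** A coarse brain mask is eroded (3 voxels),
   turned into a signed distance, and evolved as a geodesic active contour
   Φ_t = −g(1+εκ)|∇Φ| + α∇g·∇Φ with edge speed g(I) = exp(−(‖∇I‖/γ)²)
   (ε = 1, α = 5, γ = 80, narrow band 9 voxels): the front grows outward
   through tissue and locks onto the inner skull surface.
3. **Coarse CSF/vessel masking.** From the intracranial WTA histogram in
   [0, 400] HU, CSF = voxels below μ − 1.96σ and vessels = voxels above
   μ + 1.96σ, each cleaned by radius-1 erosion and connected re-growing;
   what remains is soft tissue (WM ∪ GM).
4. **Voxel classification.** Every soft-tissue voxel gets a 120-element
   descriptor (10 intensity + 6 contextual + 104 temporal features) and is
   classified WM vs GM by an RBF-kernel SVM (C = 2¹⁰, γ = 2⁻¹¹, Platt
   probabilities, 1 % training subsample; 12×12 power-of-two grid search
   maximising A_z available).
5. **Evaluation.** Dice, AVD, Hausdorff / modified / 95th-percentile
   Hausdorff and contour mean distance, computed per axial slice and
   aggregated (mean or max) as appropriate; merged-fold ROC with bootstrap
   confidence intervals.

See `docs/methods.md` for assumptions, defaults and numerical choices.

## Worked example

Three phantom cases, leave-one-out cross-validation with the full feature
set:

```python
from wmgm4d.phantom import PhantomSpec
from wmgm4d.pipeline import PipelineConfig, phantom_case, run_loocv

cases = [phantom_case(PhantomSpec(rng_seed=i), f"case{i}") for i in range(3)]
result = run_loocv(PipelineConfig(seed=0), cases)
print(result.report.to_table()[["DC", "AVD", "HD95", "CMD"]])
print(f"merged A_z = {result.roc.az:.3f}")
```

prints

```
                    DC          AVD         HD95          CMD
structure
GM         1.00 ± 0.00  0.16 ± 0.12  3.22 ± 2.82  0.02 ± 0.01
WM         1.00 ± 0.00  0.12 ± 0.07  7.13 ± 7.15  0.04 ± 0.03
merged A_z = 1.000
```

Each row is one structure, aggregated over the three folds (mean ± std):
`DC` is the slice-wise Dice overlap with the phantom truth, `AVD` the
absolute volume difference in %, `HD95`/`CMD` boundary distances in mm.
The near-perfect values reflect the phantom's idealised geometry and crisp
labels — they verify the pipeline, they do not predict clinical accuracy.
The merged A_z is the area under the ROC curve over the pooled held-out
voxel probabilities of all folds.

The same pipeline is scriptable from the shell:

```bash
wmgm4d phantom --out-dir scratch/case0 --seed 0
wmgm4d wta --series scratch/case0/vol_*.nii.gz \
           --protocol scratch/case0/protocol.cfg --out scratch/wta.nii.gz
wmgm4d loocv --out-dir scratch/loocv --cases 3 --seed 0
```

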
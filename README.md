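# sparsesvr

Slice-to-volume reconstruction (SVR) of an isotropic 3D volume from multiple
stacks of thick 2D slices that are corrupted by per-slice rigid motion **and**
sparsely sampled (a large fraction of pixels missing). The setting is
fetal-brain-style MRI: fast single-shot T2 stacks in axial/coronal/sagittal
orientations, where shortening acquisition by dropping samples trades directly
against reconstruction quality. The package is aimed at image-reconstruction
researchers who want a transparent, CPU-only reference implementation with a
fully synthetic validation path.

## Method

The reconstruction interleaves five components:

1. **Motion scoring and template choice.** Each stack's slices are vectorized
   into a data matrix `D`; the relative error of its best rank-r
   approximation, `δ_r = √(Σ_{i>r} s_i²) / √(Σ_i s_i²)` from the singular
   values `s_i`, measures how far motion breaks inter-slice correlation. The
   surrogate `μ = δ_{r*}·r*` with `r* = argmin_r{δ_r < β}` ranks stacks; the
   least-moving stack becomes the registration template.
2. **Rigid 2D/3D registration.** Stack-to-template and slice-to-volume
   registration minimize `1 − NCC` over the 6 rigid parameters (Powell,
   3-level pyramid). Slice registration compares the observed slice against
   the slice *simulated* from the current volume at the candidate pose.
3. **Gaussian-PSF volume update.** Every valid pixel scatters its corrected
   intensity `S′·exp(−B)·I` into nearby voxels weighted by a separable
   Gaussian slice profile (FWHM = slice thickness through-plane, = pixel
   spacing in-plane); accumulated weights normalize the gather.
4. **EM robust outlier rejection.** Residuals between acquired and simulated
   slices are modeled as a Gaussian-inlier/uniform-outlier mixture
   `P(e) = c·N_σ(e) + (1−c)·U`; per-pixel posteriors `p_ij` weight the
   scatter, and slices with mean squared posterior `p_slice = Σ p_ij²/N_j`
   below threshold are excluded.
5. **Adaptive steering kernel regression** (the core contribution): every
   voxel is re-estimated by order-2 local polynomial regression
   `Y_i ≈ β₀ + β₁ᵀ(X_i−X) + β₂ᵀ vech((X_i−X)(X_i−X)ᵀ)` under the steering
   kernel `K_s ∝ √det(C_i) · exp(−(X_i−X)ᵀC_i(X_i−X)/2h_s²)`, whose
   covariance `C_i` is built from local gradient structure — elongated along
   edges, wide in flat regions. Gradients, covariances and estimates are
   iterated three times, filling voxels that sparse sampling left empty.

## Worked example

```python
import sparsesvr as svr

phantom = svr.generate_phantom((64, 64, 64), spacing=1.0, seed=0)
acq = svr.AcquisitionConfig(removal_proportion=0.7, noise_sigma=2.0,
                            motion_amplitude=(0.0, 0.0), seed=13)
stacks, truth = svr.simulate_dataset(acq, gt=phantom)

cfg = svr.PipelineConfig(outer_iterations=1, register_stacks=False,
                         register_slices=False)
vol, manifest = svr.reconstruct(stacks, cfg, grid=phantom)
print(svr.evaluate_volumes(vol.voxels, phantom.voxels).as_dict())
```

prints (numbers from this exact run):

```
{'rmse': 19.599630229717953, 'mssim': 0.8246446943996855,
 'n_windows': 195112, 'window_size': 7, 'dynamic_range': 220.0}
```

i.e. with 70 % of all pixels removed the reconstructed volume differs from
the ground-truth phantom by 19.6 intensity units RMS (dynamic range 220)
with a mean structural similarity of 0.82; the PSF-only ablation
(`use_steering=False`) on the same data gives RMSE 36.9 and MSSIM 0.67 —
the steering update recovers most of what sparsity destroyed.

The same pipeline is scriptable from the shell:

```bash
sparsesvr simulate --config acq.yaml --out data/
sparsesvr assess --stacks data/stack0.nii.gz --stacks data/stack1.nii.gz
sparsesvr reconstruct --stacks data/stack0.nii.gz --masks data/mask0.nii.gz \
    --out recon.nii.gz --manifest run.json
sparsesvr evaluate --recon recon.nii.gz --truth data/ground_truth.nii.gz
```

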
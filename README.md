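# ctirecon

Reconstruction and comparison of MRI-based electrical conductivity
tensors. The package implements, as one tested pipeline, five models
that map water diffusion tensors (mm²/s) to low-frequency conductivity
tensors (S/m):

| model | scale factor | inputs |
|-------|--------------|--------|
| LEM   | global η (empirical 0.844 S·s/mm³, or matched from tissue means) | DTI tensor |
| FEM   | global η = 0.76·q²N/(k_BT) | fast tensor of a bi-exponential fit |
| VCM   | per-voxel η = 3σ_iso/trace(D) | DTI tensor + isotropic reference per tissue |
| VFM   | volume-fraction weighted literature conductivities (WM only) | DTI eigenvalues |
| CTI   | per-voxel η = α·σ_H/(α·d_ew + (1−α)·d_iw·β) | fast tensor + high-frequency conductivity map |

Because no scanner data ships with the package, a synthetic-data module
generates ground-truth objects and forward-simulates everything the
models consume: two three-compartment phantoms (electrolytes and giant
vesicle suspensions with known reference conductivities), a brain-like
object (anisotropic WM, isotropic GM, high-conductivity CSF), multi-b
diffusion-weighted stacks via the two-compartment bi-exponential signal
model, and high-frequency conductivity maps. An evaluation module
provides the comparison statistics: ROI mean ± SD, relative errors
against references, signed relative-difference maps against a reference
method, pooled conductivity-vs-diffusion regression R², and
anisotropy-ratio summaries.

## Layout

- `src/ctirecon/tensor_core.py` — symmetric 3×3 tensor fields
  (components stored as `xx, xy, xz, yy, yz, zz`), eigendecomposition,
  mean conductivity/diffusivity, anisotropy ratio.
- `src/ctirecon/synthetic_data.py` — compartment specs, phantom/brain
  generators, DWI and σ_H forward simulation, Rician noise.
- `src/ctirecon/multib_fit.py` — log-linear DTI fit at one b-shell;
  constrained bi-exponential fits (per-direction), assembled fast/slow
  tensors and extracellular volume fraction.
- `src/ctirecon/models.py` — the five reconstructions plus the
  literature-constants container.
- `src/ctirecon/evaluation.py` — ROI erosion and all comparison
  statistics.
- `src/ctirecon/io_cli.py` — NIfTI/bval/bvec/YAML I/O, pipeline
  orchestration, CLI.

## CLI

```sh
# synthesise a phantom (or phantom2 / brain) with optional Rician noise
ctirecon simulate --preset phantom1 --grid 64 64 8 --seed 1 --out sim/

# fit DTI + bi-exponential parameters from NIfTI + bval/bvec
ctirecon fit --in sim/dwi.nii --bvals sim/dwi.bval --bvecs sim/dwi.bvec \
         --mask sim/dwi_brainmask.nii --mode tensor6plus --out fit/

# reconstruct one model (lem|fem|vcm|vfm|cti)
ctirecon reconstruct --model cti --in fit/ --out rec/

# compare a reconstruction against a reference tensor field
ctirecon evaluate --recon rec/C_cti.nii --truth sim/C_true.nii \
         --labels sim/labels.nii --out eval/

# everything end-to-end with a manifest
ctirecon run --preset brain --grid 64 64 8 --seed 1 --out run/
```

All volumes are NIfTI-1; tensor fields are 4-D NIfTI with a JSON
sidecar recording quantity, units and component order; b-tables use the
whitespace-separated one-line-per-quantity text convention.

## Conventions

Diffusivities are mm²/s, b-values s/mm², conductivities S/m; scale
factors therefore carry S·s/(m·mm²) internally, and literature values
quoted in S·s/mm³ are converted by a factor 1000 on ingestion. Sample
(ddof = 1) standard deviations; eigenvalues sorted descending per
voxel; ROI erosion is 2-D in-plane. All fits are deterministic (fixed
multi-start grids, no randomness); simulation is reproducible under a
fixed seed.
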
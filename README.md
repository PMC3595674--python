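# mreit

Simulation and reconstruction toolkit for **magnetic resonance electrical
impedance tomography (MREIT)**: imaging the electrical conductivity of a
slice of tissue from the current-induced magnetic flux density measured in
an MR scanner.

In MREIT two independent currents are injected through surface electrode
pairs ℰ₁± and ℰ₂±. Each current Jⱼ = −σ∇uⱼ perturbs the z-component
B_z,j of the magnetic field, which the scanner encodes in the phase of the
complex images

ℳ± = M·e^{iδ}·e^{±iγ B_z T_c},  γ = 26.75×10⁷ rad/T·s,

so that B_z = arg(ℳ⁺/ℳ⁻)/(2γT_c) after phase unwrapping. The *harmonic
B_z algorithm* recovers the scaled conductivity σ₁ from the in-plane
Laplacians of the two fields via

∇²_{xy} ln σ₁ = ∇_{xy}·( 𝔸⁻¹ [∇²B_{z,1}, ∇²B_{z,2}]ᵀ / μ₀ ),
𝔸 = [[−J_{y,1}, J_{x,1}], [−J_{y,2}, J_{x,2}]],  σ₁ = 1 on ∂Ω_z,

solved once (σ⁰ ≡ 1, no iteration) with P1 finite elements — a contrast
image, exact up to a global scale, which is what clinical interpretation
needs. In vivo data additionally require ramp-preserving structure-tensor
denoising of B_z, automatic repair of MR signal-void regions by harmonic
inpainting (pixels under 10% of the maximum magnitude), and a *local*
variant of the solve on a user-chosen polygon D that isolates a clean
region of interest from corrupted data elsewhere. All of these are
implemented here, together with a full synthetic-experiment generator
(Shepp-Logan-style conductivity phantoms, forward solves, Biot-Savart
B_z, complex-image and k-space synthesis with seeded noise).

## Worked example

```python
import numpy as np
from mreit.pipeline import run_pipeline

cfg = {
    "seed": 1,
    "grid": {"nx": 64, "ny": 64, "dx": 2e-3, "dy": 2e-3, "dz": 2e-3, "nz": 1},
    "phantom": {"ellipses": [[0.0, 0.0, 0.85, 0.85, 0, 1.0],     # domain, 1 S/m
                             [-0.3, 0.15, 0.28, 0.20, 11, 0.8],  # resistive anomaly
                             [0.3, -0.25, 0.20, 0.26, 0, 1.2]]}, # conductive anomaly
    "signal": {"noise_sd": 0.001},
    "denoise": {"enabled": True, "t1": 1.0},
}
case, manifest = run_pipeline(cfg)

ln_sigma = case.arrays["log_sigma_raster"][0]
truth = np.log(case.arrays["sigma"])
ok = np.isfinite(ln_sigma) & case.arrays["domain_mask"].astype(bool)
r = np.corrcoef(ln_sigma[ok], truth[ok])[0, 1]
print(f"reconstructed {ok.sum()} pixels")
print(f"Pearson r(ln sigma_rec, ln sigma_true) = {r:.3f}")
print(f"background sigma_rec  = {np.exp(np.median(ln_sigma[ok & (truth == 0)])):.3f}")
print(f"anomaly (0.8 S/m) rec = {np.exp(ln_sigma[36, 20]):.3f}")  # anomaly centers
print(f"anomaly (1.2 S/m) rec = {np.exp(ln_sigma[24, 41]):.3f}")
```

prints

```
reconstructed 2260 pixels
Pearson r(ln sigma_rec, ln sigma_true) = 0.886
background sigma_rec  = 1.013
anomaly (0.8 S/m) rec = 0.800
anomaly (1.2 S/m) rec = 1.241
```

i.e. from 64×64 noisy simulated MR phase data the one-pass harmonic B_z
solve recovers the conductivity contrast: the background stays at ≈1, the
resistive anomaly reads 0.80 and the conductive one 1.24 (true values 0.8
and 1.2); the correlation with the true log-conductivity map is 0.89.

The same chain is available from the shell:

```bash
mreit run --config sim.yaml --out case.h5     # full pipeline
mreit inspect --in case.h5                    # summary of all arrays/stages
mreit simulate / phase / denoise / inpaint / mesh / reconstruct   # per stage
```

All stage outputs accumulate in one HDF5 container; magnitude and
reconstruction rasters can be exported as NIfTI (`mreit inspect --nifti`).
Exit codes: 0 ok, 2 validation, 3 solver failure, 4 quality-gate refusal
(e.g. a 3D Laplacian requested when the z-continuity check fails).

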
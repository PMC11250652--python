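# ctnmqr — low-rank tensor completion with thin-QR factor updates

`ctnmqr` completes missing entries of dense multiway arrays — synthetic
low-rank tensors, RGB images (H×W×3), MRI volumes — by exploiting their
low Tucker rank. It is aimed at people doing image/volume inpainting and
at anyone benchmarking tensor-completion solvers who wants a fast,
reproducible reference implementation with a plain CLI.

## The method

Given a tensor `T ∈ R^{I_1×…×I_N}` observed on an index set Ω, the solver
finds a completion `X`, a core `C ∈ R^{R_1×…×R_N}` and factor matrices
`U_i ∈ R^{I_i×R_i}` with orthonormal columns by minimizing

```
min  Σ_i α_i ‖C_(i)‖_*  +  (λ/2) ‖X − C ×_1 U_1 ⋯ ×_N U_N‖_F²
s.t. X_Ω = T_Ω,   U_iᵀ U_i = I_{R_i}
```

where `C_(i)` is the mode-i unfolding and `‖·‖_*` the nuclear norm. Because
the factors have orthonormal columns, the unfoldings of the reconstruction
and of the core share singular values, so penalizing the *core's* nuclear
norm is equivalent to penalizing the full tensor's — but the SVTs run on
R×R^{N−1} matrices instead of I×I^{N−1} ones.

The problem is split with core-shaped auxiliary tensors `V_i` and solved by
ADMM with multipliers `Y_i` and a geometrically increasing penalty μ:

1. `V_i ← fold_i( SVT_{α_i/μ}( unfold_i(C + Y_i/μ) ) )` — singular value
   thresholding per mode;
2. `C ← [ μ Σ_i (V_i − Y_i/μ) + λ·(X ×_1 U_1ᵀ ⋯ ×_N U_Nᵀ) ] / (Nμ + λ)` —
   closed form;
3. for each mode, an unconstrained least-squares factor solve followed by a
   **thin QR** orthogonalization — no SVD of any large matricization (an
   SVD-based HOOI-style update is kept as a baseline, `factor_strategy="hooi"`);
4. `X ← T` on Ω, the Tucker reconstruction elsewhere;
5. `Y_i ← Y_i + μ(C − V_i)`, `μ ← min(ρμ, μ_max)`.

Iteration stops when the relative change `‖X^{k+1}−X^k‖_F/‖X^k‖_F ≤ tol`
or after `K` iterations.

## Worked example

```python
import numpy as np
from ctnmqr import SolverConfig, complete, generate_tucker_tensor, rse, sample_mask

truth = generate_tucker_tensor((30, 30, 30), (4, 4, 4), seed=0)
mask = sample_mask((30, 30, 30), mr=0.6, seed=1)
config = SolverConfig(rank=(4, 4, 4), seed=0)
result = complete(truth, mask.observed, config)

print(f"observed entries : {mask.count} of {truth.size} (MR = {mask.missing_rate:.0%})")
print(f"stopped after    : {result.iterations} iterations ({result.stop_reason})")
print(f"final rel. change: {result.rel_change_trace[-1]:.2e}")
print(f"RSE vs truth     : {rse(result.completed, truth):.2e}")
```

prints

```
observed entries : 10800 of 27000 (MR = 60%)
stopped after    : 35 iterations (tolerance)
final rel. change: 8.03e-06
RSE vs truth     : 5.31e-05
```

With 60 % of entries removed from an exactly rank-(4,4,4) tensor, the
solver meets the 1e-5 relative-change tolerance in 35 sweeps and recovers
the missing entries to a relative error of about 5×10⁻⁵ — the
exact-recovery regime: the observed data are noise-free and the rank is
correctly specified, so the only error left is the stopping tolerance.

## Command line

```sh
# complete an image with 80% of pixels missing (simulated mask)
ctnmqr complete photo.png out.png --mr 0.8 --rank 40,40,3 --preset image

# complete a volume whose NaN entries mark the holes
ctnmqr complete scan.nii.gz filled.nii.gz --nan-mask --rank 30,30,20

# synthetic benchmark grid, CSV + per-replicate JSON
ctnmqr benchmark --grid order4 --replicates 10 --seed 0 --csv bench.csv --json bench.json

# RSE between two saved tensors
ctnmqr metrics recovered.h5 reference.h5
```

Rank must be supplied for real data; `--preset image` applies the
conventional channel weights `α ∝ (1, 1, 10⁻³)` for H×W×3 images.

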
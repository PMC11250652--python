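# Methods

## Model and assumptions

The solver treats completion as simultaneous estimation of a Tucker model
and a completion. The target tensor is assumed to have (approximately) low
Tucker rank `(R_1, …, R_N)`: each mode-i unfolding is (near) rank `R_i`.
The objective couples a weighted nuclear norm of the *core* unfoldings with
a quadratic fit between the completion `X` and the Tucker reconstruction,
under the hard constraint that `X` reproduces the observed entries and that
every factor has orthonormal columns. Orthonormality is what licenses the
core-for-full-tensor substitution: if `U_i` have orthonormal columns, the
mode-i unfolding of `C ×_1 U_1 ⋯ ×_N U_N` is `U_i C_(i) K_iᵀ` with both
`U_i` and the Kronecker factor `K_i` column-orthonormal, so its singular
values — hence its nuclear norm — equal those of `C_(i)`. The returned
model is tested for exactly this identity.

The ADMM splitting introduces one core-shaped auxiliary tensor per mode.
Using tensor-valued (rather than matrix-valued) auxiliaries keeps every
subproblem closed-form: the SVT acts on an unfolding of a core-shaped
tensor and is folded straight back.

The rank vector is an input. Nothing in the package estimates it; for real
data the CLI expects the user to supply (or sweep) it.

## Parameters

| name | default | meaning |
|---|---|---|
| `rank` | — | target Tucker rank, one entry per mode, `R_i ≤ I_i` |
| `alpha` | uniform `1/N` | per-mode nuclear-norm weights, `Σα_i = 1` |
| `lam` | `100` | weight of the reconstruction-fit term (dimensionless) |
| `mu0` | `1e-3` | initial ADMM penalty |
| `mu_max` | `1e10` | penalty cap |
| `rho` | `1.05` | geometric penalty growth, restricted to (1.0, 1.1] |
| `tol` | `1e-5` | relative-change stopping tolerance on `X` |
| `max_iter` | `500` | iteration cap |
| `factor_strategy` | `qr` | `qr` (thin-QR) or `hooi` (SVD baseline) |
| `seed` | `0` | seed for the random factor initialization |

### Why `lam = 100`

In the core update the data enters with weight `λ/(Nμ + λ)`, which decays
to zero as the penalty μ grows. Once `μ ≳ λ/N` the core is driven almost
entirely by the SVT consensus and stops absorbing information from the
data; whatever reconstruction error exists at that point is frozen in.
With a unit weight this crossover happens within the first ~100 sweeps
(μ grows as `1e-3·1.05^k`) and, on small problems where the shrinkage bias
is relatively large, the solver stalls at stationary points an order of
magnitude or two above the exact-recovery floor — traces show the error
plateauing exactly when μ passes λ. Setting `λ = 100` keeps the data term
dominant over `Nμ` for the entire iteration range the stopping rule
actually uses (the tolerance stop typically fires between 15 and 60
sweeps) while leaving the nuclear-norm term active. Accuracy on standard
synthetic grids is equal or better at every size we run, and the parameter
remains exposed for sensitivity sweeps.

## Initialization

The formulation does not dictate a starting point. The package uses:
`X⁰` = observed entries, zeros elsewhere; `U_i⁰` = thin-QR
orthonormalization of a seeded standard-normal `I_i×R_i` draw; `C⁰` =
projection of `X⁰` onto the factor subspaces; `V_i⁰ = C⁰`; `Y_i⁰ = 0`;
`μ = μ₀`. Every random draw flows from `SolverConfig.seed`, so identical
seed + config + input gives bitwise-identical results.

## Numerical choices

- **Unfolding convention.** Mode-n unfolding maps entry `(i_1,…,i_N)` to
  row `i_n`, column `1 + Σ_{k≠n}(i_k−1)J_k`, `J_k = Π_{m<k,m≠n} I_m`
  (the Kolda–Bader order); implemented as move-axis + Fortran reshape and
  pinned by an elementwise test. Modes are 1-based at the API surface.
- **SVT** uses a plain economy SVD: inputs are `R × R^{N−1}` core
  unfoldings, far too small for randomized or truncated methods to pay off.
- **Thin QR sign convention.** The Q factor is normalized so the R factor
  has nonnegative diagonal, making the output unique and deterministic
  across platforms. Rank-deficient input (possible in early, degenerate
  iterates) does not abort: the missing directions are filled from a
  deterministic orthonormal completion built from canonical axes, with a
  warning.
- **Factor solve.** With the other factors orthonormal,
  `Z_(i)Z_(i)ᵀ = C_(i)C_(i)ᵀ` and `X_(i)Z_(i)ᵀ = W_(i)C_(i)ᵀ` where `W` is
  `X` projected onto every factor but i — an `R_i×R_i` system per mode
  rather than any product over the full tensor, matching the advertised
  `O(Σ_i I_i R_i²)` orthogonalization cost. If orthonormality drift
  exceeds `1e-8` the solver falls back to forming `Z` explicitly; a
  singular normal matrix falls back to the pseudoinverse with a warning.
- **Monotonicity, precisely.** The quantity that provably never increases
  in the factor sweep is the objective at the *unconstrained* least-squares
  solution `Ũ_i`: it is the global minimizer, so `f(Ũ_i) ≤ f(U_i^k)`.
  The thin-QR step `Ũ = QR` preserves that value only jointly with the
  upper-triangular core transformation (`f` at `Q` with core `C ×_i R`
  equals `f(Ũ)` with core `C`); with the core held fixed the post-QR
  objective can tick upward, especially in the first few sweeps. Debug
  mode (`SolverConfig(debug=True)`) asserts the guaranteed inequality at
  every mode of every sweep, plus bitwise feasibility on Ω; the test suite
  additionally verifies the QR/core-transform equivalence exactly.
- **Stopping** uses the relative change of `X` only. A zero-norm previous
  iterate returns an `inf` sentinel rather than raising (a fully observed
  problem stops in one sweep with relative change 0). Non-finite values
  mid-run raise a `NumericalFailure` naming the iteration.

## What the synthetic generator emulates — and what it does not

`generate_tucker_tensor` reproduces the standard synthetic protocol:
standard-normal core and factors, multiplied out, giving *exactly*
low-rank, noise-free tensors whose entry variance is `Π_i R_i`.
`sample_mask` removes entries uniformly at random with an exact observed
count `M = round((1−mr)·Π I_n)` (hypergeometric rather than Bernoulli
sampling, so the printed missing rate is achieved to within one entry).

Real images and MRI volumes differ in every convenient way: they are only
approximately low-rank, their missingness is often structured (scratches,
text, slabs), intensities are bounded, and the correct rank is unknown.
Passing the synthetic suite therefore demonstrates correctness of the
optimization and exact-recovery behavior, not inpainting quality on
natural data; the image/volume pathway is exercised end-to-end on
synthetic image-shaped tensors instead.

## Problem sizes used in the test and benchmark suite

Benchmarks average 10 seeded replicates per cell (40⁴ and 20⁵ grids at
several missing rates; 100³ for convergence monitoring). Ten replicates
put the standard error of a mean RSE comfortably inside the
order-of-magnitude bands the suite asserts; the `replicates` knob raises
this for tighter studies.

## Rank selection on real data

For images and volumes the correct Tucker rank is unknown and must be
supplied. The CLI's `--rank-sweep` automates a user-specified grid: 10 %
of the *observed* entries are held out, each candidate rank completes the
reduced problem, and the rank with the lowest RSE on the held-out entries
wins before a final solve on all observations. This is model selection by
prediction, not an automatic rank estimator — the grid is the user's.

## Known limitations

- The SVT thresholds `α_i/μ` are not scale-invariant: data on a very
  different scale than the unit-variance synthetic protocol shifts the
  effective regularization along the μ schedule. Normalizing images to
  [0,1] (the default) keeps the regime consistent.
- No automatic rank selection; misspecified rank degrades gracefully but
  silently.
- Dense arithmetic only — memory is `O(Π I_n)`; sparse observation
  patterns are not exploited for storage.
- The ADMM is nonconvex; convergence is monitored empirically (penalty
  schedule, relative-change trace, debug-mode invariants), not certified.
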
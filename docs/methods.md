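# Methods

## Acquisition model

A DW volume on an `(N_x, N_y, N_z)` grid is one column of the attenuation
matrix `E ∈ R^{N_Vox × N_Q}` (C-order voxel raveling; the slice-encoding
axis is z). SMS excitation partitions the `N_z` slices into
`N_SG = N_z / R_SMS` groups; group g holds the evenly spaced slices
`{g + j·N_SG}`, one per band of the volume, mirroring how SMS spreads its
simultaneously excited slices. A SIDE volume assigns wavevector
`assignment(c, m, g) = m·N_SG + (g + c) mod N_SG` to slice group g of the
m-th volume of cycle c. Within a cycle every wavevector appears exactly
once; the +1 modular shift per cycle makes each (wavevector, slice group)
pair appear exactly once over the `N_SG` cycles. Any bijective shift would
satisfy coverage; +1 is fixed for reproducibility. Undersampling keeps
every `R_SIDE`-th cycle starting at cycle 0 (deterministic, and evenly
spreads the acquired cycles). Acquisition is then entrywise masking of E at
(slice, wavevector) granularity, with optional additive Gaussian (or
Rician) noise on the attenuations; the adjoint scatters observed entries
back and zero-fills the rest.

The conventional-undersampling comparator keeps `N_Q / R` wavevectors fully
sampled, allocated across shells by largest-remainder proportional rounding
(ties toward larger shells) and, within a shell, spread by greedy
farthest-point selection on the sphere. For the four-shell
16/32/48/64-direction protocol this yields totals 80/32/16 at 2×/5×/10×.

## Signal model

Per voxel, the DW attenuation is the spherical convolution of an axially
symmetric single-fiber response `R(q; v) = exp(−b((D_L − D_T)(q̂·v)² + D_T))`
with a fiber orientation distribution (fODF) expressed in the real,
antipodally symmetric, orthonormal spherical-harmonic basis of even orders
up to 8 (45 functions). The restriction-spectrum extension concatenates
K response blocks with distinct diffusivity pairs plus single isotropic
columns:

```
A = [R₁WY … R_KWY | exp(−b·D_iso) …],   e = A v
```

`W = diag(w_j)` holds the tessellation quadrature weights (spherical vertex
areas of a 3-times-subdivided icosahedron, 321 hemisphere directions, each
weight covering its antipode), so that `A v` discretizes the convolution
integral and a delta fODF's SH projection reproduces the closed-form
response to under 1% at order 8; without the weights the icosphere's uneven
vertex density distorts the synthesis by >10%. W is an invertible rescaling
of the basis, so column space, fitting and the reduction to plain spherical
deconvolution (K = 1, no isotropic atoms) are unaffected.

Default spectrum grid: `D_L ∈ {1.5, 2.0, 2.5}×10⁻³ mm²/s`, for each a
4-point log-spaced `D_T` ladder from `D_L/1.1` down to `0.1×10⁻³`
(enforcing the anisotropy floor `D_L/D_T ≥ 1.1`), and
`D_iso ∈ {0.5, 1.5, 3.0}×10⁻³`, spanning the physiological range from
restricted axonal to free water. Columns of A are normalized to unit
Euclidean norm before solving (atoms at different b-decay scales otherwise
condition poorly) and coefficients are rescaled on output. Coefficient
fitting is per-voxel Tikhonov-damped least squares with the normal-equation
Cholesky factored once and reused across voxels; at damping 0 a singular
Gram matrix (unavoidable when `P_total > N_Q`) raises with a hint to damp.

b = 0 volumes are used only to normalize raw intensities to attenuations
`S/S₀` (S₀ the mean of the b0 volumes; voxels with S₀ ≤ 0 are masked) and
are excluded from E, since the model describes attenuation.

## Total variation

The per-volume semi-norm is the weighted isotropic 3-D TV with forward
differences and Neumann boundary (differences past the last index vanish,
so constants have zero TV). Defaults `(γ_x, γ_y, γ_z) = (0.9, 0.9, 1)`
regularize slightly more along the slice axis, where SIDE undersampling
removes data. The prox is solved on the dual by accelerated projected
gradient (FISTA) with step `1/(strength · L)`, `L = 4(γ_x² + γ_y² + γ_z²)`
the weighted operator-norm bound; per-voxel Euclidean projection of the
dual field onto the unit ball gives the isotropic coupling. Defaults: 50
inner iterations, stop at 1e-5 relative dual change; non-convergence
returns the current iterate with a logged warning. All volumes of one ADMM
iteration are solved jointly as a batch (identical iteration count per
volume, bitwise equal to per-volume solves).

## ADMM

With auxiliary volumes `U_q ~ E^(q)` and scaled multipliers `Ψ_q`, `Φ`,
each iteration performs, in order:

1. `V ← argmin ‖Eᵀ + Φ − AV‖²` (damped least squares, factorization cached);
2. `U_q ← prox_{(λ/ρ₁)TV}(E^(q) − Ψ_q)` for all q;
3. `E ← (M ⊙ Y_obs + ρ₁(U + Ψ) + ρ₂(AV − Φ)ᵀ) / (M + ρ₁ + ρ₂)` —
   the three quadratics are separable per entry (M the acquisition mask,
   Y_obs the observations); entries with zero denominator (only possible in
   the ρ → 0 limit) are set to 0;
4. `Ψ_q += U_q − E^(q)`, `Φ += Eᵀ − AV`.

Initialization: `E⁰` = zero-filled adjoint of the observations,
`U⁰ = E⁰`, `Ψ = Φ = 0`. Stopping is the conjunction of squared multiplier
changes `‖ΔΨ‖² ≤ ε₁` and `‖ΔΦ‖² ≤ ε₂` (these coincide with the primal
residuals of the two splits, which are also what the history logs), or
`max_iter`. Defaults: `λ = 0.01`, `ρ₁ = ρ₂ = 0.5`, `ε₁ = ε₂ = 10⁻⁶` per
matrix entry, `max_iter = 100`, dictionary damping `10⁻⁸`. Stopping on
multiplier change rather than combined primal/dual residuals is unusual for
ADMM but matches the method's stated procedure; the logged history allows
external monitoring. A divergence guard aborts if the primal objective
exceeds 10× its running minimum.

In the noiseless, fully sampled, unregularized limit the problem is a
feasibility projection; since the default dictionary has full row rank for
the default phantom's 40 wavevectors, the source is recovered to machine
precision (NMSE ~ 10⁻¹¹, tested to ≤ 10⁻⁶).

## Synthetic phantom

The generator emulates the piecewise-smooth, mixture-of-compartments
structure the priors assume: per voxel
`E(q) = Σ_m f_m R(q; v_m) + f_iso exp(−b·D_iso)` with delta fODFs, so the
truth is analytic (dispersion can be emulated by mixtures of nearby
directions). The default phantom is a 16×16×12 grid with a straight bundle
along x (f = 0.8, `D_L = 2.0×10⁻³`, `D_T = 0.5×10⁻³`, 20% isotropic), a 60°
crossing region (0.4/0.4/0.2) and an isotropic background
(`D_iso = 1.5×10⁻³`); shells (500, 8), (1000, 12), (2000, 20) —
N_Q = 40, a desk-scale version of a multi-shell protocol whose slice count
(12, SMS 3 → 4 slice groups) divides the wavevector count as the cycle
structure requires. Noise is Gaussian on attenuations with σ = 1/30 of the
peak ("SNR 30"); Rician is available. Gradient directions per shell come
from seeded antipodal electrostatic-repulsion descent.

What passing tests on this phantom do **not** show: robustness to real
acquisition physics (g-factor noise amplification, eddy currents, motion,
susceptibility distortion), to anatomical complexity beyond three
homogeneous regions, or to model mismatch beyond the dictionary's
diffusivity grid.

## Metrics

NMSE and PSNR are implemented as this line of work reports them —
`NMSE = ‖E − Ẽ‖_F / N_Vox` (norm, not squared) and
`PSNR = 10 log₁₀(MAX/NMSE)` with MAX the truth maximum — with the textbook
variants (`nmse_conventional`, `psnr_conventional`) alongside, since the
printed definitions are non-standard. PSNR of identical inputs is capped at
300 dB. SSIM uses the standard constants (K₁ = 0.01, K₂ = 0.03, Gaussian
window σ = 1.5, 11³ support), computed in 3-D per volume with the border
region (one window radius) cropped from the mean, and is averaged over
wavevectors; it matches scikit-image's implementation to 10⁻⁶ on random
volumes. GFA is std/rms (population std) of the fODF amplitudes evaluated
on the tessellation from the aggregate anisotropic compartments; which ODF
to use is a free choice and this one requires no extra normalization. FBO,
`1 − Σ|p − p_GT| / Σ p_GT`, is a generic probability-map overlap and may be
negative for gross mismatches (reported as-is).

## Problem sizes and runtimes

The test suite and the acceptance script run the full phantom study at the
default sizes (3072 voxels × 40 wavevectors, 543-column dictionary, ADMM
capped at 60 iterations with tolerances 10⁻⁹ per entry): about one minute
for the five reconstructions of the trend study (factors 1/2/4, SIDE and
conventional), chosen so the whole study stays interactive on one CPU.
Representative numbers at seed 1: SIDE NMSE 0.0022 / 0.0036 / 0.0103 at
r = 1/2/4 against zero-fill 0.024 / 0.029 and conventional 0.023 / 0.029
at r = 2/4 — monotone degradation with undersampling and a consistent SIDE
advantage at matched volume budget, the two directional effects the method
predicts.

## Known limitations

- The solver holds E, U, Ψ (each N_Vox × N_Q) and Φ densely in memory;
  whole-brain problems need slab-wise processing, which the slice-separable
  forward model permits but the driver does not implement.
- No non-negativity constraint on fODF coefficients; spurious negative
  lobes are possible at high undersampling.
- The conventional comparator's per-shell allocation is one defensible
  rounding rule among several; only the totals are contractual.
- Rician noise is available in the generator but the data term remains
  least-squares (no bias correction).
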
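# sidedmri

Reconstruction toolkit for diffusion MRI acquired with **slice-interleaved
diffusion encoding (SIDE)** — scheme planning, the linear forward model, and
recovery of full diffusion-weighted (DW) volumes by ADMM under a
diffusion-spectrum dictionary constraint with anisotropic total-variation
regularization. A synthetic multi-shell phantom generator and the standard
reconstruction metrics are included, so the whole method runs end to end
with no external data.

## The problem

Conventional diffusion MRI spends one repetition time per DW volume: one
diffusion wavevector **q**, all slices. With simultaneous multi-slice (SMS)
excitation, the `n_slices` slices are covered by `N_SG = n_slices / R_SMS`
slice groups. SIDE assigns a *different* wavevector to every slice group
within a volume, so each acquired volume carries partial spatial information
for `N_SG` wavevectors at once. `N_Q / N_SG` such volumes form a *cycle*
covering every wavevector once; the group-to-wavevector assignment shifts by
one group per cycle, so `N_SG` cycles cover every (wavevector, slice group)
pair exactly once. Skipping cycles undersamples the acquisition by `R_SIDE`,
for a total acceleration of `R_SMS × R_SIDE` — up to 25× with
`R_SMS = R_SIDE = 5` — at the cost of missing slices in every DW volume.

Recovering the full `N_Vox × N_Q` attenuation matrix **E** from the acquired
slices is ill-posed. The solver uses two priors:

- **q-space**: each voxel's signal lies in the span of a restriction-spectrum
  dictionary `A = [R₁WY … R_KWY | iso]`, where `R_k` is the axially
  symmetric single-fiber response
  `R(q; v) = exp(−b((D_L − D_T)(q̂·v)² + D_T))` evaluated over a hemisphere
  tessellation (W its quadrature weights), `Y` the even-order real spherical
  harmonic basis (order 8 by default), and isotropic columns `exp(−b·D_iso)`.
  The constraint `Eᵀ = AV` couples all shells.
- **space**: per-volume weighted isotropic 3-D total variation
  `TV(u) = Σ √(γ_x²Δ_x² + γ_y²Δ_y² + γ_z²Δ_z²)`, defaults
  `(γ_x, γ_y, γ_z) = (0.9, 0.9, 1)`.

The reconstruction solves

```
min_E  ½ Σ_{q,l} ‖H_l E w_ql − E^S_q(:,l)‖²_F + λ ‖E‖_TV   s.t.  Eᵀ = AV
```

by ADMM (defaults `ρ₁ = ρ₂ = 0.5`, `λ = 0.01`), alternating a damped least-
squares fit of the spectrum coefficients V, a per-volume TV proximal step
(dual FISTA), an elementwise closed-form update of E, and dual ascent on the
two multipliers.

## Worked example

```python
import sidedmri as sd

spec = sd.default_phantom()                      # 16x16x12, 3 shells, N_Q=40
gradients = sd.make_gradients(spec.shells, seed=1)
truth, _ = sd.synthesize(spec, gradients)

grouping = sd.make_grouping(12, 3)               # 12 slices, SMS 3 -> 4 groups
scheme = sd.plan_side(grouping, truth.n_q, r_side=2)
print(sd.total_acceleration(scheme))             # 6

obs = sd.acquire(truth, scheme, noise_sigma=1/30, seed=7)
print(obs.acquired_fraction())                   # 0.5

model = sd.SideReconstructor(sd.build_dictionary(gradients),
                             max_iter=60).fit(obs)
print(round(sd.nmse(model.signal_, truth), 6))   # 0.003581
print(round(sd.nmse(sd.adjoint(obs), truth), 6)) # 0.023540
```

Half of the slice data is discarded and the ADMM reconstruction recovers the
40 DW volumes with an error (NMSE, Frobenius norm of the difference over the
voxel count) roughly 6.6× lower than zero-filling the missing slices.

The same pipeline is scriptable from the shell:

```bash
sidedmri --seed 7 run --out side_run --r-side 2
sidedmri plan --n-slices 100 --sms 5 --nq 160 --r-side 5 --out scheme.json
# n_sg=20 volumes/cycle=8 acquired_volumes=32 total_acceleration=25
```

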
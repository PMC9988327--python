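"""Synthetic multi-shell diffusion phantoms with analytically known truth.

Each voxel mixes axially symmetric fiber compartments (delta fODFs, so the
spherical convolution is evaluated in closed form) with an isotropic
compartment:

    E(q) = sum_m f_m exp(-b ((D_L - D_T)(q_hat . v_m)^2 + D_T))
           + f_iso exp(-b D_iso),     sum of fractions = 1.

The default phantom is a 16 x 16 x 12 grid with a straight bundle, a 60-deg
crossing region and an isotropic background, sampled on three b-shells —
piecewise-smooth spatial structure matching what the TV prior and spectrum
dictionary assume. Gradient directions per shell come from a seeded
electrostatic-repulsion optimization, so all inputs are generated
deterministically from the spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gradients import GradientTable, SignalMatrix


@dataclass(frozen=True)
class FiberPopulation:
    """One coherent fiber compartment: axis, volume fraction, diffusivities."""

    direction: tuple[float, float, float]
    fraction: float
    d_long: float
    d_trans: float


@dataclass(frozen=True)
class Region:
    """A spatial mask with its fiber populations and isotropic compartment."""

    mask: np.ndarray  # boolean over the phantom grid
    fibers: tuple[FiberPopulation, ...]
    iso_fraction: float
    d_iso: float

    def __post_init__(self) -> None:
        total = self.iso_fraction + sum(f.fraction for f in self.fibers)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"volume fractions sum to {total}, expected 1")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic phantom acquisition."""

    dims: tuple[int, int, int]
    regions: tuple[Region, ...]
    shells: tuple[tuple[float, int], ...]
    noise_sigma: float = 1.0 / 30.0
    noise_model: str = "gaussian"
    seed: int = 42

    def __post_init__(self) -> None:
        covered = np.zeros(self.dims, dtype=bool)
        for r in self.regions:
            if r.mask.shape != tuple(self.dims):
                raise ValueError("region mask shape does not match dims")
            if (covered & r.mask).any():
                raise ValueError("overlapping region masks")
            covered |= r.mask
        if not covered.all():
            raise ValueError("region masks do not cover the grid")
        for b, n in self.shells:
            if n < 6:
                raise ValueError("each shell needs >= 6 directions")
            if b <= 0:
                raise ValueError("shell b-values must be > 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    @property
    def n_q(self) -> int:
        return sum(n for _, n in self.shells)

    def fiber_directions(self) -> np.ndarray:
        dirs = [f.direction for r in self.regions for f in r.fibers]
        out = np.asarray(dirs, dtype=float)
        return out / np.linalg.norm(out, axis=1, keepdims=True)

    def diffusivities(self) -> tuple[set, set]:
        """Distinct (d_long, d_trans) pairs and iso diffusivities used."""
        aniso = {(f.d_long, f.d_trans) for r in self.regions for f in r.fibers}
        iso = {r.d_iso for r in self.regions if r.iso_fraction > 0}
        return aniso, iso


def _repulsion_directions(n: int, rng: np.random.Generator,
                          iters: int = 300) -> np.ndarray:
    """n unit vectors spread by antipodal electrostatic-repulsion descent."""
    x = rng.standard_normal((n, 3))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    if n == 1:
        return x
    step = 0.1
    energy = _pair_energy(x)
    for _ in range(iters):
        grad = np.zeros_like(x)
        for sign in (1.0, -1.0):
            diff = x[:, None, :] - sign * x[None, :, :]
            dist = np.linalg.norm(diff, axis=2)
            np.fill_diagonal(dist, np.inf)
            grad -= (diff / dist[..., None] ** 3).sum(axis=1)
        cand = x - step * grad
        cand /= np.linalg.norm(cand, axis=1, keepdims=True)
        e_new = _pair_energy(cand)
        if e_new < energy:
            x, energy = cand, e_new
            step *= 1.2
        else:
            step *= 0.5
            if step < 1e-12:
                break
    return x


def _pair_energy(x: np.ndarray) -> float:
    e = 0.0
    for sign in (1.0, -1.0):
        dist = np.linalg.norm(x[:, None, :] - sign * x[None, :, :], axis=2)
        np.fill_diagonal(dist, np.inf)
        e += float((1.0 / dist).sum())
    return e / 2.0


def make_gradients(shells, seed: int = 42) -> GradientTable:
    """Per-shell electrostatic-repulsion direction sets, concatenated.

    Deterministic for a given seed; shells are laid out in the given order.
    """
    rng = np.random.default_rng(seed)
    dirs, bvals = [], []
    for b, n in shells:
        dirs.append(_repulsion_directions(int(n), rng))
        bvals.extend([float(b)] * int(n))
    return GradientTable(np.concatenate(dirs, axis=0), np.asarray(bvals))


def paper_protocol_shells() -> tuple[tuple[float, int], ...]:
    """The 160-direction, 4-shell protocol: b = 500/1000/2000/3000 s/mm^2
    with 16/32/48/64 directions."""
    return ((500.0, 16), (1000.0, 32), (2000.0, 48), (3000.0, 64))


def synthesize(spec: PhantomSpec, gradients: GradientTable) -> tuple[SignalMatrix, SignalMatrix]:
    """Generate (noiseless truth, noisy copy) for a phantom spec.

    Gaussian noise of sd ``spec.noise_sigma`` is added to attenuations
    (Rician optionally, as the magnitude of a complex Gaussian
    perturbation), seeded by ``spec.seed``.
    """
    dw = ~gradients.b0_mask
    q = gradients.directions[dw]
    b = gradients.bvals[dw]
    n_q = int(dw.sum())
    n_vox = int(np.prod(spec.dims))
    values = np.zeros((n_vox, n_q))
    for region in spec.regions:
        sig = np.zeros(n_q)
        for f in region.fibers:
            v = np.asarray(f.direction, dtype=float)
            v = v / np.linalg.norm(v)
            ct2 = (q @ v) ** 2
            sig += f.fraction * np.exp(-b * ((f.d_long - f.d_trans) * ct2 + f.d_trans))
        if region.iso_fraction > 0:
            sig += region.iso_fraction * np.exp(-b * region.d_iso)
        values[region.mask.ravel()] = sig
    truth = SignalMatrix(values, spec.dims)
    rng = np.random.default_rng(spec.seed)
    if spec.noise_model == "rician":
        noisy_vals = np.abs(
            values
            + rng.normal(0, spec.noise_sigma, values.shape)
            + 1j * rng.normal(0, spec.noise_sigma, values.shape)
        )
    else:
        noisy_vals = values + rng.normal(0, spec.noise_sigma, values.shape)
    noisy = SignalMatrix(noisy_vals, spec.dims)
    return truth, noisy


def default_phantom() -> PhantomSpec:
    """16 x 16 x 12 phantom: straight bundle, 60-deg crossing, isotropic
    background; shells (500, 8), (1000, 12), (2000, 20); SNR 30."""
    dims = (16, 16, 12)
    bundle = np.zeros(dims, dtype=bool)
    bundle[:, 2:6, 2:10] = True
    crossing = np.zeros(dims, dtype=bool)
    crossing[:, 9:13, 2:10] = True
    background = ~(bundle | crossing)
    ex = (1.0, 0.0, 0.0)
    e60 = (0.5, float(np.sqrt(3) / 2), 0.0)
    regions = (
        Region(bundle, (FiberPopulation(ex, 0.8, 2.0e-3, 0.5e-3),), 0.2, 1.5e-3),
        Region(
            crossing,
            (
                FiberPopulation(ex, 0.4, 2.0e-3, 0.5e-3),
                FiberPopulation(e60, 0.4, 2.0e-3, 0.5e-3),
            ),
            0.2,
            1.5e-3,
        ),
        Region(background, (), 1.0, 1.5e-3),
    )
    return PhantomSpec(
        dims=dims,
        regions=regions,
        shells=((500.0, 8), (1000.0, 12), (2000.0, 20)),
        noise_sigma=1.0 / 30.0,
        seed=42,
    )
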
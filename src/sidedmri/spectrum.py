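"""Diffusion-spectrum dictionary: response functions x spherical harmonics.

The DW attenuation of a coherent fiber bundle along axis v is modeled by an
axially symmetric mono-exponential response

    R(q; v) = exp(-b ((D_L - D_T)(q_hat . v)^2 + D_T)),

and the voxel signal is the spherical convolution of R with the fiber
orientation distribution (fODF), parameterized in an even-order real
spherical-harmonic (SH) basis. Discretized over a hemisphere tessellation
{v_j} with quadrature weights W this is e = R W Y beta. The restriction-
spectrum extension mixes K such models with different (D_L, D_T) pairs,
plus isotropic compartments exp(-b D_iso), giving the dictionary

    A = [R_1 W Y ... R_K W Y | iso columns],   e = A v.

Coefficients are fitted per voxel by Tikhonov-damped least squares on the
column-normalized dictionary.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.linalg import cho_factor, cho_solve
from scipy.special import sph_harm_y
from sklearn.base import BaseEstimator

from .gradients import GradientTable, SignalMatrix

DEFAULT_SH_ORDER = 8


def response(direction: np.ndarray, b: float, fiber: np.ndarray,
             d_long: float, d_trans: float) -> float:
    """Single-fiber attenuation exp(-b((D_L-D_T)(q_hat.v)^2 + D_T)).

    Non-unit vectors are normalized with a warning; b=0 returns 1.
    """
    q = np.asarray(direction, dtype=float)
    v = np.asarray(fiber, dtype=float)
    if b < 0 or not np.all(np.isfinite(q)) or not np.all(np.isfinite(v)):
        raise ValueError("b must be >= 0 and vectors finite")
    for name, vec in (("direction", q), ("fiber", v)):
        n = np.linalg.norm(vec)
        if abs(n - 1.0) > 1e-6:
            warnings.warn(f"{name} not unit norm; normalizing", stacklevel=2)
    q = q / np.linalg.norm(q)
    v = v / np.linalg.norm(v)
    ct = float(q @ v)
    return float(np.exp(-b * ((d_long - d_trans) * ct**2 + d_trans)))


def _response_matrix(gradients: GradientTable, tessellation: np.ndarray,
                     d_long: float, d_trans: float) -> np.ndarray:
    """(N_Q, N_F) response values; b=0 rows evaluate to 1."""
    ct2 = (gradients.directions @ tessellation.T) ** 2
    b = gradients.bvals[:, None]
    return np.exp(-b * ((d_long - d_trans) * ct2 + d_trans))


def sh_basis(tessellation: np.ndarray, sh_order: int = DEFAULT_SH_ORDER) -> np.ndarray:
    """Real, symmetric (even-order), orthonormal SH basis, (N_F, P).

    Ordering: l ascending over even orders, m from -l to l. P =
    (sh_order+1)(sh_order+2)/2. Convention: m=0 real harmonic; m>0 is
    sqrt(2) (-1)^m Re Y_l^m; m<0 is sqrt(2) (-1)^m Im Y_l^|m|.
    """
    if sh_order < 0 or sh_order % 2:
        raise ValueError(f"sh_order must be even and >= 0, got {sh_order}")
    v = np.asarray(tessellation, dtype=float)
    v = v / np.linalg.norm(v, axis=1, keepdims=True)
    theta = np.arccos(np.clip(v[:, 2], -1, 1))  # polar
    phi = np.arctan2(v[:, 1], v[:, 0])  # azimuth
    cols = []
    for ell in range(0, sh_order + 1, 2):
        for m in range(-ell, ell + 1):
            y = sph_harm_y(ell, abs(m), theta, phi)
            if m < 0:
                cols.append(np.sqrt(2) * (-1) ** m * y.imag)
            elif m == 0:
                cols.append(y.real)
            else:
                cols.append(np.sqrt(2) * (-1) ** m * y.real)
    return np.stack(cols, axis=1)


def sh_basis_size(sh_order: int) -> int:
    return (sh_order + 1) * (sh_order + 2) // 2


def hemisphere_tessellation(subdivisions: int = 3, return_weights: bool = False):
    """Hemisphere vertex set of a subdivided icosahedron (default 321 dirs).

    Of each antipodal vertex pair, the representative with z > 0 (ties
    broken by y, then x) is kept; adequate sampling for order-8 SH. With
    ``return_weights`` the per-vertex quadrature weights (twice the
    spherical Voronoi-style vertex area, covering both antipodes; they sum
    to ~4 pi) are returned as well.
    """
    mesh = trimesh.creation.icosphere(subdivisions=subdivisions)
    verts = np.asarray(mesh.vertices)
    verts = verts / np.linalg.norm(verts, axis=1, keepdims=True)
    eps = 1e-9
    keep = (verts[:, 2] > eps) | (
        (np.abs(verts[:, 2]) <= eps)
        & ((verts[:, 1] > eps) | ((np.abs(verts[:, 1]) <= eps) & (verts[:, 0] > eps)))
    )
    if not return_weights:
        return verts[keep]
    areas = np.zeros(len(verts))
    for face, fa in zip(mesh.faces, mesh.area_faces):
        areas[face] += fa / 3.0
    return verts[keep], 2.0 * areas[keep]


@dataclass(frozen=True)
class SpectrumGrid:
    """Diffusivity atoms of the spectrum dictionary (all in mm^2/s).

    ``aniso_atoms`` are (D_L, D_T) pairs with D_L >= D_T and D_L/D_T >= 1.1;
    ``iso_atoms`` are isotropic diffusivities.
    """

    aniso_atoms: tuple = ()
    iso_atoms: tuple = ()

    def __post_init__(self) -> None:
        if not self.aniso_atoms and not self.iso_atoms:
            raise ValueError("empty spectrum grid")
        for d_l, d_t in self.aniso_atoms:
            if not (d_l >= d_t >= 0):
                raise ValueError(f"need D_L >= D_T >= 0, got ({d_l}, {d_t})")
            if d_t > 0 and d_l / d_t < 1.1:
                raise ValueError(f"need D_L/D_T >= 1.1, got {d_l / d_t:.3f}")
        for d in self.iso_atoms:
            if d < 0:
                raise ValueError("isotropic diffusivity must be >= 0")

    @property
    def n_aniso(self) -> int:
        return len(self.aniso_atoms)

    @property
    def n_iso(self) -> int:
        return len(self.iso_atoms)


def default_grid(n_trans: int = 4) -> SpectrumGrid:
    """Default spectrum: D_L in {1.5, 2.0, 2.5}e-3 with a log-spaced D_T
    ladder from D_L/1.1 down to 0.1e-3, and D_iso in {0.5, 1.5, 3.0}e-3."""
    aniso = []
    for d_l in (1.5e-3, 2.0e-3, 2.5e-3):
        for d_t in np.geomspace(d_l / 1.1, 0.1e-3, n_trans):
            aniso.append((float(d_l), float(d_t)))
    return SpectrumGrid(tuple(aniso), (0.5e-3, 1.5e-3, 3.0e-3))


@dataclass
class SpectrumDictionary:
    """Assembled dictionary A = [R_1 Y ... R_K Y | iso], with metadata.

    ``matrix_A`` is the raw (unnormalized) N_Q x P_total matrix;
    ``col_scales`` are the Euclidean column norms used by the solvers
    (columns are normalized before solving, coefficients rescaled after).
    """

    matrix_A: np.ndarray
    gradients: GradientTable
    grid: SpectrumGrid
    sh_order: int
    tessellation: np.ndarray
    tess_weights: np.ndarray | None = None
    col_scales: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.col_scales = np.linalg.norm(self.matrix_A, axis=0)
        if np.any(self.col_scales == 0):
            raise ValueError("dictionary has an all-zero column")

    @property
    def n_q(self) -> int:
        return self.matrix_A.shape[0]

    @property
    def p_total(self) -> int:
        return self.matrix_A.shape[1]

    @property
    def p_per_atom(self) -> int:
        return sh_basis_size(self.sh_order)

    @property
    def normalized(self) -> np.ndarray:
        return self.matrix_A / self.col_scales

    def synthesize(self, coeffs: np.ndarray) -> np.ndarray:
        """Signals A @ v for a (P_total,) or (P_total, N_Vox) coefficient set."""
        return self.matrix_A @ coeffs

    def aniso_block(self, k: int) -> slice:
        p = self.p_per_atom
        return slice(k * p, (k + 1) * p)

    def fodf_amplitudes(self, coeffs: np.ndarray) -> np.ndarray:
        """Aggregate anisotropic fODF amplitudes on the tessellation.

        Sums Y beta_k over the K anisotropic compartments; returns
        (N_F,) or (N_F, N_Vox) matching ``coeffs``.
        """
        basis = sh_basis(self.tessellation, self.sh_order)
        total = np.zeros(basis.shape[:1] + coeffs.shape[1:])
        for k in range(self.grid.n_aniso):
            total += basis @ coeffs[self.aniso_block(k)]
        return total

    def save(self, array_path, sidecar_path) -> None:
        """Export as a binary array container plus JSON sidecar."""
        np.savez(
            array_path,
            matrix_A=self.matrix_A,
            tessellation=self.tessellation,
            tess_weights=(np.zeros(0) if self.tess_weights is None
                          else self.tess_weights),
            directions=self.gradients.directions,
            bvals=self.gradients.bvals,
        )
        meta = {
            "sh_order": self.sh_order,
            "aniso_atoms": [list(a) for a in self.grid.aniso_atoms],
            "iso_atoms": list(self.grid.iso_atoms),
            "tessellation_hash": hash_array(self.tessellation),
        }
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, array_path, sidecar_path) -> "SpectrumDictionary":
        arrays = np.load(array_path)
        with open(sidecar_path) as fh:
            meta = json.load(fh)
        tess = arrays["tessellation"]
        if hash_array(tess) != meta["tessellation_hash"]:
            raise ValueError("tessellation hash mismatch in sidecar")
        grid = SpectrumGrid(
            tuple(tuple(a) for a in meta["aniso_atoms"]), tuple(meta["iso_atoms"])
        )
        table = GradientTable(arrays["directions"], arrays["bvals"])
        weights = arrays["tess_weights"] if arrays["tess_weights"].size else None
        return cls(arrays["matrix_A"], table, grid, meta["sh_order"], tess, weights)


def hash_array(a: np.ndarray) -> str:
    import hashlib

    return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()[:16]


def build_dictionary(
    gradients: GradientTable,
    grid: SpectrumGrid | None = None,
    sh_order: int = DEFAULT_SH_ORDER,
    tessellation: np.ndarray | None = None,
    tess_weights: np.ndarray | None = None,
) -> SpectrumDictionary:
    """Assemble the spectrum dictionary for a gradient table.

    Anisotropic atoms contribute blocks R_k W Y — the response matrix over
    the hemisphere tessellation, the diagonal quadrature weights, and the
    even SH basis — so that A v discretizes the spherical convolution
    integral and the coefficients are plain fODF SH coefficients.
    Isotropic atoms contribute single columns exp(-b D_iso). b=0 rows
    evaluate every atom's response to 1 before basis projection.

    For a custom tessellation without ``tess_weights``, uniform weights
    summing to 4 pi (each hemisphere point standing for its antipodal
    pair) are assumed.
    """
    if grid is None:
        grid = default_grid()
    if tessellation is None:
        tessellation, tess_weights = hemisphere_tessellation(return_weights=True)
    tessellation = np.asarray(tessellation, dtype=float)
    tessellation = tessellation / np.linalg.norm(tessellation, axis=1, keepdims=True)
    if tess_weights is None:
        tess_weights = np.full(len(tessellation), 4.0 * np.pi / len(tessellation))
    tess_weights = np.asarray(tess_weights, dtype=float)
    basis = sh_basis(tessellation, sh_order)
    wbasis = tess_weights[:, None] * basis
    blocks = [
        _response_matrix(gradients, tessellation, d_l, d_t) @ wbasis
        for d_l, d_t in grid.aniso_atoms
    ]
    for d_iso in grid.iso_atoms:
        blocks.append(np.exp(-gradients.bvals * d_iso)[:, None])
    return SpectrumDictionary(
        np.concatenate(blocks, axis=1), gradients, grid, sh_order,
        tessellation, tess_weights
    )


class SpectrumFitter(BaseEstimator):
    """Per-voxel damped least-squares fit of spectrum coefficients.

    Solves V = argmin ||E^T - A V||^2 + damping ||S V||^2 per voxel on the
    column-normalized dictionary (S the column scales), with the normal-
    equation Cholesky factorization computed once and reused across voxels.

    Parameters
    ----------
    dictionary : SpectrumDictionary
    damping : float, >= 0
        Tikhonov damping on the normalized coefficients.

    Attributes
    ----------
    coefficients_ : (P_total, N_Vox) fitted coefficient field.
    """

    def __init__(self, dictionary: SpectrumDictionary | None = None, damping: float = 0.0):
        self.dictionary = dictionary
        self.damping = damping

    def _factorize(self):
        a_hat = self.dictionary.normalized
        gram = a_hat.T @ a_hat + self.damping * np.eye(a_hat.shape[1])
        try:
            return cho_factor(gram)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular normal matrix; increase damping (e.g. 1e-8)"
            ) from exc

    def fit(self, E: SignalMatrix | np.ndarray):
        if self.dictionary is None:
            raise ValueError("a SpectrumDictionary is required")
        if self.damping < 0:
            raise ValueError("damping must be >= 0")
        values = E.values if isinstance(E, SignalMatrix) else np.asarray(E, dtype=float)
        if values.shape[1] != self.dictionary.n_q:
            raise ValueError(
                f"signal has {values.shape[1]} wavevectors, dictionary {self.dictionary.n_q}"
            )
        factor = self._factorize()
        rhs = self.dictionary.normalized.T @ values.T
        v_hat = cho_solve(factor, rhs)
        self.coefficients_ = v_hat / self.dictionary.col_scales[:, None]
        self.n_voxels_ = values.shape[0]
        return self


def fit_coefficients(E: SignalMatrix | np.ndarray, dictionary: SpectrumDictionary,
                     damping: float = 0.0) -> np.ndarray:
    """Thin wrapper over :class:`SpectrumFitter`; returns (P_total, N_Vox)."""
    return SpectrumFitter(dictionary, damping).fit(E).coefficients_
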
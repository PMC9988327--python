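"""Gradient tables and diffusion-weighted image stacks.

The q-space data model: a :class:`GradientTable` holds the diffusion
wavevectors (unit directions and b-values, with b0 entries flagged), and a
:class:`SignalMatrix` holds the signal attenuations ``E = S(q)/S0`` of a
4-D stack reshaped to ``N_Vox x N_Q``, with the spatial grid attached.

Gradients are read/written in the FSL dialect (whitespace-separated
``bvals``/``bvecs`` text files); volumes as NIfTI-1 via nibabel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

#: b-values below this (s/mm^2) are treated as b=0.
B0_THRESHOLD = 10.0


class GradientFormatError(ValueError):
    """Malformed bvals/bvecs input."""


class DimensionError(ValueError):
    """Image/gradient dimension mismatch."""


@dataclass
class GradientTable:
    """Diffusion wavevectors: unit directions, b-values and b0 flags.

    Parameters
    ----------
    directions : (N_Q, 3) float array
        Encoding directions; unit norm except where ``b0_mask`` is set.
    bvals : (N_Q,) float array
        Diffusion weightings b = |q|^2 (Delta - delta/3), in s/mm^2.
    delta_big, delta_small : float, optional
        Pulse timings Delta and delta of the PGSE sequence, in s. Purely
        informational; the model works on b directly.
    """

    directions: np.ndarray
    bvals: np.ndarray
    b0_threshold: float = B0_THRESHOLD
    delta_big: float | None = None
    delta_small: float | None = None
    b0_mask: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.directions = np.atleast_2d(np.asarray(self.directions, dtype=float))
        self.bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        if self.directions.shape != (self.bvals.size, 3):
            raise GradientFormatError(
                f"directions shape {self.directions.shape} does not match "
                f"{self.bvals.size} b-values"
            )
        if self.bvals.size < 1:
            raise GradientFormatError("empty gradient table")
        if np.any(self.bvals < 0) or not np.all(np.isfinite(self.bvals)):
            raise GradientFormatError("b-values must be finite and >= 0")
        self.b0_mask = self.bvals < self.b0_threshold
        norms = np.linalg.norm(self.directions, axis=1)
        zero = norms < 1e-12
        if np.any(zero & ~self.b0_mask):
            raise GradientFormatError(
                "zero-norm direction with non-zero b-value at index "
                f"{int(np.flatnonzero(zero & ~self.b0_mask)[0])}"
            )
        # renormalize non-b0 directions to exact unit norm
        nz = ~zero
        self.directions[nz] = self.directions[nz] / norms[nz, None]

    @property
    def n_q(self) -> int:
        return int(self.bvals.size)

    @property
    def shells(self) -> dict[float, int]:
        """Distinct non-zero b-values mapped to their direction counts."""
        out: dict[float, int] = {}
        for b in self.bvals[~self.b0_mask]:
            out[float(b)] = out.get(float(b), 0) + 1
        return out

    def without_b0(self) -> "GradientTable":
        """The table restricted to diffusion-weighted entries."""
        keep = ~self.b0_mask
        return GradientTable(
            self.directions[keep],
            self.bvals[keep],
            b0_threshold=self.b0_threshold,
            delta_big=self.delta_big,
            delta_small=self.delta_small,
        )


@dataclass
class SignalMatrix:
    """Signal attenuations on a voxel grid, as an ``N_Vox x N_Q`` matrix.

    ``values[i, q]`` is the attenuation E(q) = S(q)/S0 of voxel i (C-order
    raveled over the ``dims = (N_x, N_y, N_z)`` grid; the slice axis is the
    third spatial axis) for wavevector q. ``valid_mask`` flags voxels with
    a usable S0 normalization.
    """

    values: np.ndarray
    dims: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.dims = tuple(int(d) for d in self.dims)  # type: ignore[assignment]
        if self.values.ndim != 2:
            raise DimensionError("values must be a 2-D N_Vox x N_Q matrix")
        if self.values.shape[0] != int(np.prod(self.dims)):
            raise DimensionError(
                f"N_Vox {self.values.shape[0]} != prod(dims) {np.prod(self.dims)}"
            )
        if not np.all(np.isfinite(self.values)):
            raise DimensionError("attenuations must be finite")
        if self.values.size and self.values.max(initial=0.0) > 1.5:
            warnings.warn(
                "attenuations above 1.5 found; expected S/S0 in [0, ~1]",
                stacklevel=2,
            )
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.values.shape[0], dtype=bool)

    @property
    def n_vox(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_q(self) -> int:
        return int(self.values.shape[1])

    def volume(self, q: int) -> np.ndarray:
        """The q-th DW volume reshaped to the (N_x, N_y, N_z) grid."""
        return self.values[:, q].reshape(self.dims)

    def to_4d(self) -> np.ndarray:
        return self.values.reshape(self.dims + (self.n_q,))

    @classmethod
    def from_4d(
        cls,
        stack: np.ndarray,
        voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
        valid_mask: np.ndarray | None = None,
    ) -> "SignalMatrix":
        stack = np.asarray(stack, dtype=float)
        if stack.ndim != 4:
            raise DimensionError("expected a 4-D stack")
        dims = stack.shape[:3]
        return cls(
            stack.reshape(-1, stack.shape[3]), dims, voxel_size, valid_mask
        )


def read_gradient_table(bvals_path, bvecs_path, b0_threshold: float = B0_THRESHOLD) -> GradientTable:
    """Read an FSL-dialect bvals/bvecs pair.

    bvecs may be 3xN (FSL) or Nx3; disambiguated by shape, with 3x3 read
    as 3xN (a warning is logged).
    """
    try:
        bvals = np.loadtxt(bvals_path, dtype=float).ravel()
        bvecs = np.atleast_2d(np.loadtxt(bvecs_path, dtype=float))
    except ValueError as exc:
        raise GradientFormatError(f"non-numeric token in gradient files: {exc}") from exc
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        logger.warning("ambiguous 3x3 bvecs; interpreting as 3xN (FSL dialect)")
        bvecs = bvecs.T
    elif bvecs.shape[1] != 3:
        raise GradientFormatError(f"bvecs shape {bvecs.shape} is neither 3xN nor Nx3")
    if bvecs.shape[0] != bvals.size:
        raise GradientFormatError(
            f"bvals ({bvals.size}) and bvecs ({bvecs.shape[0]}) lengths differ"
        )
    return GradientTable(bvecs, bvals, b0_threshold=b0_threshold)


def write_gradient_table(table: GradientTable, bvals_path, bvecs_path) -> None:
    """Write a gradient table as FSL-dialect bvals (1xN) and bvecs (3xN)."""
    np.savetxt(bvals_path, table.bvals[None, :], fmt="%.6g")
    np.savetxt(bvecs_path, table.directions.T, fmt="%.10g")


def read_dwi(nifti_path, gradients: GradientTable | None = None) -> SignalMatrix:
    """Read a 4-D NIfTI stack into a SignalMatrix.

    If ``gradients`` is given, its b0 volumes are averaged into S0, excluded
    from the matrix, and the remaining volumes are normalized to attenuations
    S/S0. Voxels with S0 <= 0 are masked out (attenuation set to 0 there).
    Without a gradient table the raw values are returned unnormalized.
    """
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise DimensionError(f"expected 4-D NIfTI, got {data.ndim}-D")
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    if gradients is None:
        return SignalMatrix.from_4d(data, voxel_size)
    if data.shape[3] != gradients.n_q:
        raise DimensionError(
            f"4th dimension {data.shape[3]} != gradient table length {gradients.n_q}"
        )
    b0 = gradients.b0_mask
    if b0.any():
        s0 = data[..., b0].mean(axis=3)
    else:
        s0 = np.ones(data.shape[:3])
    valid = s0 > 0
    s0_safe = np.where(valid, s0, 1.0)
    atten = data[..., ~b0] / s0_safe[..., None]
    atten[~valid] = 0.0
    return SignalMatrix.from_4d(atten, voxel_size, valid_mask=valid.ravel())


def write_dwi(signal: SignalMatrix, nifti_path) -> None:
    """Write a SignalMatrix as a float32 4-D NIfTI-1 volume."""
    affine = np.diag(list(signal.voxel_size) + [1.0])
    img = nib.Nifti1Image(signal.to_4d().astype(np.float32), affine)
    img.header.set_zooms(signal.voxel_size + (1.0,))
    nib.save(img, str(nifti_path))
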
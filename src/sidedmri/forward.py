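"""Forward model of SIDE acquisition and its adjoint.

An acquired SIDE volume carries, for each of its slice groups, the slices of
one wavevector: entry-wise, the observation selects a slice (rows of E along
the slice-encoding axis z) and a wavevector (a column of E). Acquisition is
therefore a mask at (slice, wavevector) granularity; at SIDE factor r_side
exactly 1/r_side of all (wavevector, slice-group) pairs are acquired.
Observations are stored sparsely per acquired (cycle, volume) with the
slice-group payloads, plus the dense boolean mask the solver uses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gradients import DimensionError, SignalMatrix
from .scheme import SideScheme


@dataclass
class SideObservation:
    """Observed SIDE slices scattered into an N_Vox x N_Q container.

    ``data`` holds observed values at acquired positions (zero elsewhere);
    ``mask`` marks acquired entries and is constant across the in-plane
    voxels of a slice. ``records`` lists the acquired (cycle, volume,
    slice-group, wavevector) tuples in acquisition order.
    """

    data: np.ndarray
    mask: np.ndarray
    dims: tuple[int, int, int]
    records: list
    r_side: int
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    @property
    def n_vox(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_q(self) -> int:
        return int(self.data.shape[1])

    def acquired_fraction(self) -> float:
        return float(self.mask.mean())


def _slice_rows(dims: tuple[int, int, int], slice_idx: np.ndarray) -> np.ndarray:
    """Raveled voxel rows (C-order over dims) belonging to the given z-slices."""
    nx, ny, nz = dims
    base = np.arange(nx * ny) * nz  # offsets of (x, y, 0)
    return (base[:, None] + np.asarray(slice_idx)[None, :]).ravel()


def acquire(
    E: SignalMatrix,
    scheme: SideScheme,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> SideObservation:
    """Simulate SIDE acquisition of ``E`` under ``scheme``.

    For each acquired (cycle, volume, slice group), the slices of that group
    are copied from the wavevector column given by the scheme assignment,
    with additive Gaussian noise of standard deviation ``noise_sigma``
    (seeded, reproducible).
    """
    if E.n_q != scheme.n_q:
        raise DimensionError(f"E has {E.n_q} wavevectors, scheme expects {scheme.n_q}")
    if E.dims[2] != scheme.grouping.n_slices:
        raise DimensionError(
            f"E has {E.dims[2]} slices, scheme expects {scheme.grouping.n_slices}"
        )
    rng = np.random.default_rng(seed)
    data = np.zeros_like(E.values)
    mask = np.zeros(E.values.shape, dtype=bool)
    records = []
    for c in scheme.acquired_cycles:
        for m in range(scheme.volumes_per_cycle):
            for g in range(scheme.n_sg):
                q = scheme.assignment(c, m, g)
                rows = _slice_rows(E.dims, scheme.grouping.group_slices(g))
                vals = E.values[rows, q]
                if noise_sigma > 0:
                    vals = vals + rng.normal(0.0, noise_sigma, size=vals.shape)
                data[rows, q] = vals
                mask[rows, q] = True
                records.append((int(c), int(m), int(g), int(q)))
    return SideObservation(data, mask, E.dims, records, scheme.r_side, E.voxel_size)


def acquire_conventional(
    E: SignalMatrix,
    selected_q: np.ndarray,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> SideObservation:
    """Conventional angular undersampling: full volumes for a wavevector subset.

    The comparator to SIDE at matched volume budget — ``len(selected_q)``
    fully sampled volumes instead of all volumes at 1/r_side slice coverage.
    """
    selected_q = np.asarray(selected_q, dtype=int)
    if selected_q.size == 0 or selected_q.max() >= E.n_q:
        raise DimensionError("selected wavevector indices out of range")
    rng = np.random.default_rng(seed)
    data = np.zeros_like(E.values)
    mask = np.zeros(E.values.shape, dtype=bool)
    vals = E.values[:, selected_q]
    if noise_sigma > 0:
        vals = vals + rng.normal(0.0, noise_sigma, size=vals.shape)
    data[:, selected_q] = vals
    mask[:, selected_q] = True
    r_eff = max(1, E.n_q // selected_q.size)
    records = [(0, int(i), -1, int(q)) for i, q in enumerate(selected_q)]
    return SideObservation(data, mask, E.dims, records, r_eff, E.voxel_size)


def adjoint(obs: SideObservation) -> SignalMatrix:
    """Zero-filled adjoint: observed entries at their positions, zeros elsewhere."""
    return SignalMatrix(obs.data * obs.mask, obs.dims, obs.voxel_size)


def data_residual(E: SignalMatrix, obs: SideObservation) -> float:
    """Data-fidelity term: half the sum of squared differences on acquired entries."""
    diff = (E.values - obs.data)[obs.mask]
    return 0.5 * float(diff @ diff)
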
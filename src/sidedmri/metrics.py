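"""Evaluation metrics for reconstructed DW images.

NMSE and PSNR follow the conventions used with this reconstruction method:

    NMSE = ||E - E_truth||_F / N_Vox          (norm, not squared)
    PSNR = 10 log10(MAX / NMSE)               (MAX of the truth over the mask)

These differ from the textbook definitions (squared norm over the reference
energy; MAX^2 over the MSE); the conventional variants are available as
:func:`nmse_conventional` and :func:`psnr_conventional`. SSIM is the mean
local structural-similarity index with the standard constants (K1 = 0.01,
K2 = 0.03, Gaussian window sigma = 1.5, 11^3 support), computed in 3-D per
DW volume and averaged over wavevectors. GFA is std/rms of the fODF
amplitudes per voxel. FBO is 1 minus the normalized absolute difference of
two voxelwise bundle-probability maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .gradients import SignalMatrix

PSNR_CEILING_DB = 300.0


def _as_matrix(x) -> np.ndarray:
    return x.values if isinstance(x, SignalMatrix) else np.asarray(x, dtype=float)


def _resolve_mask(values: np.ndarray, mask) -> np.ndarray:
    if mask is None:
        mask = np.ones(values.shape[0], dtype=bool)
    mask = np.asarray(mask).astype(bool).ravel()
    if mask.size != values.shape[0]:
        raise ValueError("mask length does not match the voxel count")
    if not mask.any():
        raise ValueError("empty evaluation mask")
    return mask


def nmse(E, E_truth, mask=None) -> float:
    """Frobenius norm of the masked difference divided by N_Vox."""
    a, b = _as_matrix(E), _as_matrix(E_truth)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    m = _resolve_mask(a, mask)
    n_vox = int(m.sum())
    return float(np.linalg.norm(a[m] - b[m])) / n_vox


def nmse_conventional(E, E_truth, mask=None) -> float:
    """Textbook NMSE: squared error energy over reference energy."""
    a, b = _as_matrix(E), _as_matrix(E_truth)
    m = _resolve_mask(a, mask)
    denom = float((b[m] ** 2).sum())
    if denom == 0:
        raise ValueError("reference is all zero on the mask")
    return float(((a[m] - b[m]) ** 2).sum()) / denom


def psnr(E, E_truth, mask=None, ceiling: float = PSNR_CEILING_DB) -> float:
    """10 log10(MAX / NMSE), MAX the truth maximum over the mask.

    Capped at ``ceiling`` dB when NMSE vanishes (identical inputs).
    """
    a, b = _as_matrix(E), _as_matrix(E_truth)
    m = _resolve_mask(a, mask)
    err = nmse(E, E_truth, mask)
    peak = float(b[m].max())
    if err == 0:
        return ceiling
    return min(10.0 * np.log10(peak / err), ceiling)


def psnr_conventional(E, E_truth, mask=None, ceiling: float = PSNR_CEILING_DB) -> float:
    """Textbook PSNR: 10 log10(MAX^2 / MSE)."""
    a, b = _as_matrix(E), _as_matrix(E_truth)
    m = _resolve_mask(a, mask)
    mse = float(((a[m] - b[m]) ** 2).mean())
    peak = float(b[m].max())
    if mse == 0:
        return ceiling
    return min(10.0 * np.log10(peak**2 / mse), ceiling)


def _ssim_volume(a: np.ndarray, b: np.ndarray, sigma: float = 1.5,
                 truncate: float = 3.5, k1: float = 0.01, k2: float = 0.03,
                 data_range: float | None = None) -> float:
    """Mean local SSIM of two 3-D volumes, Gaussian-windowed.

    The window is 2*ceil(truncate*sigma)+1 wide (11 at the defaults); the
    SSIM map is cropped by the window radius at the borders before
    averaging, so border voxels with truncated support do not contribute.
    """
    if a.shape != b.shape:
        raise ValueError("volumes must have the same shape")
    if data_range is None:
        lo = min(a.min(), b.min())
        hi = max(a.max(), b.max())
        data_range = hi - lo if hi > lo else 1.0
    radius = int(truncate * sigma + 0.5)
    if min(a.shape) < 2 * radius + 1:
        import warnings

        warnings.warn("volume smaller than the SSIM window; shrinking window",
                      stacklevel=2)
        radius = max((min(a.shape) - 1) // 2, 1)
        truncate = radius / sigma

    def filt(x):
        return gaussian_filter(x, sigma, truncate=truncate)

    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    mu_a, mu_b = filt(a), filt(b)
    var_a = filt(a * a) - mu_a**2
    var_b = filt(b * b) - mu_b**2
    cov = filt(a * b) - mu_a * mu_b
    num = (2 * mu_a * mu_b + c1) * (2 * cov + c2)
    den = (mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2)
    smap = num / den
    core = tuple(slice(radius, s - radius) for s in smap.shape)
    return float(smap[core].mean())


def ssim(volume_a, volume_b, dims: tuple[int, int, int] | None = None, **kwargs) -> float:
    """Mean 3-D SSIM; SignalMatrix inputs are averaged over wavevectors."""
    if isinstance(volume_a, SignalMatrix):
        dims = volume_a.dims
    a, b = _as_matrix(volume_a), _as_matrix(volume_b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    if a.ndim == 3:
        return _ssim_volume(a, b, **kwargs)
    if dims is None:
        raise ValueError("dims required for matrix-form inputs")
    vols_a = a.T.reshape((-1,) + tuple(dims))
    vols_b = b.T.reshape((-1,) + tuple(dims))
    return float(np.mean([
        _ssim_volume(va, vb, **kwargs) for va, vb in zip(vols_a, vols_b)
    ]))


def relative_difference(x, x_truth, threshold: float = 1e-12) -> np.ndarray:
    """Elementwise |x - x_GT| / x_GT; NaN where the truth is <= threshold."""
    x = np.asarray(x, dtype=float)
    gt = np.asarray(x_truth, dtype=float)
    out = np.full(np.broadcast(x, gt).shape, np.nan)
    ok = gt > threshold
    np.divide(np.abs(x - gt), gt, out=out, where=ok)
    return out


def fiber_bundle_overlap(p, p_truth) -> float:
    """FBO = 1 - sum|p - p_GT| / sum p_GT on voxelwise probability maps.

    May be negative for gross mismatches; reported as-is.
    """
    p = np.asarray(p, dtype=float)
    gt = np.asarray(p_truth, dtype=float)
    if p.shape != gt.shape:
        raise ValueError("probability maps must share a grid")
    if np.any(p < 0) or np.any(gt < 0):
        raise ValueError("probability maps must be non-negative")
    denom = gt.sum()
    if denom == 0:
        raise ValueError("ground-truth map is all zero")
    return float(1.0 - np.abs(p - gt).sum() / denom)


def gfa(fodf_amplitudes: np.ndarray) -> np.ndarray:
    """Generalized fractional anisotropy: std/rms of the amplitudes.

    The last axis holds the N_F tessellation amplitudes per voxel
    (population standard deviation); 0 where the rms vanishes.
    """
    amp = np.asarray(fodf_amplitudes, dtype=float)
    rms = np.sqrt((amp**2).mean(axis=-1))
    std = amp.std(axis=-1)
    out = np.divide(std, rms, out=np.zeros_like(std), where=rms > 0)
    return out


@dataclass
class MetricReport:
    """NMSE/PSNR/SSIM summary with an optional per-shell breakdown."""

    nmse: float
    psnr: float
    ssim: float
    per_shell: dict | None = None
    n_voxels: int = 0

    def __post_init__(self) -> None:
        if self.nmse < 0 or not -1.0 <= self.ssim <= 1.0:
            raise ValueError("inconsistent metric values")

    def to_dict(self) -> dict:
        out = {"nmse": self.nmse, "psnr": self.psnr, "ssim": self.ssim,
               "n_voxels": self.n_voxels}
        if self.per_shell is not None:
            out["per_shell"] = self.per_shell
        return out


def evaluate(E, E_truth, mask=None, bvals: np.ndarray | None = None) -> MetricReport:
    """Full metric report between a reconstruction and the ground truth."""
    if isinstance(E, SignalMatrix) and isinstance(E_truth, SignalMatrix):
        if E.dims != E_truth.dims:
            raise ValueError("grids differ")
    m = _resolve_mask(_as_matrix(E), mask)
    per_shell = None
    if bvals is not None:
        a, b = _as_matrix(E), _as_matrix(E_truth)
        per_shell = {}
        for bval in sorted(set(np.asarray(bvals, dtype=float))):
            cols = np.asarray(bvals, dtype=float) == bval
            per_shell[bval] = nmse(a[:, cols], b[:, cols], mask)
    return MetricReport(
        nmse=nmse(E, E_truth, mask),
        psnr=psnr(E, E_truth, mask),
        ssim=ssim(E, E_truth),
        per_shell=per_shell,
        n_voxels=int(m.sum()),
    )
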
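"""ADMM reconstruction of full DW images from slice-undersampled SIDE data.

The constrained problem

    min_E 1/2 sum_{q,l} ||H_l E w_ql - E^S_q(:,l)||_F^2 + lambda ||E||_TV
    s.t.  E^T = A V

(data fidelity on acquired slices, TV regularization per DW volume, and the
diffusion-spectrum dictionary constraint) is split with auxiliary volumes
U_q ~ E^(q) and solved by ADMM with scaled multipliers Psi_q (TV split) and
Phi (dictionary split):

    1. V   <- argmin ||E^T + Phi - A V||^2          (damped least squares)
    2. U_q <- prox_{(lambda/rho1) TV}(E^(q) - Psi_q)   per wavevector
    3. E   <- elementwise closed form combining data, U + Psi, (A V - Phi)^T
    4. Psi_q += U_q - E^(q);  Phi += E^T - A V

Iterations stop at max_iter or when the squared multiplier changes fall
below (eps1, eps2) jointly. The multiplier changes coincide with the primal
residuals of the two splits, which are logged per iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_solve
from sklearn.base import BaseEstimator

from .forward import SideObservation, adjoint, data_residual
from .gradients import SignalMatrix
from .spectrum import SpectrumDictionary, SpectrumFitter
from .tv import TVWeights, tv_prox, tv_seminorm

logger = logging.getLogger(__name__)


class ReconDivergence(RuntimeError):
    """The ADMM objective increased far beyond its running minimum."""


@dataclass
class ReconConfig:
    """Solver settings.

    lambda_tv is the TV regularization weight (default 0.01); rho1, rho2
    the ADMM penalties of the TV and dictionary splits (default 0.5 each);
    eps1/eps2 the stopping tolerances on the squared multiplier change,
    defaulting to 1e-6 per matrix entry.
    """

    lambda_tv: float = 0.01
    rho1: float = 0.5
    rho2: float = 0.5
    weights: TVWeights = field(default_factory=TVWeights)
    eps1: float | None = None
    eps2: float | None = None
    max_iter: int = 100
    dict_damping: float = 1e-8
    tv_inner_iters: int = 50
    tv_tol: float = 1e-5

    def __post_init__(self) -> None:
        if self.rho1 <= 0 or self.rho2 <= 0:
            raise ValueError("rho1 and rho2 must be > 0")
        if self.lambda_tv < 0 or self.dict_damping < 0:
            raise ValueError("lambda_tv and dict_damping must be >= 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        for name in ("eps1", "eps2"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class ReconResult:
    """Recovered signal plus final ADMM state and per-iteration history."""

    signal: SignalMatrix
    coefficients: np.ndarray
    U: np.ndarray
    Psi: np.ndarray
    Phi: np.ndarray
    history: dict
    n_iter: int
    stop_reason: str


def update_V(E: np.ndarray, Phi: np.ndarray, dictionary: SpectrumDictionary,
             damping: float = 0.0, fitter: SpectrumFitter | None = None) -> np.ndarray:
    """Dictionary-coefficient subproblem: argmin_V ||E^T + Phi - A V||^2.

    A prefactorized :class:`SpectrumFitter` can be passed to reuse the
    normal-equation Cholesky across iterations.
    """
    target = (E.T + Phi).T  # (N_Vox, N_Q) view for the fitter
    if fitter is None:
        fitter = SpectrumFitter(dictionary, damping)
    return fitter.fit(target).coefficients_


def update_U(E: np.ndarray, Psi: np.ndarray, dims: tuple[int, int, int],
             cfg: ReconConfig) -> np.ndarray:
    """TV subproblem: U_q = prox_{(lambda/rho1) TV}(E^(q) - Psi_q), all q jointly."""
    target = E - Psi
    if cfg.lambda_tv == 0:
        return target.copy()
    vols = target.T.reshape((-1,) + tuple(dims))
    out = tv_prox(vols, cfg.weights, cfg.lambda_tv / cfg.rho1,
                  cfg.tv_inner_iters, cfg.tv_tol)
    return out.reshape(vols.shape[0], -1).T


def update_E(obs: SideObservation, U: np.ndarray, Psi: np.ndarray,
             AV: np.ndarray, Phi: np.ndarray, cfg: ReconConfig) -> np.ndarray:
    """Signal subproblem: elementwise closed form.

    The data, TV-split and dictionary-split quadratics are separable per
    entry: E = (M Y + rho1 (U + Psi) + rho2 (A V - Phi)^T) / (M + rho1 + rho2),
    with M the acquisition mask and Y the observed values. Entries with a
    zero denominator (possible only in the rho -> 0 limit) are set to 0.
    """
    m = obs.mask.astype(float)
    num = m * obs.data + cfg.rho1 * (U + Psi) + cfg.rho2 * (AV - Phi).T
    den = m + cfg.rho1 + cfg.rho2
    return np.divide(num, den, out=np.zeros_like(num), where=den > 0)


def update_multipliers(Psi: np.ndarray, Phi: np.ndarray, U: np.ndarray,
                       E: np.ndarray, AV: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scaled dual ascent: Psi += U - E (per volume); Phi += E^T - A V."""
    return Psi + (U - E), Phi + (E.T - AV)


def reconstruct(obs: SideObservation, dictionary: SpectrumDictionary,
                cfg: ReconConfig | None = None) -> ReconResult:
    """Run the full ADMM cycle (V, U, E, multipliers) on a SIDE observation."""
    if cfg is None:
        cfg = ReconConfig()
    if obs.n_q != dictionary.n_q:
        raise ValueError(
            f"observation has {obs.n_q} wavevectors, dictionary {dictionary.n_q}"
        )
    n_entries = obs.data.size
    eps1 = cfg.eps1 if cfg.eps1 is not None else 1e-6 * n_entries
    eps2 = cfg.eps2 if cfg.eps2 is not None else 1e-6 * n_entries

    fitter = SpectrumFitter(dictionary, cfg.dict_damping)
    a_hat = dictionary.normalized

    E = adjoint(obs).values
    U = E.copy()
    Psi = np.zeros_like(E)
    Phi = np.zeros((obs.n_q, obs.n_vox))
    history: dict[str, list[float]] = {
        "psi_change": [], "phi_change": [], "data_residual": [], "objective": []
    }
    best_obj = np.inf
    stop_reason = "max_iter"
    t = 0
    for t in range(1, cfg.max_iter + 1):
        V = update_V(E, Phi, dictionary, cfg.dict_damping, fitter)
        AV = a_hat @ (V * dictionary.col_scales[:, None])
        U = update_U(E, Psi, obs.dims, cfg)
        E = update_E(obs, U, Psi, AV, Phi, cfg)
        # multiplier increments double as the primal residuals of the splits
        d_psi = float(((U - E) ** 2).sum())
        d_phi = float(((E.T - AV) ** 2).sum())
        Psi, Phi = update_multipliers(Psi, Phi, U, E, AV)

        sig = SignalMatrix(E, obs.dims, obs.voxel_size)
        res = data_residual(sig, obs)
        obj = res
        if cfg.lambda_tv > 0:
            vols = E.T.reshape((-1,) + tuple(obs.dims))
            obj = res + cfg.lambda_tv * float(tv_seminorm(vols, cfg.weights).sum())
        history["psi_change"].append(d_psi)
        history["phi_change"].append(d_phi)
        history["data_residual"].append(res)
        history["objective"].append(obj)
        best_obj = min(best_obj, obj)
        if obj > 10 * best_obj and obj > 1e-9:
            raise ReconDivergence(
                f"objective {obj:.3e} exceeds 10x its minimum {best_obj:.3e} "
                f"at iteration {t}"
            )
        logger.debug(
            "ADMM iter %d: |dPsi|^2=%.3e |dPhi|^2=%.3e data=%.3e obj=%.3e",
            t, d_psi, d_phi, res, obj,
        )
        if d_psi <= eps1 and d_phi <= eps2:
            stop_reason = "tolerance"
            break

    V = update_V(E, Phi, dictionary, cfg.dict_damping, fitter)
    return ReconResult(
        signal=SignalMatrix(E, obs.dims, obs.voxel_size),
        coefficients=V,
        U=U, Psi=Psi, Phi=Phi,
        history=history, n_iter=t, stop_reason=stop_reason,
    )


class SideReconstructor(BaseEstimator):
    """Scikit-learn-style front end to the ADMM reconstruction.

    Parameters mirror :class:`ReconConfig`; ``fit(obs)`` solves the inverse
    problem for one :class:`~sidedmri.forward.SideObservation`.

    Attributes
    ----------
    signal_ : SignalMatrix
        Recovered N_Vox x N_Q attenuation matrix.
    coefficients_ : (P_total, N_Vox) ndarray
        Final spectrum coefficients.
    history_ : dict of per-iteration residuals and objective values.
    n_iter_ : int
    stop_reason_ : str, "tolerance" or "max_iter".
    """

    def __init__(
        self,
        dictionary: SpectrumDictionary | None = None,
        lambda_tv: float = 0.01,
        rho1: float = 0.5,
        rho2: float = 0.5,
        gamma_x: float = 0.9,
        gamma_y: float = 0.9,
        gamma_z: float = 1.0,
        eps1: float | None = None,
        eps2: float | None = None,
        max_iter: int = 100,
        dict_damping: float = 1e-8,
        tv_inner_iters: int = 50,
        tv_tol: float = 1e-5,
    ):
        self.dictionary = dictionary
        self.lambda_tv = lambda_tv
        self.rho1 = rho1
        self.rho2 = rho2
        self.gamma_x = gamma_x
        self.gamma_y = gamma_y
        self.gamma_z = gamma_z
        self.eps1 = eps1
        self.eps2 = eps2
        self.max_iter = max_iter
        self.dict_damping = dict_damping
        self.tv_inner_iters = tv_inner_iters
        self.tv_tol = tv_tol

    def _config(self) -> ReconConfig:
        return ReconConfig(
            lambda_tv=self.lambda_tv, rho1=self.rho1, rho2=self.rho2,
            weights=TVWeights(self.gamma_x, self.gamma_y, self.gamma_z),
            eps1=self.eps1, eps2=self.eps2, max_iter=self.max_iter,
            dict_damping=self.dict_damping,
            tv_inner_iters=self.tv_inner_iters, tv_tol=self.tv_tol,
        )

    def fit(self, obs: SideObservation, y=None):
        if self.dictionary is None:
            raise ValueError("a SpectrumDictionary is required")
        result = reconstruct(obs, self.dictionary, self._config())
        self.result_ = result
        self.signal_ = result.signal
        self.coefficients_ = result.coefficients
        self.history_ = result.history
        self.n_iter_ = result.n_iter
        self.stop_reason_ = result.stop_reason
        return self

    def transform(self, obs: SideObservation) -> SignalMatrix:
        """Reconstruct an observation (stateless apart from parameters)."""
        return reconstruct(obs, self.dictionary, self._config()).signal
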
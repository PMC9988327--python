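"""End-to-end orchestration: phantom -> plan -> forward -> recon -> eval.

Every stage writes its artifact plus a JSON provenance sidecar (config,
seed, package version, SHA-256 of the inputs), and each stage is
individually invocable. The whole pipeline is deterministic under a fixed
seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .forward import SideObservation, acquire, adjoint
from .gradients import SignalMatrix, read_dwi, write_dwi, write_gradient_table
from .metrics import evaluate
from .phantom import PhantomSpec, default_phantom, make_gradients, synthesize
from .recon import SideReconstructor
from .scheme import SideScheme, make_grouping, plan_side, total_acceleration
from .spectrum import build_dictionary, default_grid

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    """Configuration of a full synthetic run.

    Scheme sizes, solver settings and the noise level; the slice count is
    the phantom's z dimension. Loadable from YAML with flag overrides.
    """

    out_dir: str = "side_run"
    seed: int = 42
    r_sms: int = 3
    r_side: int = 2
    noise_sigma: float = 1.0 / 30.0
    lambda_tv: float = 0.01
    rho1: float = 0.5
    rho2: float = 0.5
    gamma: tuple[float, float, float] = (0.9, 0.9, 1.0)
    max_iter: int = 100
    sh_order: int = 8
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    _TYPES = {
        "out_dir": str, "seed": int, "r_sms": int, "r_side": int,
        "noise_sigma": (int, float), "lambda_tv": (int, float),
        "rho1": (int, float), "rho2": (int, float),
        "max_iter": int, "sh_order": int, "log_level": str,
    }

    def validate(self) -> "RunConfig":
        for name, typ in self._TYPES.items():
            val = getattr(self, name)
            if not isinstance(val, typ) or isinstance(val, bool):
                raise ConfigError(f"config field {name!r} has invalid value {val!r}")
        if len(self.gamma) != 3 or any(g < 0 for g in self.gamma):
            raise ConfigError(f"gamma must be 3 non-negative weights, got {self.gamma}")
        if self.seed < 0 or self.max_iter < 1 or self.sh_order % 2:
            raise ConfigError("seed >= 0, max_iter >= 1, even sh_order required")
        return self

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must hold a mapping")
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        kwargs.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(extra=extra, **kwargs)
        if isinstance(cfg.gamma, list):
            cfg.gamma = tuple(cfg.gamma)
        return cfg.validate()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_sidecar(artifact: Path, stage: str, config: dict,
                  inputs: list[Path] | None = None, **extra) -> Path:
    sidecar = artifact.with_suffix(artifact.suffix + ".json") if artifact.suffix != ".json" \
        else artifact.with_name(artifact.stem + ".prov.json")
    payload = {
        "stage": stage,
        "package_version": __version__,
        "config": config,
        "input_hashes": {str(p): _sha256(Path(p)) for p in (inputs or [])},
        **extra,
    }
    with open(sidecar, "w") as fh:
        json.dump(payload, fh, indent=1, default=str)
    return sidecar


def save_observation(obs: SideObservation, scheme: SideScheme, path: Path,
                     config: dict) -> None:
    """Write an observation as a zero-filled NIfTI stack + scheme sidecar."""
    write_dwi(SignalMatrix(obs.data * obs.mask, obs.dims, obs.voxel_size), path)
    write_sidecar(path, "forward", config, scheme_json=json.loads(scheme.to_json()))


def load_observation(path: Path) -> tuple[SideObservation, SideScheme]:
    """Rebuild an observation from a NIfTI stack + scheme sidecar.

    The mask is reconstructed deterministically from the scheme, the data
    from the stack; this mirrors how a scanner would emit SIDE data."""
    sidecar = Path(str(path) + ".json")
    with open(sidecar) as fh:
        meta = json.load(fh)
    scheme = SideScheme.from_json(json.dumps(meta["scheme_json"]))
    stack = read_dwi(path)
    template = SignalMatrix(np.zeros_like(stack.values), stack.dims, stack.voxel_size)
    obs = acquire(template, scheme, noise_sigma=0.0)
    obs.data[obs.mask] = stack.values[obs.mask]
    return obs, scheme


def run_pipeline(config: RunConfig, phantom_spec: PhantomSpec | None = None) -> dict:
    """Execute the five stages, writing every intermediate with provenance.

    Returns a report dict (paths, scheme accounting, metrics). A stage
    failure propagates after a failure marker is written.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = asdict(config)
    report: dict = {"config": cfg_dict, "package_version": __version__}
    try:
        # 1. phantom
        spec = phantom_spec if phantom_spec is not None else default_phantom()
        spec = PhantomSpec(spec.dims, spec.regions, spec.shells,
                           config.noise_sigma, spec.noise_model, config.seed)
        gradients = make_gradients(spec.shells, seed=config.seed)
        truth, noisy = synthesize(spec, gradients)
        truth_path, noisy_path = out / "truth.nii.gz", out / "noisy.nii.gz"
        write_dwi(truth, truth_path)
        write_dwi(noisy, noisy_path)
        write_gradient_table(gradients, out / "bvals", out / "bvecs")
        write_sidecar(truth_path, "phantom", cfg_dict, seed=config.seed)

        # 2. plan
        if spec.dims[2] % config.r_sms:
            raise ConfigError(
                f"r_sms={config.r_sms} does not divide {spec.dims[2]} slices"
            )
        grouping = make_grouping(spec.dims[2], config.r_sms)
        scheme = plan_side(grouping, truth.n_q, config.r_side)
        scheme_path = out / "scheme.json"
        scheme_path.write_text(scheme.to_json())
        report["scheme"] = {
            "n_sg": scheme.n_sg,
            "volumes_per_cycle": scheme.volumes_per_cycle,
            "acquired_volumes": scheme.n_acquired_volumes,
            "total_acceleration": total_acceleration(scheme),
        }

        # 3. forward
        obs = acquire(truth, scheme, noise_sigma=config.noise_sigma,
                      seed=config.seed + 1)
        obs_path = out / "observation.nii.gz"
        save_observation(obs, scheme, obs_path, cfg_dict)

        # 4. recon
        dictionary = build_dictionary(gradients, default_grid(), config.sh_order)
        recon = SideReconstructor(
            dictionary, lambda_tv=config.lambda_tv, rho1=config.rho1,
            rho2=config.rho2, gamma_x=config.gamma[0], gamma_y=config.gamma[1],
            gamma_z=config.gamma[2], max_iter=config.max_iter,
        ).fit(obs)
        recon_path = out / "recon.nii.gz"
        write_dwi(recon.signal_, recon_path)
        write_sidecar(
            recon_path, "recon", cfg_dict, inputs=[obs_path],
            n_iter=recon.n_iter_, stop_reason=recon.stop_reason_,
            final_residuals={k: v[-1] for k, v in recon.history_.items()},
        )
        report["recon"] = {"n_iter": recon.n_iter_, "stop_reason": recon.stop_reason_}

        # 5. eval
        zero_fill = adjoint(obs)
        metrics = {
            "recon": evaluate(recon.signal_, truth, bvals=gradients.bvals[~gradients.b0_mask]).to_dict(),
            "zero_filled": evaluate(zero_fill, truth).to_dict(),
        }
        report["metrics"] = metrics
        eval_path = out / "eval.json"
        eval_path.write_text(json.dumps({"seed": config.seed, **metrics},
                                        indent=1, sort_keys=True))
        write_sidecar(eval_path, "eval", cfg_dict, inputs=[recon_path, truth_path])
        report["paths"] = {
            "truth": str(truth_path), "noisy": str(noisy_path),
            "observation": str(obs_path), "recon": str(recon_path),
            "eval": str(eval_path), "scheme": str(scheme_path),
        }
    except Exception as exc:
        (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise
    return report
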
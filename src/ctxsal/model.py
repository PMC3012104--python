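"""The trained saliency model: whitening + structured ICA + GG densities.

A :class:`SaliencyModel` bundles everything needed to score a new scene:
the patch geometry, the separate target/context whitening transforms, the
joint unpaired-amplitude filter, and the per-component generalized-Gaussian
densities fitted on training amplitudes.  Models persist as a single
versioned ``.npz`` container; loading validates the schema version and the
presence of every block.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .density import GGParams, fit_gg_per_component
from .patches import PatchBatch, PatchConfig, WhitenTransform
from .structured_ica import ICAModel, amplitudes, fit_structured_ica

__all__ = ["SaliencyModel", "save_model", "load_model", "train_model"]

SCHEMA_VERSION = 1


@dataclass
class SaliencyModel:
    config: PatchConfig
    ica: ICAModel
    gg: GGParams

    @property
    def k_u(self) -> int:
        return self.ica.k_u


def _pack_whiten(prefix: str, t: WhitenTransform, out: dict) -> None:
    out[f"{prefix}_mean"] = t.mean
    out[f"{prefix}_forward"] = t.forward
    out[f"{prefix}_inverse"] = t.inverse


def _unpack_whiten(prefix: str, data) -> WhitenTransform:
    fwd = data[f"{prefix}_forward"]
    return WhitenTransform(
        mean=data[f"{prefix}_mean"],
        forward=fwd,
        inverse=data[f"{prefix}_inverse"],
        retained_k=fwd.shape[0],
    )


def save_model(model: SaliencyModel, path: str | Path) -> None:
    """Serialize to a single versioned npz container (bit-exact round trip)."""
    out: dict = {
        "schema_version": np.array(SCHEMA_VERSION),
        "cfg_center_diameter": np.array(model.config.center_diameter),
        "cfg_surround_diameter": np.array(model.config.surround_diameter),
        "cfg_channels": np.array(model.config.channels),
        "cfg_temporal_depth": np.array(model.config.temporal_depth),
        "ica_W_s": model.ica.W_s,
        "ica_A_ss": model.ica.A_ss,
        "ica_A_cs": model.ica.A_cs,
        "ica_A_cu": model.ica.A_cu,
        "ica_W_u_joint": model.ica.W_u_joint,
        "ica_residual_offset": np.asarray(
            model.ica.diagnostics.get("residual_offset", np.zeros(model.ica.k_u))
        ),
        "gg_scale": model.gg.scale,
        "gg_shape": model.gg.shape,
    }
    if model.config.explicit_radii is not None:
        out["cfg_explicit_radii"] = np.asarray(model.config.explicit_radii, dtype=float)
    _pack_whiten("whiten_c", model.ica.whiten_c, out)
    _pack_whiten("whiten_s", model.ica.whiten_s, out)
    np.savez(Path(path), **out)


def load_model(path: str | Path) -> SaliencyModel:
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such model file: {path}")
    try:
        data = np.load(path)
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"cannot read model container {path}: {exc}") from exc
    if "schema_version" not in data:
        raise ValueError(f"{path} is not a saliency model container")
    version = int(data["schema_version"])
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"model schema version {version} is incompatible with supported version "
            f"{SCHEMA_VERSION}"
        )
    required = ["ica_W_s", "ica_A_ss", "ica_A_cs", "ica_A_cu", "ica_W_u_joint",
                "gg_scale", "gg_shape", "whiten_c_forward", "whiten_s_forward"]
    missing = [k for k in required if k not in data]
    if missing:
        raise ValueError(f"model container {path} is missing blocks: {missing}")
    cfg = PatchConfig(
        center_diameter=int(data["cfg_center_diameter"]),
        surround_diameter=int(data["cfg_surround_diameter"]),
        channels=int(data["cfg_channels"]),
        temporal_depth=int(data["cfg_temporal_depth"]),
        explicit_radii=(
            tuple(data["cfg_explicit_radii"]) if "cfg_explicit_radii" in data else None
        ),
    )
    W_u_joint = data["ica_W_u_joint"]
    ica = ICAModel(
        whiten_c=_unpack_whiten("whiten_c", data),
        whiten_s=_unpack_whiten("whiten_s", data),
        k_s=data["ica_W_s"].shape[0],
        k_u=W_u_joint.shape[0],
        W_s=data["ica_W_s"],
        A_ss=data["ica_A_ss"],
        A_cs=data["ica_A_cs"],
        A_cu=data["ica_A_cu"],
        W_u_joint=W_u_joint,
        diagnostics={"residual_offset": data["ica_residual_offset"]},
    )
    gg = GGParams(data["gg_scale"], data["gg_shape"])
    return SaliencyModel(config=cfg, ica=ica, gg=gg)


def train_model(
    batch: PatchBatch,
    config: PatchConfig,
    k_c: int,
    k_s: int,
    k_u: int | None = None,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    ml_refine: bool = False,
) -> SaliencyModel:
    """Fit structured ICA on a patch batch, then GG densities on its amplitudes.

    Densities are fitted on amplitudes pooled across all training patches,
    reflecting statistics of the scene ensemble rather than any one image.
    """
    if batch.X_c.shape[1] != config.d_center or batch.X_s.shape[1] != config.d_context:
        raise ValueError(
            f"batch dims ({batch.X_c.shape[1]}, {batch.X_s.shape[1]}) do not match "
            f"config dims ({config.d_center}, {config.d_context})"
        )
    ica = fit_structured_ica(batch, k_c=k_c, k_s=k_s, k_u=k_u, seed=seed,
                             tol=tol, max_iter=max_iter)
    U = amplitudes(ica, batch.X_c, batch.X_s)
    gg = fit_gg_per_component(U, ml_refine=ml_refine)
    return SaliencyModel(config=config, ica=ica, gg=gg)
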
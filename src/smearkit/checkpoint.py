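"""Model checkpoints: weights as ``.npz`` plus a JSON sidecar carrying
the architecture config and the declarative layer table, so a
checkpoint is self-describing and reloadable without pickle."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

__all__ = ["save_checkpoint", "load_checkpoint"]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (tuple, list)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    return obj


def save_checkpoint(model, path: str | Path, extra: dict | None = None) -> Path:
    """Write ``<path>.npz`` (weights) and ``<path>.json`` (sidecar).

    ``model`` is a built U-Net or classifier carrying its ``cfg``/``spec``.
    """
    from .classifier import LWCNNConfig
    from .unet import UNet

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    weights = model.get_weights()
    np.savez(path.with_suffix(".npz"), *weights)
    if isinstance(model, UNet):
        kind, cfg = "unet", model.cfg
    else:
        kind = "lwcnn"
        cfg = getattr(model, "cfg", None) or LWCNNConfig()
    sidecar = {
        "kind": kind,
        "config": _jsonable(cfg),
        "layers": [
            {"name": r.name, "kind": r.kind, "output_shape": list(r.output_shape),
             "n_params": r.n_params, "activation": r.activation}
            for r in model.spec.layers
        ],
        "total_params": model.spec.total_params,
        "extra": _jsonable(extra or {}),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path.with_suffix(".npz")


def _tuplify(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


def load_checkpoint(path: str | Path):
    """Rebuild the model described by the sidecar and restore its weights."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg_dict = _tuplify(sidecar["config"])
    if sidecar["kind"] == "unet":
        from .unet import UNetConfig, build_unet

        model = build_unet(UNetConfig(**cfg_dict))
    else:
        from .classifier import LWCNNConfig, build_lwcnn

        model = build_lwcnn(LWCNNConfig(**cfg_dict))
    with np.load(path.with_suffix(".npz")) as data:
        model.set_weights([data[f"arr_{i}"] for i in range(len(data.files))])
    if model.spec.total_params != sidecar["total_params"]:
        raise ValueError("checkpoint sidecar does not match the rebuilt model")
    return model
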
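"""Pipeline configuration: defaults, YAML loading, validation.

An empty config file resolves to the published defaults (probability
threshold tau = 0.5, minimum inter-peak distance 7 px, area bounds
80/6000 px, circularity floor 0.40, CLAHE clip 2.0 on an 8x8 tile grid,
and the Adam/early-stopping training policy).  Unknown keys are
rejected; validation errors name the offending key and its allowed
range.  The ablation toggles switch CLAHE, augmentation, ROI
segmentation (off = direct-tile mode) and two extra classifier
convolution blocks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .preprocessing import ClaheParams
from .watershed import WatershedParams

__all__ = ["Toggles", "SynthSettings", "UNetSettings", "LWCNNSettings",
           "PipelineConfig", "load_config", "validate_config", "dump_config"]


@dataclass(frozen=True)
class Toggles:
    """Ablation switches (one per published ablation row)."""

    clahe: bool = True
    augmentation: bool = True
    segmentation: bool = True  # False = classifier consumes direct tiles
    extra_conv_blocks: int = 0  # 0 | 2

    def __post_init__(self):
        if self.extra_conv_blocks not in (0, 2):
            raise ValueError("toggles.extra_conv_blocks must be 0 or 2")


@dataclass(frozen=True)
class SynthSettings:
    """Synthetic-data scale for a pipeline run."""

    n_smears: int = 24
    height: int = 128
    width: int = 128
    cells_per_class: int = 1
    overlap_fraction: float = 0.2
    noise_sigma: float = 4.0
    illumination_gradient: float = 0.15
    rois_per_class: int = 40
    roi_size: int = 64

    def __post_init__(self):
        if self.n_smears < 2:
            raise ValueError("synth.n_smears must be >= 2")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("synth.overlap_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class UNetSettings:
    width_divisor: int = 8
    max_epochs: int = 4
    batch_size: int = 8
    lr: float = 1e-3
    l2: float = 1e-4
    tau: float = 0.5
    activation: str = "relu"  # 'gelu' available as a rejected-ablation toggle
    loss: str = "bce"  # 'bce_dice' available as a rejected-ablation toggle

    def __post_init__(self):
        if not 0.0 < self.tau < 1.0:
            raise ValueError("unet.tau must lie strictly inside (0, 1)")
        if self.lr <= 0:
            raise ValueError("unet.lr must be positive")


@dataclass(frozen=True)
class LWCNNSettings:
    folds: int = 2
    max_epochs: int = 8
    batch_size: int = 16
    lr: float = 1e-3
    dropout_conv: float = 0.25
    dropout_dense: float = 0.5

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("lwcnn.folds must be >= 2")
        if not 0.0 <= self.dropout_conv < 1.0 or not 0.0 <= self.dropout_dense < 1.0:
            raise ValueError("lwcnn dropout rates must lie in [0, 1)")


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    toggles: Toggles = field(default_factory=Toggles)
    clahe: ClaheParams = field(default_factory=ClaheParams)
    watershed: WatershedParams = field(default_factory=WatershedParams)
    synth: SynthSettings = field(default_factory=SynthSettings)
    unet: UNetSettings = field(default_factory=UNetSettings)
    lwcnn: LWCNNSettings = field(default_factory=LWCNNSettings)


_SECTIONS = {
    "toggles": Toggles,
    "clahe": ClaheParams,
    "watershed": WatershedParams,
    "synth": SynthSettings,
    "unet": UNetSettings,
    "lwcnn": LWCNNSettings,
}


def _build_section(name: str, cls, data: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)} in section {name!r}")
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list):
            v = tuple(v)
        coerced[f.name] = v
    try:
        return cls(**coerced)
    except (ValueError, TypeError) as e:
        raise ValueError(f"invalid value in config section {name!r}: {e}") from e


def validate_config(data: dict | None) -> PipelineConfig:
    """Build a config from a (possibly empty) mapping, filling defaults."""
    data = dict(data or {})
    unknown = set(data) - (set(_SECTIONS) | {"seed"})
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
    kwargs = {}
    if "seed" in data:
        if not isinstance(data["seed"], int):
            raise ValueError("seed must be an integer")
        kwargs["seed"] = data["seed"]
    for name, cls in _SECTIONS.items():
        if name in data:
            section = data[name] or {}
            if not isinstance(section, dict):
                raise ValueError(f"config section {name!r} must be a mapping")
            kwargs[name] = _build_section(name, cls, section)
    return PipelineConfig(**kwargs)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config file; an empty or missing body yields defaults."""
    if path is None:
        return PipelineConfig()
    text = Path(path).read_text()
    return validate_config(yaml.safe_load(text) or {})


def dump_config(cfg: PipelineConfig) -> str:
    """Serialize a config to YAML that round-trips via load_config."""
    def as_plain(obj):
        if dataclasses.is_dataclass(obj):
            return {k: as_plain(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return list(obj)
        if isinstance(obj, dict):
            return {k: as_plain(v) for k, v in obj.items()}
        return obj

    return yaml.safe_dump(as_plain(cfg), sort_keys=False)
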
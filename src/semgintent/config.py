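"""Configuration objects for the whole pipeline.

Every stage of the pipeline is driven by a small frozen dataclass.  YAML
configs mirror the field names one-to-one; unknown keys are rejected so a
typo (e.g. ``plable``) fails loudly instead of silently using a default.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

#: The 17 locomotion classes, indexed by integer label 1..17.
MOTION_CLASS_NAMES: dict[int, str] = {
    1: "Sitting",
    2: "Standing",
    3: "Walking",
    4: "Turn around axes",
    5: "Ascending stairs",
    6: "Descending stairs",
    7: "Ascending a ramp",
    8: "Descending a ramp",
    9: "Walking on uneven terrain",
    10: "Diagonal step in front left",
    11: "Diagonal step in front right",
    12: "Diagonal step backwards right",
    13: "Diagonal step backwards left",
    14: "Small steps in front",
    15: "Small steps to the right",
    16: "Small steps backwards",
    17: "Small steps to the left",
}

FUSION_VARIANTS = (
    "baseline",
    "ifia_full",
    "no_channel_attention",
    "no_cross_interaction",
    "no_temporal_compression",
    "data_level",
    "feature_level",
    "decision_level",
)


@dataclass(frozen=True)
class WindowingConfig:
    """Sliding-window segmentation and look-ahead labeling parameters.

    ``plabel_ms`` is the prediction time: the label of a window is taken from
    the motion event active ``plabel_ms`` after the window ends, so the
    classifier learns to anticipate the upcoming motion rather than describe
    the current one.
    """

    window_ms: int = 1200
    step_ms: int = 200
    plabel_ms: int = 100
    fs: int = 1000

    def __post_init__(self) -> None:
        if self.window_ms <= 0 or self.step_ms <= 0:
            raise ValueError("window_ms and step_ms must be positive")
        if self.plabel_ms < 0:
            raise ValueError("plabel_ms must be >= 0")
        if (self.window_ms * self.fs) % 1000:
            raise ValueError("window_ms must map to an integer sample count")

    @property
    def window_samples(self) -> int:
        return self.window_ms * self.fs // 1000


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyper-parameters of the CNN-TCN encoder/decoder."""

    n_channels: int = 8          # muscle channels
    n_scales: int = 30           # CWT bands
    window_samples: int = 1200
    spectrum_bins: int = 601
    n_classes: int = 17
    per_band_kernel: int = 3     # along time
    pool_size: int = 4
    agg_out_channels: int = 16
    leaky_slope: float = 0.01
    tcn_kernel: int = 3
    tcn_dilations: tuple[int, ...] = (1, 2, 4)
    tcn_channels: tuple[int, ...] = (128, 256, 128)
    embed_dim: int = 32
    dropout_p: float = 0.3
    fusion_mode: str = "baseline"

    def __post_init__(self) -> None:
        if self.fusion_mode not in FUSION_VARIANTS:
            raise ValueError(
                f"unknown fusion_mode {self.fusion_mode!r}; "
                f"expected one of {FUSION_VARIANTS}"
            )
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        d = self.tcn_dilations
        if any(b <= a for a, b in zip(d, d[1:])) or any(
            x & (x - 1) for x in d
        ):
            raise ValueError("tcn_dilations must be strictly increasing powers of 2")
        if len(self.tcn_channels) != len(self.tcn_dilations):
            raise ValueError("tcn_channels and tcn_dilations must align")

    @property
    def seq_len(self) -> int:
        # Table-2 ladder: 1200 -> three conv+pool stages -> 18 -> agg conv -> 16
        t = self.window_samples
        for _ in range(3):
            t = (t - self.per_band_kernel + 1 - self.pool_size) // self.pool_size + 1
        return t - self.per_band_kernel + 1

    @property
    def seq_features(self) -> int:
        return self.agg_out_channels * self.n_channels


@dataclass(frozen=True)
class IFIAConfig:
    """Frequency-informed integration attention hyper-parameters.

    ``r`` is the squeeze-style reduction ratio of the gating MLP: hidden
    width = floor(input_width / r).  ``d_model`` / ``n_heads`` size the
    cross-domain multi-head attention over 30-dim band tokens.
    """

    r: int = 4
    n_heads: int = 2
    d_model: int = 64

    def __post_init__(self) -> None:
        if self.r < 1:
            raise ValueError("reduction ratio r must be >= 1")
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol (AdamW + plateau scheduler + early stopping)."""

    batch_size: int = 128
    epochs: int = 100
    lr: float = 0.003
    betas: tuple[float, float] = (0.9, 0.999)
    weight_decay: float = 0.0001
    scheduler_factor: float = 0.5
    scheduler_patience: int = 5
    early_stop_patience: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr < 0:
            raise ValueError("lr must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass(frozen=True)
class DatasetConfig:
    """Synthetic dataset layout (subjects x trials over a class subset)."""

    n_subjects: int = 1
    trials_per_subject: int = 10
    classes: tuple[int, ...] = (1, 2, 3, 5, 14)
    trial_duration_s: float = 20.0

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("classes must be non-empty")
        bad = [c for c in self.classes if c not in MOTION_CLASS_NAMES]
        if bad:
            raise ValueError(f"unknown class labels {bad}; valid labels are 1..17")


@dataclass(frozen=True)
class RunConfig:
    """Top-level config for CLI runs: one sub-config per pipeline stage."""

    seed: int = 0
    dataset: DatasetConfig = field(default_factory=DatasetConfig)
    windowing: WindowingConfig = field(default_factory=WindowingConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    ifia: IFIAConfig = field(default_factory=IFIAConfig)
    training: TrainConfig = field(default_factory=TrainConfig)


_TUPLE_FIELDS = {"tcn_dilations", "tcn_channels", "betas", "classes"}


def _build(cls: type, data: Mapping[str, Any], path: str = "") -> Any:
    if not isinstance(data, Mapping):
        raise ValueError(f"config section {path or cls.__name__!r} must be a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(
            f"unknown config key(s) {sorted(unknown)} at {path or 'top level'}; "
            f"valid keys: {sorted(fields)}"
        )
    kwargs: dict[str, Any] = {}
    for name, value in data.items():
        ftype = fields[name].type
        if dataclasses.is_dataclass(_SECTIONS.get(name)) and isinstance(value, Mapping):
            kwargs[name] = _build(_SECTIONS[name], value, f"{path}{name}.")
        elif name in _TUPLE_FIELDS and isinstance(value, (list, tuple)):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
        del ftype
    return cls(**kwargs)


_SECTIONS: dict[str, type] = {
    "dataset": DatasetConfig,
    "windowing": WindowingConfig,
    "model": ModelConfig,
    "ifia": IFIAConfig,
    "training": TrainConfig,
}


def run_config_from_dict(data: Mapping[str, Any]) -> RunConfig:
    return _build(RunConfig, data)


def load_run_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run config; unknown keys are errors."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return run_config_from_dict(data)


def config_to_dict(cfg: Any) -> dict[str, Any]:
    def _convert(obj: Any) -> Any:
        if dataclasses.is_dataclass(obj):
            return {f.name: _convert(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    return _convert(cfg)


def save_run_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


def config_json(cfg: Any) -> str:
    return json.dumps(config_to_dict(cfg), sort_keys=True)
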
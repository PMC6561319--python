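"""Single-document YAML configuration for the whole pipeline."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields

import yaml

from .lfq_stats import ImputeConfig, TestConfig
from .synthetic_data import SimConfig
from .tf_inference import TFModelConfig

__all__ = ["PipelineConfig", "load_config", "dump_config"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs; serializes to/from one YAML document.

    Stage toggles select which of simulate / diff / tf / network run;
    when ``simulate`` is off, ``intensities_path``/``design_path`` (and
    ``connectivity_path`` if the tf stage is on) must point at inputs.
    """

    seed: int = 0
    out_dir: str = "results"
    log_level: str = "INFO"
    run_simulate: bool = True
    run_diff: bool = True
    run_tf: bool = True
    run_network: bool = True
    normalization_mode: str = "sample"
    intensities_path: str | None = None
    design_path: str | None = None
    connectivity_path: str | None = None
    sim: SimConfig = field(default_factory=SimConfig)
    test: TestConfig = field(default_factory=TestConfig)
    impute: ImputeConfig = field(default_factory=ImputeConfig)
    tf: TFModelConfig = field(default_factory=TFModelConfig)

    def validate(self) -> None:
        if not self.run_simulate:
            if self.run_diff and (self.intensities_path is None or self.design_path is None):
                raise ValueError(
                    "diff stage without simulation requires intensities_path and design_path"
                )
            if self.run_tf and self.connectivity_path is None:
                raise ValueError("tf stage without simulation requires connectivity_path")
        if self.normalization_mode not in ("sample", "group"):
            raise ValueError("normalization_mode must be 'sample' or 'group'")


_SUBCONFIGS = {"sim": SimConfig, "test": TestConfig, "impute": ImputeConfig, "tf": TFModelConfig}


def _build(cls, data: dict):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    kwargs = {}
    for key, value in raw.items():
        if key in _SUBCONFIGS:
            if not isinstance(value, dict):
                raise ValueError(f"config section {key!r} must be a mapping")
            kwargs[key] = _build(_SUBCONFIGS[key], value)
        else:
            kwargs[key] = value
    cfg = _build(PipelineConfig, kwargs)
    cfg.validate()
    return cfg


def dump_config(config: PipelineConfig, path) -> None:
    def as_dict(obj):
        return {f.name: getattr(obj, f.name) for f in fields(obj)}

    doc = as_dict(config)
    for key in _SUBCONFIGS:
        doc[key] = dataclasses.asdict(doc[key])
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
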
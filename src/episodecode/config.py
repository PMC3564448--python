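"""Run configuration: one YAML document drives simulation and analysis."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields as dc_fields
from pathlib import Path

import yaml

from .taskmodel import TrackingParams, TuningParams, DEFAULT_BLOCKS


class ConfigError(ValueError):
    pass


@dataclass
class AnalysisParams:
    immobility_cms: float = 5.0
    si_threshold: float = 1.0
    similarity_method: str = "spearman"
    n_shuffles: int = 1000
    alpha: float = 0.05
    n_ratemap_cells: int = 3  # per-cell rate-map CSVs exported for the report


@dataclass
class RunConfig:
    seed: int = 0
    blocks: list = field(default_factory=lambda: [list(b) for b in DEFAULT_BLOCKS])
    error_rate: float = 0.0
    tracking: TrackingParams = field(default_factory=TrackingParams)
    tuning: TuningParams = field(default_factory=TuningParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)

    def to_dict(self):
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        kwargs = {}
        for name, sub_cls in (("tracking", TrackingParams),
                              ("tuning", TuningParams),
                              ("analysis", AnalysisParams)):
            sub = data.pop(name, {})
            if not isinstance(sub, dict):
                raise ConfigError(f"section {name!r} must be a mapping")
            known = {f.name for f in dc_fields(sub_cls)}
            bad = set(sub) - known
            if bad:
                raise ConfigError(f"unknown keys in {name!r}: {sorted(bad)}")
            if "peak_range" in sub:
                sub["peak_range"] = tuple(sub["peak_range"])
            kwargs[name] = sub_cls(**sub)
        top = {f.name for f in dc_fields(cls)} - {"tracking", "tuning", "analysis"}
        bad = set(data) - top
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        blocks = data.pop("blocks", None)
        if blocks is not None:
            kwargs["blocks"] = [[str(s), int(n)] for s, n in blocks]
        return cls(**{**data, **kwargs})

    @classmethod
    def load(cls, path) -> "RunConfig":
        try:
            with open(path) as fh:
                data = yaml.safe_load(fh)
        except yaml.YAMLError as e:
            raise ConfigError(f"malformed YAML in {path}: {e}") from e
        if data is not None and not isinstance(data, dict):
            raise ConfigError(f"{path} must contain a YAML mapping")
        return cls.from_dict(data or {})

    def save(self, path):
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
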
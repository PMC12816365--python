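"""Device configuration: one YAML/JSON file describing the whole build.

The defaults reproduce the reference prototype exactly (as-printed
27.8/9.8 mm Venturi bores, MPX5010-class sensor, 4.7k/10k divider,
12-bit 3.3 V ADC, 1 kHz x 10,000-sample captures).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .acquisition_model import AcquisitionConfig, AdcSpec, DividerSpec, SensorSpec
from .breath_pipeline import PipelineConfig
from .venturi_core import FluidProperties, TubeGeometry

__all__ = ["DeviceConfig", "load_config", "save_config"]


@dataclass
class DeviceConfig:
    """Complete description of one device build plus processing settings."""

    tube: TubeGeometry = field(default_factory=TubeGeometry)
    fluid: FluidProperties = field(default_factory=FluidProperties)
    sensor: SensorSpec = field(default_factory=SensorSpec)
    divider: DividerSpec = field(default_factory=DividerSpec)
    adc: AdcSpec = field(default_factory=AdcSpec)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)

    def to_dict(self) -> dict:
        return {
            name: dataclasses.asdict(getattr(self, name))
            for name in (
                "tube",
                "fluid",
                "sensor",
                "divider",
                "adc",
                "acquisition",
                "pipeline",
            )
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DeviceConfig":
        sections = {
            "tube": TubeGeometry,
            "fluid": FluidProperties,
            "sensor": SensorSpec,
            "divider": DividerSpec,
            "adc": AdcSpec,
            "acquisition": AcquisitionConfig,
            "pipeline": PipelineConfig,
        }
        kwargs = {}
        unknown = set(d) - set(sections)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        for name, klass in sections.items():
            payload = d.get(name, {})
            valid = {f.name for f in dataclasses.fields(klass)}
            bad = set(payload) - valid
            if bad:
                raise ValueError(f"unknown keys in '{name}': {sorted(bad)}")
            kwargs[name] = klass(**payload)
        return cls(**kwargs)

    @property
    def config_hash(self) -> str:
        """Short stable digest of the full configuration, for run logs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path) -> DeviceConfig:
    """Load a device config from YAML or JSON (by file extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        data = json.loads(text)
    else:
        # note: YAML 1.1 parses bare "1e-05" as a string, so JSON files
        # must go through the json loader above
        data = yaml.safe_load(text)
    if data is None:
        return DeviceConfig()
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return DeviceConfig.from_dict(data)


def save_config(path, cfg: DeviceConfig) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(cfg.to_dict(), indent=2))
    else:
        path.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
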
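"""Configuration files for the simulation pipeline.

A config is a JSON (or YAML, if PyYAML is available) document with any
of the sections ``display``, ``observer``, ``staircase``, ``fit`` and
``experiment``; omitted fields take the package defaults.  Example::

    {
      "display":   {"frame_rate": 75, "arcmin_per_pixel": 1.05},
      "observer":  {"strategy": "super_resolution", "noise_sd": 6.0},
      "staircase": {"max_trials": 50, "max_reversals": 8},
      "fit":       {"n_boot": 1000},
      "experiment": {"experiment": 1, "n_subjects": 8, "n_runs": 10, "seed": 0}
    }
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .display import DisplayModel
from .errors import ConfigurationError
from .experiment import ExperimentConfig
from .observer import ObserverParams

_SECTIONS = {"display", "observer", "staircase", "fit", "experiment"}


@dataclass
class PipelineConfig:
    display: DisplayModel = field(default_factory=DisplayModel)
    observer: ObserverParams = field(default_factory=ObserverParams)
    staircase: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    experiment: ExperimentConfig | None = None


def _load_raw(path: Path) -> dict:
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        try:
            import yaml
        except ImportError as exc:  # pragma: no cover
            raise ConfigurationError("PyYAML needed for YAML configs") from exc
        return yaml.safe_load(text)
    return json.loads(text)


def load_config(path) -> PipelineConfig:
    """Parse a pipeline config file into typed sections."""
    path = Path(path)
    raw = _load_raw(path)
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    unknown = set(raw) - _SECTIONS
    if unknown:
        raise ConfigurationError(f"unknown config sections: {sorted(unknown)}")
    cfg = PipelineConfig()
    if "display" in raw:
        disp = dict(raw["display"])
        for key in ("canvas_center", "canvas_extent"):
            if key in disp:
                disp[key] = tuple(disp[key])
        cfg.display = DisplayModel(**disp)
    if "observer" in raw:
        cfg.observer = ObserverParams(**raw["observer"])
    cfg.staircase = dict(raw.get("staircase", {}))
    cfg.fit = dict(raw.get("fit", {}))
    if "experiment" in raw:
        cfg.experiment = ExperimentConfig(observer=cfg.observer,
                                          **raw["experiment"])
    return cfg
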
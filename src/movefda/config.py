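"""Analysis-wide configuration.

Defaults follow the workflow's standard parameterization: 60-minute refined
grid, 0.25 m/s rest cutoff, 1800 m cooccurrence threshold, 48 h LMI window
radius.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .exceptions import ConfigurationError


@dataclass(frozen=True)
class AnalysisConfig:
    epoch: str | None = None                 # calendar date of study time 0
    grid_resolution_min: float = 60.0
    rest_cutoff_mps: float = 0.25
    delta_m: float = 1800.0
    lmi_window_hours: float = 48.0
    knot_quantile: float = 0.05
    knot_min_spacing_hours: float = 2.0
    lambda_grid: tuple = tuple(float(x) for x in
                               (10.0 ** e for e in
                                [i * 0.5 - 8 for i in range(25)]))
    gcv_denominator: str = "squared"
    equal_lambda: bool = False
    mi_estimator: str = "histogram"
    mi_bins: int | None = None
    mi_min_samples: int = 10
    time_density_bandwidth: object = "auto"
    rest_bandwidth: object = "auto"
    cooccurrence_bandwidth: object = "auto"
    scale_policy: str = "pointwise-max"
    scale_method: str = "arc"
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lambda_grid"] = list(d["lambda_grid"])
        return d

    def config_hash(self) -> str:
        """Stable hash of the configuration for run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        """Load from a JSON or YAML file."""
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} must hold a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "lambda_grid" in data:
            data["lambda_grid"] = tuple(float(x) for x in data["lambda_grid"])
        return cls(**data)
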
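"""Run configuration: YAML-backed parameters for the end-to-end pipeline."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


_DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "px_size_um": 2.0,
    "output_dir": "micropat_out",
    "input_image": None,
    "channel_names": None,
    "channel_map": {"nuclei": "nuclei", "reporter": "reporter", "ligand": "ligand"},
    "pattern": {
        "type": "square_array",
        "side_um": 500.0,
        "interspace_um": 1000.0,
        "width_um": 500.0,
        "orientation": "horizontal",
        "bitmap": None,
        "threshold": 128,
        "field_um": [3000.0, 3000.0],
    },
    "simulate": {
        "density_per_mm2": 800.0,
        "min_spacing_um": 10.0,
        "cell_radius_um": 8.0,
        "dose_ug_ml": 100.0,
        "p_max": 0.9,
        "K_ug_ml": 30.0,
        "h": 2.0,
        "p_basal": 0.05,
        "psf_sigma_um": 1.0,
        "noise_sd": 0.0,
        "on_intensity": 200.0,
        "off_intensity": 10.0,
        "lognorm_sigma": 0.0,
    },
    "segment": {
        "blur_sigma": 2.0,
        "threshold_method": "otsu",
        "min_area_px": 4,
        "watershed": True,
    },
    "quantify": {"positive_threshold": 50.0},
    "fidelity": {"n_scrambles": 100},
    "orient": {"tensor_sigma": 2.0, "weight": "none", "channel": "reporter"},
    "myo": {
        "actinin_channel": "actinin",
        "min_size_px": 200,
        "threshold": "otsu",
    },
    "dose": {"csv": None},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclass
class RunConfig:
    """All pipeline parameters, with recorded defaults and a stable hash."""

    data: dict[str, Any] = field(default_factory=lambda: json.loads(json.dumps(_DEFAULTS)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        return cls(_merge(json.loads(json.dumps(_DEFAULTS)), user))

    @classmethod
    def from_dict(cls, user: dict) -> "RunConfig":
        return cls(_merge(json.loads(json.dumps(_DEFAULTS)), user))

    def __getitem__(self, key: str) -> Any:
        return self.data[key]

    def get(self, key: str, default: Any = None) -> Any:
        return self.data.get(key, default)

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    @property
    def px_size_um(self) -> float:
        return float(self.data["px_size_um"])

    @property
    def output_dir(self) -> Path:
        return Path(self.data["output_dir"])

    def config_hash(self) -> str:
        """Stable short hash of the scientific parameters, for provenance columns.

        The output directory is excluded: two runs of the same analysis into
        different folders share a hash (and must produce identical tables).
        """
        data = {k: v for k, v in self.data.items() if k != "output_dir"}
        blob = json.dumps(data, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def validate(self, require_input: bool = False) -> None:
        d = self.data
        if d["px_size_um"] <= 0:
            raise ConfigError("px_size_um must be positive")
        if d["fidelity"]["n_scrambles"] < 1:
            raise ConfigError("fidelity.n_scrambles must be >= 1")
        pt = d["pattern"]["type"]
        if pt not in ("square_array", "rows", "bitmap"):
            raise ConfigError(f"unknown pattern.type {pt!r}")
        if pt == "bitmap" and not d["pattern"]["bitmap"]:
            raise ConfigError("pattern.type bitmap requires pattern.bitmap path")
        if require_input and not d["input_image"]:
            raise ConfigError("input_image is required for this stage")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.data, fh, sort_keys=False)
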
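"""Run configuration: YAML round-trip with strict schema checking.

A :class:`RunConfig` bundles the defaults of every stage (scene synthesis,
tiling, LBP, regression, evaluation strata) plus paths, seed and verbosity.
Unknown keys are rejected with their full key path; omitted keys fall back
to defaults.  The effective configuration of a run is always written next to
its outputs so any artifact can be re-created exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import os
from dataclasses import dataclass, field

import yaml

from .detection import TileSpec
from .regression import RegressionConfig
from .synthetic import SceneParams
from .texture import LBPConfig


@dataclass
class RunConfig:
    data_dir: str = "data"
    artifact_dir: str = "artifacts"
    output_dir: str = "out"
    scene: SceneParams = field(default_factory=SceneParams)
    tiles: TileSpec = field(default_factory=TileSpec)
    lbp: LBPConfig = field(default_factory=LBPConfig)
    regression: RegressionConfig = field(default_factory=RegressionConfig)
    strata: tuple[float, float] = (3.0, 5.0)
    seed: int = 0
    verbosity: str = "info"


_NESTED = {"scene": SceneParams, "tiles": TileSpec, "lbp": LBPConfig,
           "regression": RegressionConfig}
_TUPLE_KEYS = {"strata", "mlp_hidden"}


def _build(cls, data: dict, path: str = "") -> object:
    names = {f.name for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        full = f"{path}{key}"
        if key not in names:
            raise ValueError(f"unknown config key {full!r}")
        if key in _NESTED and path == "":
            if not isinstance(value, dict):
                raise ValueError(f"config key {full!r} must be a mapping")
            kwargs[key] = _build(_NESTED[key], value, path=f"{full}.")
        elif key in _TUPLE_KEYS:
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config under {path or 'root'}: {exc}")


def load_config(path: str) -> RunConfig:
    """Parse a YAML config; defaults fill omitted keys, unknown keys error."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    return _build(RunConfig, data)  # type: ignore[return-value]


def config_to_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    for key in ("strata",):
        d[key] = list(d[key])
    d["regression"]["mlp_hidden"] = list(d["regression"]["mlp_hidden"])
    return d


def save_config(cfg: RunConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)


def config_hash(cfg: RunConfig) -> str:
    blob = yaml.safe_dump(config_to_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_effective_config(cfg: RunConfig, out_dir: str) -> str:
    """Persist the effective config (and its hash) next to a run's outputs."""
    os.makedirs(out_dir, exist_ok=True)
    path = os.path.join(out_dir, "effective_config.yaml")
    save_config(cfg, path)
    return path
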
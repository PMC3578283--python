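"""Run configuration: YAML round-trip with validation.

Defaults match the headline setting used throughout the analysis
(U_se = 0.1, b = 0.2, p = 3, N = 10^4, tau_R = 4, tau_F = 2, T = 1.0).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any, Optional

import yaml

from .params import ModelParams

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Model parameters plus command-level options."""

    params: ModelParams = field(default_factory=ModelParams)
    seed: int = 0
    steps: int = 1000
    init: str = "random"
    out_dir: str = "."
    schema_version: int = SCHEMA_VERSION

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["params"] = asdict(self.params)
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _coerce(value: Any, typ: type) -> Any:
    return typ(value) if typ in (int, float, str) else value


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config; unknown keys are rejected by name."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    return config_from_dict(raw)


def config_from_dict(raw: dict[str, Any]) -> RunConfig:
    raw = dict(raw)
    param_fields = {f.name: f for f in fields(ModelParams)}
    run_fields = {f.name: f for f in fields(RunConfig) if f.name != "params"}

    params_raw = raw.pop("params", {}) or {}
    unknown = [k for k in params_raw if k not in param_fields]
    unknown += [k for k in raw if k not in run_fields]
    if unknown:
        raise ValueError(
            "unknown config keys: " + ", ".join(sorted(unknown))
            + f"; allowed: params.{{{', '.join(sorted(param_fields))}}}, "
            + ", ".join(sorted(run_fields))
        )
    try:
        params = ModelParams(**{
            k: _coerce(v, type(param_fields[k].default)) for k, v in params_raw.items()
        })
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid model parameters: {exc}") from exc
    return RunConfig(params=params, **raw)
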
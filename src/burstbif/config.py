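"""Run configuration: flag/file parsing, validation, and provenance.

A run is specified by the model parameters plus method/grid/seed settings,
either as command-line flags or as a YAML/JSON file with the same keys
(flags override the file).  Every writer emits a '#'-prefixed provenance
block so results are self-describing and reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .model_core import SchloglParams

__all__ = ["RunConfig", "load_config", "provenance_lines"]

_PARAM_KEYS = {"k1", "k2", "k3", "k4", "r"}
_SETTING_KEYS = {
    "method", "x_max", "grid_step", "x0", "t_max", "seed",
    "burn_in", "out", "ktilde",
}


@dataclass(frozen=True)
class RunConfig:
    """Validated parameters and method settings for one invocation."""

    params: SchloglParams
    method: str | None = None
    x_max: float | None = None
    grid_step: float = 0.05
    x0: int | None = None
    t_max: float | None = None
    seed: int = 0
    burn_in: float = 0.1
    out: str | None = None

    def as_dict(self) -> dict:
        d = self.params.as_dict()
        for k in ("method", "x_max", "grid_step", "x0", "t_max", "seed", "burn_in", "out"):
            v = getattr(self, k)
            if v is not None:
                d[k] = v
        return d


def load_config(path: str | Path | None = None, **flags) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML/JSON file and/or flags.

    Flag values (non-None) override file values.  ``ktilde=True`` marks the
    rates as reduced parameters, forcing k4 = 1.  Unknown keys and invalid
    values raise ``ValueError`` with the violated constraint named.
    """
    data: dict = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            data = yaml.safe_load(text) or {}
        elif path.suffix == ".json":
            data = json.loads(text)
        else:  # sniff: YAML is a superset of JSON for our purposes
            data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config {path} must contain a mapping")

    unknown = set(data) - _PARAM_KEYS - _SETTING_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    merged = dict(data)
    for k, v in flags.items():
        if k not in _PARAM_KEYS | _SETTING_KEYS:
            raise ValueError(f"unknown setting {k!r}")
        if v is not None:
            merged[k] = v

    ktilde = bool(merged.pop("ktilde", False))
    missing = [k for k in ("k1", "k2", "k3") if k not in merged]
    if missing:
        raise ValueError(f"missing required rate constants: {missing}")
    if ktilde and merged.get("k4", 1.0) not in (None, 1.0, 1):
        raise ValueError("reduced parameters (ktilde) imply k4 = 1")

    r = merged.get("r", 1)
    if (isinstance(r, float) and not r.is_integer()) or int(r) < 1:
        raise ValueError(f"burst size r must be an integer >= 1, got {r!r}")

    params = SchloglParams(
        k1=float(merged["k1"]), k2=float(merged["k2"]), k3=float(merged["k3"]),
        k4=1.0 if ktilde else float(merged.get("k4", 1.0)), r=int(r),
    )
    bi = float(merged.get("burn_in", 0.1))
    if not 0.0 <= bi < 1.0:
        raise ValueError(f"burn_in must be in [0, 1), got {bi}")
    return RunConfig(
        params=params,
        method=merged.get("method"),
        x_max=None if merged.get("x_max") is None else float(merged["x_max"]),
        grid_step=float(merged.get("grid_step", 0.05)),
        x0=None if merged.get("x0") is None else int(merged["x0"]),
        t_max=None if merged.get("t_max") is None else float(merged["t_max"]),
        seed=int(merged.get("seed", 0)),
        burn_in=bi,
        out=merged.get("out"),
    )


def provenance_lines(cfg_or_params, extra: dict | None = None) -> list[str]:
    """'#'-prefixed comment lines recording parameters, seed and version."""
    if isinstance(cfg_or_params, RunConfig):
        d = cfg_or_params.as_dict()
    elif isinstance(cfg_or_params, SchloglParams):
        d = cfg_or_params.as_dict()
    else:
        d = dict(cfg_or_params)
    if extra:
        d.update(extra)
    body = json.dumps(d, sort_keys=True, default=str)
    return [f"# burstbif v{__version__}", f"# {body}"]
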
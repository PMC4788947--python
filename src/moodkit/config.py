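"""Structured run configuration (YAML) with full up-front validation.

An empty file (or no file) yields the characterized defaults everywhere:
Table-style fixed kinetic constants, the wet-lab decision ranges, the
default stimulus protocol, pertinency box, optimizer settings, guideline
settings and load parameters. Unknown keys are rejected so typos fail
loudly before a multi-hour run.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator

from .errors import ConfigError
from .model import (
    BOUNDS,
    CircuitParameters,
    LoadParameters,
    StimulusProtocol,
)
from .objectives import PertinencyBox
from .optimize import MOOConfig

__all__ = ["RunConfig", "load_config", "save_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ProtocolConfig(_Strict):
    equilibration: float = 5000.0
    t0: float = 0.0
    tf: float = 300.0
    Ie_step: float = 1000.0


class BoxConfig(_Strict):
    j1: tuple[float, float] = (1e-3, 200.0)
    j2: tuple[float, float] = (1e-4, 20.0)
    p: tuple[float, float] = (1.0, 1e4)


class MOOSection(_Strict):
    population: int = 50
    F: float = 0.5
    CR: float = 0.9
    max_evals: int = 15000
    sectors: int = 33


class GuidelineSection(_Strict):
    alpha: float = 0.05
    shrink_threshold: float = 0.6
    k_min: int = 2
    k_max: int = 10

    @field_validator("alpha")
    @classmethod
    def _alpha_range(cls, v: float) -> float:
        if not 0 < v < 1:
            raise ValueError("alpha must be in (0, 1)")
        return v


class LoadSection(_Strict):
    K1: float = 40.0
    K2: float = 20.0
    LT: float = 800.0


class SolverSection(_Strict):
    rtol: float = 1e-8
    atol: float = 1e-10


class SweepSection(_Strict):
    num: int = 20                  # default grid resolution (log-spaced)
    dominance_margin: float = 0.05  # normalized-objective margin for "on-front"


class RunConfig(_Strict):
    """Validated settings for a full design run."""

    parameters: dict[str, float] = {}
    bounds: dict[str, tuple[float, float]] = {}
    protocol: ProtocolConfig = ProtocolConfig()
    box: BoxConfig = BoxConfig()
    moo: MOOSection = MOOSection()
    guidelines: GuidelineSection = GuidelineSection()
    load: LoadSection = LoadSection()
    solver: SolverSection = SolverSection()
    sweep: SweepSection = SweepSection()
    tie_kmA: bool = True
    output_dir: str = "results"
    seed: int = 0

    @field_validator("parameters")
    @classmethod
    def _check_parameters(cls, v: dict[str, float]) -> dict[str, float]:
        valid = {f for f in CircuitParameters.__dataclass_fields__}
        unknown = set(v) - valid
        if unknown:
            raise ValueError(f"unknown kinetic parameters: {sorted(unknown)}")
        return v

    @field_validator("bounds")
    @classmethod
    def _check_bounds(cls, v: dict) -> dict:
        for name, pair in v.items():
            if name not in BOUNDS:
                raise ValueError(f"unknown decision variable {name!r}")
            lo, hi = pair
            if not lo < hi:
                raise ValueError(f"bounds for {name}: lower {lo} must be < upper {hi}")
            wlo, whi = BOUNDS[name]
            if not (wlo <= lo and hi <= whi):
                raise ValueError(
                    f"bounds for {name} must lie within [{wlo}, {whi}]"
                )
        return v

    # ---- domain-object builders -------------------------------------
    def base_params(self) -> CircuitParameters:
        try:
            return CircuitParameters(**self.parameters)
        except Exception as exc:  # invariant violations surface as ConfigError
            raise ConfigError(str(exc)) from exc

    def protocol_obj(self) -> StimulusProtocol:
        return StimulusProtocol(**self.protocol.model_dump())

    def box_obj(self) -> PertinencyBox:
        b = self.box
        return PertinencyBox(j1=tuple(b.j1), j2=tuple(b.j2), p=tuple(b.p))

    def moo_config(self, seed: Optional[int] = None) -> MOOConfig:
        return MOOConfig(
            seed=self.seed if seed is None else seed,
            box=None,  # the problem applies the box itself
            **self.moo.model_dump(),
        )

    def load_obj(self) -> LoadParameters:
        return LoadParameters(**self.load.model_dump())

    def bounds_dict(self) -> dict[str, tuple[float, float]]:
        merged = dict(BOUNDS)
        merged.update({k: tuple(v) for k, v in self.bounds.items()})
        return merged

    def config_hash(self) -> str:
        """Stable hash of every setting (changes iff a setting changes)."""
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: Optional[str | Path] = None) -> RunConfig:
    """Read and validate a YAML run configuration.

    ``None`` or an empty file produce the full default configuration.
    Malformed YAML, unknown keys and inconsistent values raise
    :class:`ConfigError` with the offending field named.
    """
    if path is None:
        return RunConfig()
    raw = Path(path).read_text()
    try:
        data = yaml.safe_load(raw)
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
    if data is None:
        return RunConfig()
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    try:
        cfg = RunConfig(**data)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc
    # eagerly validate the derived domain objects too
    cfg.base_params()
    cfg.protocol_obj()
    cfg.box_obj()
    cfg.moo_config()
    cfg.load_obj()
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a configuration back to YAML (round-trips through load_config)."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.model_dump(mode="json"), fh, sort_keys=True)
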
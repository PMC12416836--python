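"""Simulation configuration: JSON schema, validation, defaults.

A config is a JSON object with blocks ``model``, ``population``, ``drug``,
``event_detection`` and ``output`` plus a mandatory top-level ``seed``
(wall-clock seeding is deliberately impossible: every run must be
reproducible from its config alone).  Unknown keys anywhere are rejected
with a path-addressed message.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pydantic
from pydantic import BaseModel, ConfigDict, Field

from .drugs import DrugParams, builtin_drug
from .errors import ConfigurationError
from .events import PeakParams
from .model import MinimalModelParams
from .telegraph import TelegraphParams

__all__ = [
    "SimConfig",
    "validate_config",
    "load_config",
    "config_params",
    "config_drug",
    "config_peak_params",
    "config_hash",
]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TelegraphBlock(_Block):
    k_act: float = TelegraphParams.k_act
    k_inact: float = TelegraphParams.k_inact
    k_m: float = TelegraphParams.k_m
    gamma_m: float = TelegraphParams.gamma_m
    dt: float = TelegraphParams.dt


class ModelParamsBlock(_Block):
    T0: float = 24.0
    R: float = 0.1
    marker_centers: tuple[float, float, float] = (0.45, 0.70, 0.95)
    kappa: float = 10.0
    a_E: float = 0.5
    b_E: float = 0.5
    k_E: float = 0.2
    GF: float = 1.0
    drug_response: str = "linear"
    hill_h: float = 2.0
    hill_k: float = 0.5
    k_apop: float = 1.0
    s_tox: float = 0.0
    noise: bool = True
    telegraph: TelegraphBlock = Field(default_factory=TelegraphBlock)


class ModelBlock(_Block):
    name: str = "minimal"
    load_model: str | None = None
    run_model: str | None = None
    params: ModelParamsBlock = Field(default_factory=ModelParamsBlock)


class PopulationBlock(_Block):
    n_start: int = Field(default=100, ge=1)
    duration_h: float = Field(default=72.0, gt=0)
    replicates: int = Field(default=1, ge=1)
    heterogenize_h: float = Field(default=48.0, ge=0)
    gen0_h: float = Field(default=48.0, gt=0)
    shared_pools: bool = True


class CustomDrugBlock(_Block):
    name: str = "custom"
    k_transport: float = 0.01
    kon: float = 1e-3
    koff: float = 0.0
    irreversible: bool = False
    k_deg: float = 0.0
    target_total: float = 100.0


class DrugBlock(_Block):
    name: str | None = None
    custom: CustomDrugBlock | None = None
    dose_nM: float = Field(default=0.0, ge=0)
    doses_nM: list[float] | None = None
    start_time_h: float = 0.0


class EventBlock(_Block):
    min_prominence: float = 0.2
    min_separation_h: float | None = None  # defaults to 0.25 * T0
    min_height: float = 0.05
    death_threshold: float = 0.5


class OutputBlock(_Block):
    dir: str | None = None


class SimConfig(_Block):
    seed: int
    model: ModelBlock = Field(default_factory=ModelBlock)
    population: PopulationBlock = Field(default_factory=PopulationBlock)
    drug: DrugBlock | None = None
    event_detection: EventBlock = Field(default_factory=EventBlock)
    output: OutputBlock = Field(default_factory=OutputBlock)


def validate_config(raw: dict) -> SimConfig:
    """Validate a parsed JSON dict; fill defaults, reject unknown keys."""
    try:
        cfg = SimConfig.model_validate(raw)
    except pydantic.ValidationError as exc:
        lines = [
            f"  {'.'.join(str(p) for p in err['loc']) or '<root>'}: {err['msg']}"
            for err in exc.errors()
        ]
        raise ConfigurationError("invalid configuration:\n" + "\n".join(lines)) from None
    if cfg.drug is not None:
        if (cfg.drug.name is None) == (cfg.drug.custom is None):
            raise ConfigurationError(
                "drug: specify exactly one of 'name' (built-in) or 'custom'"
            )
        if cfg.drug.start_time_h != 0.0:
            raise ConfigurationError(
                "drug.start_time_h: drug addition defines t = 0; only 0.0 is supported"
            )
        if (cfg.drug.doses_nM is not None) and any(d < 0 for d in cfg.drug.doses_nM):
            raise ConfigurationError("drug.doses_nM: doses must be >= 0")
    return cfg


def load_config(path: str | Path) -> SimConfig:
    try:
        raw = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ConfigurationError(f"config is not valid JSON: {exc}") from exc
    return validate_config(raw)


def config_params(cfg: SimConfig) -> MinimalModelParams:
    p = cfg.model.params
    return MinimalModelParams(
        T0=p.T0,
        R=p.R,
        marker_centers=tuple(p.marker_centers),
        kappa=p.kappa,
        a_E=p.a_E,
        b_E=p.b_E,
        k_E=p.k_E,
        GF=p.GF,
        drug_response=p.drug_response,
        hill_h=p.hill_h,
        hill_k=p.hill_k,
        k_apop=p.k_apop,
        s_tox=p.s_tox,
        noise=p.noise,
        telegraph=TelegraphParams(
            k_act=p.telegraph.k_act,
            k_inact=p.telegraph.k_inact,
            k_m=p.telegraph.k_m,
            gamma_m=p.telegraph.gamma_m,
            dt=p.telegraph.dt,
        ),
    )


def config_drug(cfg: SimConfig, dose_nM: float | None = None) -> DrugParams | None:
    if cfg.drug is None:
        return None
    dose = cfg.drug.dose_nM if dose_nM is None else dose_nM
    if cfg.drug.name is not None:
        return builtin_drug(cfg.drug.name, dose)
    c = cfg.drug.custom
    return DrugParams(
        name=c.name,
        k_transport=c.k_transport,
        kon=c.kon,
        koff=c.koff,
        irreversible=c.irreversible,
        k_deg=c.k_deg,
        dose_ext=dose,
        target_total=c.target_total,
    )


def config_peak_params(cfg: SimConfig) -> PeakParams:
    e = cfg.event_detection
    sep = e.min_separation_h
    if sep is None:
        sep = 0.25 * cfg.model.params.T0
    return PeakParams(
        min_prominence=e.min_prominence,
        min_separation=sep,
        min_height=e.min_height,
    )


def config_hash(cfg: SimConfig) -> str:
    """Stable hash of the fully-defaulted config, for run logging."""
    canon = json.dumps(cfg.model_dump(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
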
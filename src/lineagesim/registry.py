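"""Plug-in registry for single-cell models.

A model is a pair of entry points: a *loader* returning
``(ModelSpecs, kwargs_default)`` and a *runner* mapping
``(state, duration_h, rng, **kwargs)`` to a :class:`~lineagesim.model.Trajectory`.
A runner may additionally provide a vectorized batch form
``(states, durations, rng, **kwargs) -> list[Trajectory]``; the population
engine uses it when present and otherwise loops the per-cell runner.

Entry points can be registered programmatically or named in a config as
``"module:function"`` strings (see docs/model_contract.md).
"""

from __future__ import annotations

import importlib
from dataclasses import dataclass
from typing import Callable

from .errors import ConfigurationError
from . import model as _minimal

__all__ = ["RegisteredModel", "register_model", "get_model", "resolve_entry"]


@dataclass(frozen=True)
class RegisteredModel:
    name: str
    loader: Callable
    runner: Callable
    runner_batch: Callable | None = None


_REGISTRY: dict[str, RegisteredModel] = {}


def register_model(
    name: str,
    loader: Callable,
    runner: Callable,
    runner_batch: Callable | None = None,
) -> None:
    _REGISTRY[name] = RegisteredModel(name, loader, runner, runner_batch)


def get_model(name: str) -> RegisteredModel:
    try:
        return _REGISTRY[name]
    except KeyError:
        valid = ", ".join(sorted(_REGISTRY))
        raise ConfigurationError(
            f"unknown model {name!r}; registered models: {valid}"
        ) from None


def resolve_entry(spec: str) -> Callable:
    """Resolve a ``"package.module:function"`` entry-point string."""
    if ":" not in spec:
        raise ConfigurationError(
            f"entry point {spec!r} must have the form 'module:function'"
        )
    mod_name, attr = spec.split(":", 1)
    try:
        mod = importlib.import_module(mod_name)
        return getattr(mod, attr)
    except (ImportError, AttributeError) as exc:
        raise ConfigurationError(f"cannot resolve entry point {spec!r}: {exc}") from exc


def _minimal_runner(state, duration_h, rng, *, params, dt_s, record_dt_h):
    return _minimal.run_single_cell(
        state, duration_h, params, rng, dt_s=dt_s, record_dt_h=record_dt_h
    )


def _minimal_runner_batch(states, durations_h, rng, *, params, dt_s, record_dt_h):
    return _minimal.run_batch(
        states, durations_h, params, rng, dt_s=dt_s, record_dt_h=record_dt_h
    )


register_model(
    "minimal",
    _minimal.load_minimal_model,
    _minimal_runner,
    _minimal_runner_batch,
)
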
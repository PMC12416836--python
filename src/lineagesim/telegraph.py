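"""Two-state (telegraph) stochastic gene expression.

A gene switches between an inactive (0) and active (1) state with first-order
rates ``k_act`` and ``k_inact``.  While active it produces transcripts at rate
``k_m``; transcripts degrade first-order at rate ``gamma_m``.  The process is
advanced with a tau-leap scheme on a fixed time step (30 s by default): one
uniform draw per gene per step decides switching, and transcript births and
deaths are independent Poisson draws, with deaths truncated so the count never
goes negative.

This is the sole noise source of the minimal cell model: daughter cells start
from identical states and drift apart purely through independent telegraph
dynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "TelegraphParams",
    "telegraph_step",
    "stationary_transcript_mean",
]

#: Warn when a switching probability per step exceeds this (tau-leap validity).
_SWITCH_PROB_WARN = 0.1


@dataclass(frozen=True)
class TelegraphParams:
    """Rate constants of the telegraph process, all per second.

    Defaults give a stationary transcript mean of 20 (p_on = 1/2,
    k_m/gamma_m = 40), a 30 min mean transcript lifetime and a slow on/off
    switching timescale of 24 h (1/(k_act+k_inact)), so expression bursts
    persist across a large part of an assay window and are inherited by
    daughter cells — the heritable proliferative-capacity heterogeneity that
    the mother-cell state analysis is designed to expose.
    """

    k_act: float = 1.0 / 172800.0
    k_inact: float = 1.0 / 172800.0
    k_m: float = 1.0 / 45.0
    gamma_m: float = 1.0 / 1800.0
    dt: float = 30.0

    def __post_init__(self) -> None:
        for name in ("k_act", "k_inact", "k_m", "gamma_m"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"telegraph rate {name!r} must be >= 0")
        if self.dt <= 0:
            raise ConfigurationError("telegraph dt must be > 0")
        for name in ("k_act", "k_inact"):
            if getattr(self, name) * self.dt > _SWITCH_PROB_WARN:
                warnings.warn(
                    f"{name} * dt = {getattr(self, name) * self.dt:.3g} > "
                    f"{_SWITCH_PROB_WARN}; tau-leap switching approximation "
                    "is inaccurate at this step size",
                    stacklevel=2,
                )


def telegraph_step(
    gene_state: np.ndarray | int,
    transcripts: np.ndarray | int,
    params: TelegraphParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance gene state and transcript count by one tau-leap step.

    Works elementwise on arrays (one gene per cell) or on scalars.  Switching
    is decided by comparing a single uniform draw per gene to rate*dt; births
    are Poisson(k_m*g*dt) and deaths Poisson(gamma_m*m*dt), truncated so the
    updated count is non-negative.
    """
    g = np.asarray(gene_state)
    m = np.asarray(transcripts)
    if np.any(m < 0):
        raise ConfigurationError("transcript count must be >= 0")
    dt = params.dt
    u = rng.random(g.shape)
    switch_on = (g == 0) & (u < params.k_act * dt)
    switch_off = (g == 1) & (u < params.k_inact * dt)
    g_new = np.where(switch_on, 1, np.where(switch_off, 0, g))
    births = rng.poisson(params.k_m * dt * g)
    deaths = rng.poisson(params.gamma_m * dt * m)
    m_new = np.maximum(m + births - deaths, 0)
    return g_new, m_new


def stationary_transcript_mean(params: TelegraphParams) -> float:
    """Closed-form stationary mean transcript count.

    mean = k_m * p_on / gamma_m with p_on = k_act / (k_act + k_inact).
    """
    if params.gamma_m <= 0:
        raise ConfigurationError("gamma_m must be > 0 for a stationary mean")
    if params.k_act + params.k_inact <= 0:
        raise ConfigurationError("k_act + k_inact must be > 0 for a stationary mean")
    p_on = params.k_act / (params.k_act + params.k_inact)
    return params.k_m * p_on / params.gamma_m
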
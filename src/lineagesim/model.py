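"""Minimal stochastic cell-cycle model and the pluggable model contract.

The population engine only assumes a model exposes (i) an ordered species
list, (ii) a cycle-marker species whose peaks mark division, and optionally
(iii) a cleaved death-marker species.  This module defines those contract
types and ships a self-contained minimal model used for all desk-scale work:

* a cumulative cycle-phase variable advancing at ``(a_E + b_E*E) * GF / T0``
  cycles per hour, where ``E`` is a smoothed read-out of telegraph gene
  expression (so noisy expression translates into cycle-period
  heterogeneity) and ``GF`` is a growth-factor switch;
* three cyclin-like phase markers — periodic bumps
  ``exp(kappa*(cos(2*pi*(phase - c)) - 1))`` centered at ``marker_centers`` —
  with the B-like marker (center 0.95) acting as the division marker;
* a restriction-point rule: an attached drug rescales the phase speed by the
  free-target fraction only while the cell is within the first ``R`` of its
  cycle (measured from the inter-cycle trough of the averaged markers); a
  committed cell finishes its current cycle at full speed;
* an optional death route: the cleaved death-marker fraction accumulates at
  ``k_apop * s_tox * drug_in`` per hour and a cell is scored dead once it
  exceeds one half (threshold applied downstream in event detection).

Integration is hybrid: stochastic gene expression is updated every 30 s of
simulated time, deterministic states are advanced between those updates, and
output is recorded on a 6 min grid.  The drug subsystem (clamped reservoir,
no feedback from the rest of the cell state) is sub-stepped with RK4 until it
reaches its fixed point and is then held frozen.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .drugs import DrugParams, occupancy_free_fraction
from .errors import ConfigurationError, InputError, NumericsError
from .telegraph import TelegraphParams, stationary_transcript_mean, telegraph_step

__all__ = [
    "ModelSpecs",
    "StateVector",
    "Trajectory",
    "MinimalModelParams",
    "BASE_SPECIES",
    "DRUG_SPECIES",
    "load_minimal_model",
    "serum_starved_state",
    "run_single_cell",
    "run_batch",
    "attach_drug",
]

BASE_SPECIES = (
    "phase",
    "gene_state",
    "transcripts",
    "expression_activity",
    "marker_E",
    "marker_A",
    "marker_B",
    "cleaved_fraction",
)
DRUG_SPECIES = ("drug_in", "target_free", "target_bound")

DEFAULT_DT_S = 30.0
DEFAULT_RECORD_DT_H = 0.1


@dataclass(frozen=True)
class ModelSpecs:
    """What the population engine needs to know about a single-cell model."""

    species_all: tuple[str, ...]
    cc_marker: str
    death_marker: str | None = None
    progress_markers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.species_all)) != len(self.species_all):
            raise ConfigurationError("species names must be unique")
        if self.cc_marker not in self.species_all:
            raise ConfigurationError(
                f"cc_marker {self.cc_marker!r} not in species_all"
            )
        if self.death_marker is not None and self.death_marker not in self.species_all:
            raise ConfigurationError(
                f"death_marker {self.death_marker!r} not in species_all"
            )
        missing = [m for m in self.progress_markers if m not in self.species_all]
        if missing:
            raise ConfigurationError(f"progress markers not in species_all: {missing}")

    def index(self, name: str) -> int:
        try:
            return self.species_all.index(name)
        except ValueError:
            raise ConfigurationError(f"unknown species {name!r}") from None


@dataclass(frozen=True)
class Trajectory:
    """Uniform-grid time course of one cell, times in hours from its birth."""

    times: np.ndarray
    states: np.ndarray
    specs: ModelSpecs

    def __post_init__(self) -> None:
        if self.states.shape != (len(self.times), len(self.specs.species_all)):
            raise InputError(
                f"state matrix shape {self.states.shape} does not match "
                f"{len(self.times)} times x {len(self.specs.species_all)} species"
            )
        if len(self.times) and self.times[0] != 0.0:
            raise InputError("trajectory times must start at 0 (birth-relative)")

    def column(self, name: str) -> np.ndarray:
        return self.states[:, self.specs.index(name)]

    @property
    def duration(self) -> float:
        return float(self.times[-1]) if len(self.times) else 0.0

    def truncated(self, n_points: int) -> "Trajectory":
        return Trajectory(self.times[:n_points], self.states[:n_points], self.specs)


@dataclass(frozen=True)
class MinimalModelParams:
    """Parameters of the minimal cycle model.

    ``T0`` is the unperturbed cycle period (hours) at the mean expression
    level; ``R`` the committed fraction of the cycle (restriction point);
    ``marker_centers`` the phase positions of the E-, A- and B-like cyclin
    markers (cycle units); ``kappa`` their sharpness.  The centers cluster in
    the second half of the cycle so the averaged marker trace has a single
    deep trough per cycle (at phase ``cycle_start_phase``), which is what
    makes trough-to-trough progress estimation well defined.
    """

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
    telegraph: TelegraphParams = field(default_factory=TelegraphParams)
    drug: DrugParams | None = None

    def __post_init__(self) -> None:
        if self.T0 <= 0:
            raise ConfigurationError("T0 must be > 0")
        if not 0 <= self.R < 1:
            raise ConfigurationError(f"R must lie in [0, 1); got {self.R}")
        centers = tuple(self.marker_centers)
        if any(not 0 <= c < 1 for c in centers) or any(
            b <= a for a, b in zip(centers, centers[1:])
        ):
            raise ConfigurationError(
                f"marker_centers must be strictly increasing in [0, 1); got {centers}"
            )
        if self.kappa <= 0:
            raise ConfigurationError("kappa must be > 0")
        for name in ("a_E", "b_E", "k_E", "k_apop", "s_tox"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.GF not in (0, 1, 0.0, 1.0):
            raise ConfigurationError("GF must be 0 or 1")
        if self.drug_response not in ("linear", "hill"):
            raise ConfigurationError(
                f"drug_response must be 'linear' or 'hill'; got {self.drug_response!r}"
            )

    @property
    def cycle_start_phase(self) -> float:
        """Phase of the inter-cycle trough of the averaged markers.

        The trough sits midway across the circular gap between the B-like
        marker and the next cycle's E-like marker; with default centers this
        is 0.20.  The commitment window [0, R) is measured from here.
        """
        c_first, c_last = self.marker_centers[0], self.marker_centers[-1]
        return float((c_last + 1.0 + c_first) / 2.0 % 1.0)

    def species(self) -> tuple[str, ...]:
        return BASE_SPECIES + (DRUG_SPECIES if self.drug is not None else ())


@dataclass
class StateVector:
    """One cell's full minimal-model state at an instant."""

    phase: float = 0.0
    gene_state: int = 1
    transcripts: int = 0
    expression_activity: float = 1.0
    cleaved_fraction: float = 0.0
    drug_in: float = 0.0
    target_free: float = 0.0
    target_bound: float = 0.0

    def to_array(self, params: MinimalModelParams) -> np.ndarray:
        x = np.asarray(self.phase, float)
        markers = _marker_values(np.atleast_1d(x), params)[0]
        base = [
            self.phase,
            float(self.gene_state),
            float(self.transcripts),
            self.expression_activity,
            *markers,
            self.cleaved_fraction,
        ]
        if params.drug is not None:
            base += [self.drug_in, self.target_free, self.target_bound]
        return np.asarray(base, float)

    @classmethod
    def from_array(cls, arr: np.ndarray, specs: ModelSpecs) -> "StateVector":
        get = lambda n: float(arr[specs.index(n)])
        has_drug = "drug_in" in specs.species_all
        return cls(
            phase=get("phase"),
            gene_state=int(round(get("gene_state"))),
            transcripts=int(round(get("transcripts"))),
            expression_activity=get("expression_activity"),
            cleaved_fraction=get("cleaved_fraction"),
            drug_in=get("drug_in") if has_drug else 0.0,
            target_free=get("target_free") if has_drug else 0.0,
            target_bound=get("target_bound") if has_drug else 0.0,
        )


def _marker_values(phase: np.ndarray, params: MinimalModelParams) -> np.ndarray:
    """Marker bump values for an array of phases; shape (..., 3)."""
    x = np.asarray(phase, float)[..., None]
    centers = np.asarray(params.marker_centers, float)
    return np.exp(params.kappa * (np.cos(2 * np.pi * (x - centers)) - 1.0))


def load_minimal_model(
    params: MinimalModelParams | None = None,
) -> tuple[ModelSpecs, dict]:
    """Loader entry point for the built-in minimal model.

    Returns the model contract (species order, division marker, death marker,
    progress markers) and the default keyword arguments for the runner.
    """
    params = params if params is not None else MinimalModelParams()
    specs = ModelSpecs(
        species_all=params.species(),
        cc_marker="marker_B",
        death_marker="cleaved_fraction",
        progress_markers=("marker_E", "marker_A", "marker_B"),
    )
    kwargs_default = {
        "params": params,
        "dt_s": DEFAULT_DT_S,
        "record_dt_h": DEFAULT_RECORD_DT_H,
    }
    return specs, kwargs_default


def serum_starved_state(params: MinimalModelParams | None = None) -> StateVector:
    """Average serum-starved cell: phase 0, stationary transcripts, no drug.

    The gene starts active; the transcript count is the rounded stationary
    mean of the telegraph process so the population average is unbiased.
    """
    params = params if params is not None else MinimalModelParams()
    m_ss = stationary_transcript_mean(params.telegraph)
    state = StateVector(
        phase=0.0,
        gene_state=1,
        transcripts=int(round(m_ss)),
        expression_activity=1.0,
        cleaved_fraction=0.0,
    )
    if params.drug is not None:
        state.target_free = params.drug.target_total
    return state


def attach_drug(
    params: MinimalModelParams,
    drug: DrugParams,
    coupling: str = "cycle_speed",
) -> MinimalModelParams:
    """Attach a pharmacodynamic module to the minimal model.

    The drug couples to the model by rescaling the pre-commitment cycle speed
    with the free-target fraction (linear by default, Hill optional via
    ``drug_response``).  At dose 0 the dynamics are unchanged.
    """
    if coupling != "cycle_speed":
        raise ConfigurationError(f"unsupported drug coupling {coupling!r}")
    if params.drug is not None:
        raise ConfigurationError(
            "a drug module is already attached; combinations on one target "
            "are not supported"
        )
    return dataclasses.replace(params, drug=drug)


def _speed_factor_free(f_free: np.ndarray, params: MinimalModelParams) -> np.ndarray:
    if params.drug_response == "linear":
        return f_free
    h, k = params.hill_h, params.hill_k
    fh = np.power(np.maximum(f_free, 0.0), h)
    return fh * (1.0 + k**h) / (fh + k**h)


def run_batch(
    states: np.ndarray,
    durations_h: Sequence[float] | float,
    params: MinimalModelParams,
    rng: np.random.Generator,
    *,
    gf: float | None = None,
    dt_s: float = DEFAULT_DT_S,
    record_dt_h: float = DEFAULT_RECORD_DT_H,
) -> list[Trajectory]:
    """Simulate a batch of cells with shared stochastic-step and output grids.

    ``states`` is (n_cells, n_species) in the model's species order; each cell
    may have its own duration.  Stochastic gene expression is updated every
    ``dt_s`` seconds; the output is sampled every ``record_dt_h`` hours.  With
    a fixed generator state the result is bit-reproducible.
    """
    states = np.atleast_2d(np.asarray(states, float))
    n = states.shape[0]
    specs, _ = load_minimal_model(params)
    n_sp = len(specs.species_all)
    if states.shape[1] != n_sp:
        raise InputError(
            f"state width {states.shape[1]} does not match species count {n_sp}"
        )
    durations = np.broadcast_to(np.asarray(durations_h, float), (n,)).copy()
    if np.any(durations <= 0):
        raise InputError("durations must be > 0")
    dt_h = dt_s / 3600.0
    steps_per_rec = max(1, int(round(record_dt_h / dt_h)))
    n_rec = (durations / record_dt_h + 1e-9).astype(int) + 1
    n_rec_max = int(n_rec.max())
    n_steps = (n_rec_max - 1) * steps_per_rec

    gf_val = float(params.GF if gf is None else gf)
    m_ss = stationary_transcript_mean(params.telegraph)

    phase = states[:, 0].copy()
    gene = np.round(states[:, 1]).astype(np.int64)
    m = np.round(states[:, 2]).astype(np.int64)
    E = states[:, 3].copy()
    P = states[:, 7].copy()
    drug = params.drug
    if drug is not None:
        D_in = states[:, 8].copy()
        T_free = states[:, 9].copy()
        TD = states[:, 10].copy()
        rate_max = (
            drug.k_transport
            + drug.kon * (drug.dose_ext + drug.target_total)
            + drug.koff
            + drug.k_deg
        )
        n_sub = max(1, int(np.ceil(dt_s * rate_max / 0.2)))
        dt_sub = dt_s / n_sub
        drug_frozen = False
        drug_scale = drug.dose_ext + drug.target_total + 1.0

    # Recorded columns: phase, gene, transcripts, E, cleaved (+ drug block);
    # markers are pure functions of phase and are filled in afterwards.
    rec_phase = np.empty((n, n_rec_max))
    rec_gene = np.empty((n, n_rec_max))
    rec_m = np.empty((n, n_rec_max))
    rec_E = np.empty((n, n_rec_max))
    rec_P = np.empty((n, n_rec_max))
    if drug is not None:
        rec_D = np.empty((n, n_rec_max))
        rec_Tf = np.empty((n, n_rec_max))
        rec_TD = np.empty((n, n_rec_max))

    def record(row: int) -> None:
        rec_phase[:, row] = phase
        rec_gene[:, row] = gene
        rec_m[:, row] = m
        rec_E[:, row] = E
        rec_P[:, row] = P
        if drug is not None:
            rec_D[:, row] = D_in
            rec_Tf[:, row] = T_free
            rec_TD[:, row] = TD

    record(0)
    decay_E = np.exp(-params.k_E * dt_h)
    cycle_start = params.cycle_start_phase
    for k in range(1, n_steps + 1):
        if params.noise:
            gene, m = telegraph_step(gene, m, params.telegraph, rng)
            target = m / m_ss
            E = target + (E - target) * decay_E
        if drug is not None and not drug_frozen:
            prev = (D_in.copy(), T_free.copy(), TD.copy())
            y = [D_in, T_free, TD]
            for _ in range(n_sub):
                y = _rk4_drug(y, dt_sub, drug)
            D_in, T_free, TD = (np.maximum(v, 0.0) for v in y)
            delta = max(
                float(np.max(np.abs(D_in - prev[0]))),
                float(np.max(np.abs(T_free - prev[1]))),
                float(np.max(np.abs(TD - prev[2]))),
            )
            if delta / drug_scale < 1e-12:
                drug_frozen = True
        speed = gf_val * (params.a_E + params.b_E * E) / params.T0
        if drug is not None:
            f_free = occupancy_free_fraction(T_free, TD)
            s_drug = _speed_factor_free(f_free, params)
            uncommitted = (phase - cycle_start) % 1.0 < params.R
            speed = speed * np.where(uncommitted, s_drug, 1.0)
        phase = phase + speed * dt_h
        if drug is not None and params.s_tox > 0:
            P = np.minimum(P + params.k_apop * params.s_tox * D_in * dt_h, 1.0)
        if k % steps_per_rec == 0:
            row = k // steps_per_rec
            record(row)
            if not (np.all(np.isfinite(phase)) and np.all(np.isfinite(E))):
                bad = int(np.flatnonzero(~(np.isfinite(phase) & np.isfinite(E)))[0])
                raise NumericsError(
                    f"non-finite state in cell {bad} at t = {row * record_dt_h:.2f} h"
                )

    markers = _marker_values(rec_phase, params)  # (n, n_rec_max, 3)
    cols = [rec_phase, rec_gene, rec_m, rec_E] + [
        markers[..., j] for j in range(3)
    ] + [rec_P]
    if drug is not None:
        cols += [rec_D, rec_Tf, rec_TD]
    full = np.stack(cols, axis=-1)  # (n, n_rec_max, n_sp)

    out = []
    for i in range(n):
        k_i = int(n_rec[i])
        times = np.arange(k_i) * record_dt_h
        out.append(Trajectory(times, full[i, :k_i].copy(), specs))
    return out


def _rk4_drug(y, dt, p: DrugParams):
    def deriv(s):
        bind = p.kon * s[0] * s[1]
        unbind = p.koff * s[2]
        return (
            p.k_transport * (p.dose_ext - s[0]) - bind + unbind,
            -bind + unbind + p.k_deg * (p.target_total - s[1] - s[2]),
            bind - unbind - p.k_deg * s[2],
        )

    k1 = deriv(y)
    k2 = deriv([y[i] + 0.5 * dt * k1[i] for i in range(3)])
    k3 = deriv([y[i] + 0.5 * dt * k2[i] for i in range(3)])
    k4 = deriv([y[i] + dt * k3[i] for i in range(3)])
    return [y[i] + dt / 6.0 * (k1[i] + 2 * k2[i] + 2 * k3[i] + k4[i]) for i in range(3)]


def run_single_cell(
    state: StateVector | np.ndarray,
    duration_h: float,
    params: MinimalModelParams,
    rng: np.random.Generator | int | None = None,
    **kwargs,
) -> Trajectory:
    """Runner entry point: simulate one cell for ``duration_h`` hours."""
    if duration_h <= 0:
        raise InputError("duration must be > 0")
    if isinstance(state, StateVector):
        state = state.to_array(params)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return run_batch(np.atleast_2d(state), duration_h, params, rng, **kwargs)[0]
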
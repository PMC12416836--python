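"""Lineage-resolved population simulation.

The assay timeline mirrors a drug-treatment viability experiment:

1. *Heterogenization*: every starting cell is an independent stochastic run
   from one average serum-starved state (growth factor off) so intrinsic
   gene-expression noise spreads the population in state space.
2. *Gen 0 / asynchronization*: growth factor is switched on for a fixed
   window; each cell's Gen-1 initial condition is its state at a uniformly
   random time point of that window, producing an asynchronously cycling
   population.
3. *Generation loop* (t = 0 at drug addition): every living cell is
   simulated for its remaining time; the first division peak of the cycle
   marker spawns two daughters with the mother's state at division
   (symmetric by default, customizable via a divider hook) and remaining
   time = duration - division time; a death-marker crossing halts the
   lineage; cells with neither event are censored at the end of the window.
   The loop terminates when a generation produces no divisions.

All randomness flows from one root seed through named SeedSequence streams
per (replicate, stage/generation), so reruns reproduce every trajectory and
record exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .drugs import DrugParams
from .errors import ConfigurationError, InputError
from .events import PeakParams, detect_death, first_division
from .model import (
    DEFAULT_RECORD_DT_H,
    MinimalModelParams,
    ModelSpecs,
    Trajectory,
    attach_drug,
    run_batch,
    serum_starved_state,
)
from .registry import RegisteredModel, get_model

__all__ = [
    "CellRecord",
    "LineageTable",
    "InitialPool",
    "ReplicateResult",
    "PopulationResult",
    "heterogenize",
    "asynchronize",
    "spawn_daughters",
    "build_initial_pool",
    "simulate_population",
]

CellId = tuple[int, int]

# SeedSequence stage tags: heterogenize, Gen 0, asynchronize, then 10+g per
# treated generation g.
_STAGE_HET, _STAGE_GEN0, _STAGE_ASYNC = 0, 1, 2
_STAGE_GEN_BASE = 10


@dataclass(frozen=True)
class CellRecord:
    """Bookkeeping for one cell: identity, times (absolute hours since drug
    addition) and fate ('divided' | 'died' | 'censored')."""

    generation: int
    index: int
    parent: CellId | None
    birth_time: float
    end_time: float
    fate: str
    division_time: float | None = None

    @property
    def cell_id(self) -> CellId:
        return (self.generation, self.index)

    @property
    def lifetime(self) -> float:
        return self.end_time - self.birth_time


@dataclass
class LineageTable:
    """All cell records of one replicate at one condition."""

    records: list[CellRecord]
    replicate: int = 0
    dose: float = 0.0
    drug: str | None = None
    duration: float = 72.0

    def __post_init__(self) -> None:
        self._by_id = {r.cell_id: r for r in self.records}
        self._children: dict[CellId, list[CellRecord]] = {}
        for r in self.records:
            if r.parent is not None:
                self._children.setdefault(r.parent, []).append(r)

    def __len__(self) -> int:
        return len(self.records)

    def record(self, cell_id: CellId) -> CellRecord:
        return self._by_id[cell_id]

    def children(self, cell_id: CellId) -> list[CellRecord]:
        return self._children.get(cell_id, [])

    def roots(self) -> list[CellRecord]:
        return [r for r in self.records if r.parent is None]

    def subtree(self, cell_id: CellId) -> list[CellRecord]:
        out, stack = [], [self.record(cell_id)]
        while stack:
            r = stack.pop()
            out.append(r)
            stack.extend(self.children(r.cell_id))
        return out

    def validate(self) -> None:
        """Check every structural invariant; raise InputError on violation."""
        if len(self._by_id) != len(self.records):
            raise InputError("duplicate cell ids in lineage")
        for r in self.records:
            if not (r.birth_time <= r.end_time <= self.duration + 1e-9):
                raise InputError(f"cell {r.cell_id}: times outside [birth, duration]")
            if r.parent is None:
                if r.generation != 1 or r.birth_time != 0.0:
                    raise InputError(f"root cell {r.cell_id} must be Gen 1 at t=0")
            elif r.parent not in self._by_id:
                raise InputError(f"cell {r.cell_id}: parent {r.parent} missing")
            kids = self.children(r.cell_id)
            if r.fate == "divided":
                if len(kids) != 2:
                    raise InputError(f"divided cell {r.cell_id} has {len(kids)} children")
                for k in kids:
                    if abs(k.birth_time - r.division_time) > 1e-9:
                        raise InputError(
                            f"child {k.cell_id} birth != parent division time"
                        )
            elif kids:
                raise InputError(f"non-divided cell {r.cell_id} has children")

    def counts(self) -> dict[str, int]:
        out = {"divided": 0, "died": 0, "censored": 0}
        for r in self.records:
            out[r.fate] += 1
        return out


@dataclass
class InitialPool:
    """Asynchronized Gen-1 initial conditions plus their Gen-0 provenance."""

    states: np.ndarray  # (n_cells, n_species) without drug columns
    sample_times: np.ndarray  # hours into the Gen-0 window
    gen0_trajectories: list[Trajectory]
    specs: ModelSpecs


@dataclass
class ReplicateResult:
    lineage: LineageTable
    trajectories: dict[CellId, Trajectory]
    pool: InitialPool
    specs: ModelSpecs
    params: MinimalModelParams


@dataclass
class PopulationResult:
    replicates: list[ReplicateResult]

    def lineages(self) -> list[LineageTable]:
        return [r.lineage for r in self.replicates]


def heterogenize(
    n_cells: int,
    params: MinimalModelParams | None = None,
    seed: int | np.random.Generator | np.random.SeedSequence = 0,
    duration_h: float = 48.0,
) -> np.ndarray:
    """Final states of ``n_cells`` independent serum-starved runs (GF = 0)."""
    if n_cells < 1:
        raise InputError("n_cells must be >= 1")
    params = params if params is not None else MinimalModelParams()
    rng = _as_rng(seed)
    base = serum_starved_state(params).to_array(params)
    states0 = np.tile(base, (n_cells, 1))
    trajs = run_batch(states0, duration_h, params, rng, gf=0.0)
    return np.stack([t.states[-1] for t in trajs])


def asynchronize(
    gen0_trajectories: Sequence[Trajectory],
    rng: np.random.Generator | int,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample one uniformly random time index per Gen-0 trajectory.

    Returns the sampled states (Gen-1 initial conditions) and the sampled
    times within the Gen-0 window.
    """
    if len(gen0_trajectories) == 0 or any(len(t.times) == 0 for t in gen0_trajectories):
        raise InputError("asynchronize requires non-empty Gen-0 trajectories")
    rng = _as_rng(rng)
    states, t_samp = [], []
    for traj in gen0_trajectories:
        j = int(rng.integers(0, len(traj.times)))
        states.append(traj.states[j])
        t_samp.append(traj.times[j])
    return np.stack(states), np.asarray(t_samp)


def spawn_daughters(
    mother_trajectory: Trajectory,
    division_time: float,
    divider: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]] | None = None,
) -> tuple[np.ndarray, np.ndarray, Trajectory]:
    """Symmetric division at ``division_time`` (a grid point of the mother).

    Returns the two daughter state vectors and the mother's trajectory
    truncated at the division point.  An optional divider hook transforms the
    inherited state pair (e.g. binomial partitioning of molecule counts).
    """
    times = mother_trajectory.times
    if not (times[0] <= division_time <= times[-1]):
        raise InputError(
            f"division time {division_time} outside mother span "
            f"[{times[0]}, {times[-1]}]"
        )
    j = int(np.argmin(np.abs(times - division_time)))
    state = mother_trajectory.states[j]
    if divider is None:
        d1, d2 = state.copy(), state.copy()
    else:
        d1, d2 = divider(state.copy())
    return d1, d2, mother_trajectory.truncated(j + 1)


def build_initial_pool(
    n_start: int,
    params: MinimalModelParams,
    seed: int | np.random.SeedSequence,
    heterogenize_h: float = 48.0,
    gen0_h: float = 48.0,
) -> InitialPool:
    """Heterogenize, run the growth-stimulated Gen-0 window, asynchronize."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    drug_free = dataclasses.replace(params, drug=None)
    het_states = heterogenize(
        n_start,
        drug_free,
        np.random.SeedSequence(entropy=ss.entropy, spawn_key=(_STAGE_HET,)),
        duration_h=heterogenize_h,
    )
    rng0 = _as_rng(np.random.SeedSequence(entropy=ss.entropy, spawn_key=(_STAGE_GEN0,)))
    gen0 = run_batch(het_states, gen0_h, drug_free, rng0, gf=1.0)
    rng_a = _as_rng(np.random.SeedSequence(entropy=ss.entropy, spawn_key=(_STAGE_ASYNC,)))
    states, t_samp = asynchronize(gen0, rng_a)
    from .model import load_minimal_model

    specs, _ = load_minimal_model(drug_free)
    return InitialPool(states, t_samp, gen0, specs)


def simulate_population(
    *,
    seed: int,
    n_start: int = 100,
    duration_h: float = 72.0,
    replicates: int = 1,
    params: MinimalModelParams | None = None,
    drug: DrugParams | None = None,
    model: str | RegisteredModel = "minimal",
    heterogenize_h: float = 48.0,
    gen0_h: float = 48.0,
    peak_params: PeakParams | None = None,
    death_threshold: float = 0.5,
    divider: Callable | None = None,
    pools: Sequence[InitialPool] | None = None,
    keep_trajectories: bool = True,
) -> PopulationResult:
    """Run the full lineage-resolved assay and return lineages + trajectories.

    ``pools`` lets a caller reuse one asynchronized Gen-1 pool per replicate
    across doses of a drug so dose comparisons are paired; when omitted each
    replicate builds its own pool from its seed (identical pools across doses
    for the same seed either way, since pool streams do not depend on dose).
    """
    base_params = params if params is not None else MinimalModelParams()
    if base_params.drug is not None and drug is not None:
        raise ConfigurationError("pass the drug either on params or as `drug`, not both")
    run_params = attach_drug(base_params, drug) if drug is not None else base_params
    reg = get_model(model) if isinstance(model, str) else model
    specs, kwargs_default = reg.loader(run_params)
    if specs.cc_marker not in specs.species_all:  # defensive; ModelSpecs validates
        raise ConfigurationError("model contract violated: cc_marker missing")
    if peak_params is None:
        peak_params = PeakParams(min_separation=0.25 * run_params.T0)

    out = []
    for rep in range(replicates):
        rep_ss = np.random.SeedSequence([seed, rep])
        if pools is not None:
            pool = pools[rep]
        else:
            pool = build_initial_pool(
                n_start, base_params, rep_ss, heterogenize_h, gen0_h
            )
        states1 = pool.states
        if run_params.drug is not None:
            extra = np.zeros((states1.shape[0], 3))
            extra[:, 1] = run_params.drug.target_total  # free target pool
            states1 = np.hstack([states1, extra])
        result = _run_generations(
            states1,
            duration_h,
            run_params,
            reg,
            kwargs_default,
            rep_ss,
            peak_params,
            death_threshold,
            divider,
            keep_trajectories,
        )
        records, trajectories = result
        lineage = LineageTable(
            records,
            replicate=rep,
            dose=run_params.drug.dose_ext if run_params.drug else 0.0,
            drug=run_params.drug.name if run_params.drug else None,
            duration=duration_h,
        )
        out.append(ReplicateResult(lineage, trajectories, pool, specs, run_params))
    return PopulationResult(out)


def _run_generations(
    states1,
    duration_h,
    run_params,
    reg,
    kwargs_default,
    rep_ss,
    peak_params,
    death_threshold,
    divider,
    keep_trajectories,
):
    records: list[CellRecord] = []
    trajectories: dict[CellId, Trajectory] = {}
    # (index, parent_id, birth_time, state)
    cells = [(i, None, 0.0, states1[i]) for i in range(states1.shape[0])]
    gen = 1
    while cells:
        durations = np.array([duration_h - c[2] for c in cells])
        runnable = durations > DEFAULT_RECORD_DT_H / 2
        rng = _as_rng(
            np.random.SeedSequence(
                entropy=rep_ss.entropy, spawn_key=(_STAGE_GEN_BASE + gen,)
            )
        )
        run_idx = np.flatnonzero(runnable)
        trajs: dict[int, Trajectory] = {}
        if run_idx.size:
            batch_states = np.stack([cells[i][3] for i in run_idx])
            batch_durs = durations[run_idx]
            if reg.runner_batch is not None:
                batch = reg.runner_batch(batch_states, batch_durs, rng, **kwargs_default)
            else:
                batch = [
                    reg.runner(
                        batch_states[j],
                        float(batch_durs[j]),
                        _as_rng(
                            np.random.SeedSequence(
                                entropy=rep_ss.entropy,
                                spawn_key=(_STAGE_GEN_BASE + gen, int(cells[i][0])),
                            )
                        ),
                        **kwargs_default,
                    )
                    for j, i in enumerate(run_idx)
                ]
            trajs = dict(zip(run_idx.tolist(), batch))

        daughters = []
        next_index = 0
        specs = None
        for i, (index, parent, birth, state) in enumerate(cells):
            if i not in trajs:  # spawned with (near-)zero remaining time
                records.append(
                    CellRecord(gen, index, parent, birth, duration_h, "censored")
                )
                continue
            traj = trajs[i]
            specs = traj.specs
            t_div = first_division(traj, specs, peak_params)
            t_die = detect_death(traj, specs, death_threshold)
            if t_die is not None and (t_div is None or t_die <= t_div):
                j_end = int(np.searchsorted(traj.times, t_die)) + 1
                records.append(
                    CellRecord(gen, index, parent, birth, birth + t_die, "died")
                )
                if keep_trajectories:
                    trajectories[(gen, index)] = traj.truncated(min(j_end, len(traj.times)))
            elif t_div is not None:
                d1, d2, truncated = spawn_daughters(traj, t_div, divider)
                abs_div = birth + t_div
                records.append(
                    CellRecord(
                        gen, index, parent, birth, abs_div, "divided", abs_div
                    )
                )
                if keep_trajectories:
                    trajectories[(gen, index)] = truncated
                for d in (d1, d2):
                    daughters.append((next_index, (gen, index), abs_div, d))
                    next_index += 1
            else:
                records.append(
                    CellRecord(gen, index, parent, birth, duration_h, "censored")
                )
                if keep_trajectories:
                    trajectories[(gen, index)] = traj
        cells = daughters
        gen += 1
    return records, trajectories


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
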
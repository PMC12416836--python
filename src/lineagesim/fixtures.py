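"""Programmatic fixtures: synthetic lineages and marker traces with known
ground truth, so event detection and every lineage analytic can be tested
without running the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import InputError
from .model import ModelSpecs, Trajectory
from .population import CellRecord, LineageTable

__all__ = [
    "FIXTURE_SPECS",
    "bump_train",
    "death_ramp",
    "LineageFixture",
    "make_fixture",
    "make_random_lineage",
]

CellId = tuple[int, int]

#: Two-species contract used by fixture trajectories.
FIXTURE_SPECS = ModelSpecs(
    species_all=("marker_B", "cleaved_fraction"),
    cc_marker="marker_B",
    death_marker="cleaved_fraction",
    progress_markers=("marker_B",),
)


def bump_train(
    times: np.ndarray,
    peak_times,
    width_h: float = 1.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Sum of unit Gaussian bumps at the scheduled peak times + white noise."""
    times = np.asarray(times, float)
    trace = np.zeros_like(times)
    for tp in np.atleast_1d(peak_times):
        trace += np.exp(-0.5 * ((times - tp) / width_h) ** 2)
    if noise_sd > 0:
        rng = rng if rng is not None else np.random.default_rng(0)
        trace = trace + rng.normal(0.0, noise_sd, size=times.shape)
    return trace


def death_ramp(times: np.ndarray, cross_time: float | None) -> np.ndarray:
    """Cleaved-fraction ramp crossing 0.5 exactly at ``cross_time`` (flat 0
    when no death is scheduled), clipped to [0, 1]."""
    times = np.asarray(times, float)
    if cross_time is None:
        return np.zeros_like(times)
    span = max(float(times[-1] - times[0]), 1e-6)
    slope = 0.5 / max(cross_time - times[0], 0.05 * span)
    return np.clip(slope * (times - times[0]), 0.0, 1.0)


@dataclass
class LineageFixture:
    """A synthetic lineage plus per-cell traces and the exact event schedule."""

    lineage: LineageTable
    trajectories: dict[CellId, Trajectory]
    division_times: dict[CellId, float] = field(default_factory=dict)
    death_times: dict[CellId, float] = field(default_factory=dict)
    specs: ModelSpecs = FIXTURE_SPECS


def make_fixture(
    n_roots: int = 3,
    duration_h: float = 72.0,
    division_times: Mapping[CellId, float] | None = None,
    death_times: Mapping[CellId, float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    record_dt_h: float = 0.1,
) -> LineageFixture:
    """Build a lineage from an explicit event schedule.

    ``division_times`` / ``death_times`` map (generation, index) cell ids to
    absolute event times; a cell with neither event is censored at the end of
    the window.  When a cell has both, the earlier wins (tie: death).  Marker
    traces carry a bump at the division time, death traces a ramp crossing
    0.5 at the death time; the schedule itself is returned as ground truth.
    """
    division_times = dict(division_times or {})
    death_times = dict(death_times or {})
    rng = np.random.default_rng(seed)
    records: list[CellRecord] = []
    trajectories: dict[CellId, Trajectory] = {}
    true_div: dict[CellId, float] = {}
    true_die: dict[CellId, float] = {}

    cells: list[tuple[CellId, CellId | None, float]] = [
        ((1, i), None, 0.0) for i in range(n_roots)
    ]
    while cells:
        next_cells = []
        counters: dict[int, int] = {}
        for cid, parent, birth in cells:
            gen = cid[0]
            t_div = division_times.get(cid)
            t_die = death_times.get(cid)
            for label, t in (("division", t_div), ("death", t_die)):
                if t is not None and not (birth < t <= duration_h):
                    raise InputError(
                        f"scheduled {label} of cell {cid} at {t} h lies outside "
                        f"its window ({birth}, {duration_h}]"
                    )
            if t_die is not None and (t_div is None or t_die <= t_div):
                end, fate, t_div = t_die, "died", None
            elif t_div is not None:
                end, fate = t_div, "divided"
            else:
                end, fate = duration_h, "censored"
            records.append(
                CellRecord(gen, cid[1], parent, birth, end, fate, t_div if fate == "divided" else None)
            )
            times = np.arange(0.0, end - birth + record_dt_h / 2, record_dt_h)
            if len(times) < 3:
                times = np.arange(3) * record_dt_h
            marker = bump_train(
                times, [t_div - birth] if t_div is not None else [], noise_sd=noise_sd, rng=rng
            )
            death = death_ramp(times, (t_die - birth) if fate == "died" else None)
            trajectories[cid] = Trajectory(times, np.column_stack([marker, death]), FIXTURE_SPECS)
            if t_div is not None:
                true_div[cid] = t_div
            if fate == "died":
                true_die[cid] = t_die
            if fate == "divided":
                base = counters.get(gen + 1, 0)
                for j in range(2):
                    next_cells.append(((gen + 1, base + j), cid, end))
                counters[gen + 1] = base + 2
        cells = next_cells

    lineage = LineageTable(records, duration=duration_h)
    lineage.validate()
    return LineageFixture(lineage, trajectories, true_div, true_die)


def make_random_lineage(
    seed: int = 0,
    n_start: int = 10,
    duration_h: float = 72.0,
    p_divide: float = 0.7,
    p_die: float = 0.1,
    min_cycle_h: float = 5.0,
) -> LineageTable:
    """Random but structurally valid lineage for property-based checks."""
    rng = np.random.default_rng(seed)
    division_times: dict[CellId, float] = {}
    death_times: dict[CellId, float] = {}
    cells: list[tuple[CellId, float]] = [((1, i), 0.0) for i in range(n_start)]
    while cells:
        next_cells = []
        counters: dict[int, int] = {}
        for cid, birth in cells:
            u = rng.random()
            remaining = duration_h - birth
            if u < p_divide and remaining > min_cycle_h:
                t = birth + rng.uniform(min_cycle_h, min(remaining, 4 * min_cycle_h))
                division_times[cid] = float(t)
                gen = cid[0]
                base = counters.get(gen + 1, 0)
                for j in range(2):
                    next_cells.append(((gen + 1, base + j), t))
                counters[gen + 1] = base + 2
            elif u < p_divide + p_die and remaining > 0.5:
                death_times[cid] = float(birth + rng.uniform(0.25, remaining))
        cells = next_cells
    fx = make_fixture(
        n_roots=n_start,
        duration_h=duration_h,
        division_times=division_times,
        death_times=death_times,
        seed=seed,
    )
    return fx.lineage
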
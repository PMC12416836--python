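"""Population-level read-outs of lineage-resolved simulations.

Covers the analysis layer of a viability assay: alive-cell growth curves and
doubling time, growth-rate-inhibition (GR) dose response, the observable
death fraction in a trailing window, lineage dendrograms and Newick export,
fractional cell-cycle progress from cyclin-like markers, the KDE-based
division-probability-vs-progress curve, and generic parameter sweeps.

The GR endpoint metric normalizes drug effect by control growth over the
assay window:  GR = 2^(log2(x/x0) / log2(x_ctrl/x0)) - 1,  so 1 means
uninhibited growth, 0 complete cytostasis and negative values net cell loss.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from .errors import ConfigurationError, InputError, NumericsError
from .model import MinimalModelParams, ModelSpecs, Trajectory, serum_starved_state
from .population import (
    CellRecord,
    LineageTable,
    PopulationResult,
    ReplicateResult,
    simulate_population,
)

__all__ = [
    "alive_count_curve",
    "doubling_time",
    "gr_value",
    "dose_response",
    "death_fraction_window",
    "dendrogram_layout",
    "export_newick",
    "Reference",
    "deterministic_reference",
    "cycle_progress",
    "ProgressCurve",
    "division_probability_by_progress",
    "progress_at_dose",
    "division_probability_analysis",
    "crossing_progress",
    "sweep_division_probability",
]


# ---------------------------------------------------------------- growth


def _alive_at(records: Sequence[CellRecord], t: float) -> int:
    n = 0
    for r in records:
        if r.birth_time <= t and (t < r.end_time or (r.fate == "censored" and t <= r.end_time)):
            n += 1
    return n


def alive_count_curve(lineage: LineageTable, grid: np.ndarray) -> np.ndarray:
    """Number of living cells at each grid time.

    A cell is alive on [birth, end); censored cells additionally count at
    their end point so the final census includes survivors.
    """
    grid = np.asarray(grid, float)
    if grid.size and (grid.min() < -1e-9 or grid.max() > lineage.duration + 1e-9):
        raise InputError(
            f"grid [{grid.min()}, {grid.max()}] outside simulated window "
            f"[0, {lineage.duration}]"
        )
    births = np.array([r.birth_time for r in lineage.records])
    ends = np.array([r.end_time for r in lineage.records])
    censored = np.array([r.fate == "censored" for r in lineage.records])
    counts = np.empty(grid.size, dtype=int)
    for i, t in enumerate(grid):
        alive = (births <= t) & ((t < ends) | (censored & (t <= ends)))
        counts[i] = int(alive.sum())
    return counts


def final_count(lineage: LineageTable) -> int:
    """Living cells at the end of the window (= censored records)."""
    return lineage.counts()["censored"]


def doubling_time(
    median_curve: np.ndarray, grid: np.ndarray, n_start: int
) -> float | None:
    """First time the median growth curve reaches twice the starting count,
    linearly interpolated; None if never reached."""
    curve = np.asarray(median_curve, float)
    grid = np.asarray(grid, float)
    target = 2.0 * n_start
    above = curve >= target
    if not np.any(above):
        return None
    j = int(np.argmax(above))
    if j == 0 or curve[j] == target or curve[j] == curve[j - 1]:
        return float(grid[j])
    frac = (target - curve[j - 1]) / (curve[j] - curve[j - 1])
    return float(grid[j - 1] + frac * (grid[j] - grid[j - 1]))


# ---------------------------------------------------------------- GR metric


def gr_value(count: float, count_ctrl: float, count_t0: float) -> float:
    """Endpoint growth-rate-inhibition value for one replicate."""
    if count <= 0 or count_ctrl <= 0 or count_t0 <= 0:
        raise InputError("cell counts must be > 0 for the GR metric")
    denom = math.log2(count_ctrl / count_t0)
    if denom == 0:
        raise NumericsError("GR undefined: control did not grow (x_ctrl = x0)")
    return 2.0 ** (math.log2(count / count_t0) / denom) - 1.0


def dose_response(
    lineages: Mapping[tuple[float, int], LineageTable],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-replicate GR table and per-dose mean +/- SE summary.

    ``lineages`` maps (dose_nM, replicate) to a lineage; a dose-0 control must
    be present for every replicate and each replicate is normalized by its own
    control (replicates are independent end to end, so the SE over replicates
    reflects full pipeline variance).
    """
    reps = sorted({k[1] for k in lineages})
    doses = sorted({k[0] for k in lineages})
    for rep in reps:
        if (0.0, rep) not in lineages:
            raise InputError(f"missing dose-0 control for replicate {rep}")
    rows = []
    for dose in doses:
        for rep in reps:
            if (dose, rep) not in lineages:
                continue
            lin = lineages[(dose, rep)]
            ctrl = lineages[(0.0, rep)]
            n0 = _alive_at(lin.records, 0.0)
            rows.append(
                {
                    "drug": lin.drug,
                    "concentration_nM": dose,
                    "replicate": rep,
                    "cell_count__time0": n0,
                    "cell_count__ctrl": final_count(ctrl),
                    "cell_count": final_count(lin),
                    "GRvalue": gr_value(final_count(lin), final_count(ctrl), n0),
                }
            )
    table = pd.DataFrame(rows)
    summary = (
        table.groupby("concentration_nM")["GRvalue"]
        .agg(mean="mean", se=lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0)
        .reset_index()
    )
    return table, summary


def death_fraction_window(
    lineage: LineageTable, window: tuple[float, float] | None = None
) -> tuple[float, int, int]:
    """Fraction of at-risk cells dying within a time window.

    Defaults to the last hour of the run (what an end-point viability stain
    would observe).  Returns (fraction, deaths, cells at risk at window start).
    """
    w0, w1 = window if window is not None else (lineage.duration - 1.0, lineage.duration)
    deaths = sum(
        1 for r in lineage.records if r.fate == "died" and w0 < r.end_time <= w1
    )
    at_risk = _alive_at(lineage.records, w0)
    return (deaths / at_risk if at_risk else 0.0), deaths, at_risk


# ---------------------------------------------------------------- dendrogram


@dataclass(frozen=True)
class Segment:
    """One drawable dendrogram piece in (time, lane) coordinates."""

    kind: str  # 'cell' (horizontal) or 'division' (vertical)
    x0: float
    x1: float
    y0: float
    y1: float
    cell_id: tuple[int, int] | None = None


def dendrogram_layout(lineage: LineageTable) -> list[Segment]:
    """Lay out the lineage as horizontal lifetime segments plus vertical
    division connectors; leaves are placed depth-first, elder daughter first."""
    lineage.validate()
    y: dict[tuple[int, int], float] = {}
    next_leaf = [0.0]

    def place(rec: CellRecord) -> float:
        kids = sorted(lineage.children(rec.cell_id), key=lambda r: r.index)
        if not kids:
            y[rec.cell_id] = next_leaf[0]
            next_leaf[0] += 1.0
        else:
            ys = [place(k) for k in kids]
            y[rec.cell_id] = float(np.mean(ys))
        return y[rec.cell_id]

    segments: list[Segment] = []
    for root in sorted(lineage.roots(), key=lambda r: r.index):
        place(root)
    for rec in lineage.records:
        segments.append(
            Segment("cell", rec.birth_time, rec.end_time, y[rec.cell_id], y[rec.cell_id], rec.cell_id)
        )
        kids = lineage.children(rec.cell_id)
        if kids:
            ys = [y[k.cell_id] for k in kids]
            segments.append(
                Segment("division", rec.end_time, rec.end_time, min(ys), max(ys), rec.cell_id)
            )
    return segments


def export_newick(lineage: LineageTable) -> str:
    """Newick text, one tree per Gen-1 root cell (one per line).

    Branch lengths are cell lifetimes in hours; every node is labeled
    ``g<generation>_i<index>``.
    """
    lineage.validate()

    def render(rec: CellRecord) -> str:
        label = f"g{rec.generation}_i{rec.index}"
        kids = sorted(lineage.children(rec.cell_id), key=lambda r: r.index)
        inner = f"({','.join(render(k) for k in kids)})" if kids else ""
        return f"{inner}{label}:{rec.lifetime:.10g}"

    return "\n".join(
        render(root) + ";" for root in sorted(lineage.roots(), key=lambda r: r.index)
    )


# ------------------------------------------------------- cycle progress


@dataclass(frozen=True)
class Reference:
    """Deterministic average-cell reference for progress estimation."""

    period: float
    trough_times: np.ndarray
    marker_peaks: dict[str, float]


def _averaged_marker(
    traj: Trajectory,
    specs: ModelSpecs,
    reference: Reference | None,
) -> np.ndarray:
    """Average of the progress markers, each normalized by its own observed
    peak (falling back to the reference peak when the cell spans less than a
    full cycle and its own maximum is unrepresentative)."""
    if not specs.progress_markers:
        raise ConfigurationError("model declares no progress markers")
    cols = []
    for name in specs.progress_markers:
        series = traj.states[:, specs.index(name)]
        top = float(series.max())
        if reference is not None:
            ref_peak = reference.marker_peaks.get(name, top)
            if top < 0.5 * ref_peak:
                top = ref_peak
        if top <= 0:
            top = 1.0
        cols.append(series / top)
    return np.mean(cols, axis=0)


def _find_troughs(
    A: np.ndarray,
    times: np.ndarray,
    period_hint: float,
    trough_frac: float = 0.05,
) -> np.ndarray:
    """Times of per-cycle minima of the averaged marker.

    Candidate local minima are filtered to those near the global floor
    (below ``trough_frac`` of the trace maximum), which rejects the shallow
    dips between adjacent within-cycle markers.
    """
    dt = float(np.median(np.diff(times)))
    distance = max(1, int(round(0.5 * period_hint / dt)))
    idx, _ = find_peaks(-A, distance=distance)
    floor = trough_frac * float(A.max())
    idx = idx[A[idx] <= floor]
    return times[idx]


def deterministic_reference(
    params: MinimalModelParams | None = None, duration_h: float = 72.0
) -> Reference:
    """Average-cell trajectory statistics from a noise-free simulation."""
    from .model import load_minimal_model, run_single_cell

    params = params if params is not None else MinimalModelParams()
    det = dataclasses.replace(params, noise=False, drug=None)
    traj = run_single_cell(serum_starved_state(det), duration_h, det, rng=0)
    specs, _ = load_minimal_model(det)
    peaks = {
        name: float(traj.states[:, specs.index(name)].max())
        for name in specs.progress_markers
    }
    A = _averaged_marker(traj, specs, None)
    troughs = _find_troughs(A, traj.times, params.T0)
    if troughs.size < 2:
        raise NumericsError("reference run shows fewer than two marker troughs")
    period = float(np.median(np.diff(troughs)))
    return Reference(period, troughs, peaks)


def cycle_progress(
    trajectory: Trajectory,
    specs: ModelSpecs | None = None,
    reference: Reference | None = None,
    at_time: float = 0.0,
) -> float:
    """Fractional cell-cycle progress at ``at_time`` of a trajectory.

    Progress is time since the previous trough of the averaged normalized
    markers, divided by the local trough-to-trough interval; when the
    bracketing trough is unobserved the reference period substitutes for the
    denominator.  Result lies in [0, 1).
    """
    specs = specs if specs is not None else trajectory.specs
    A = _averaged_marker(trajectory, specs, reference)
    if float(A.max() - A.min()) < 1e-9:
        raise NumericsError("cycle progress undefined: markers are flat")
    period_hint = reference.period if reference is not None else _default_period(trajectory)
    troughs = _find_troughs(A, trajectory.times, period_hint)
    eps = 1e-9
    prev = troughs[troughs <= at_time + eps]
    nxt = troughs[troughs > at_time + eps]
    if prev.size and nxt.size:
        p = (at_time - prev[-1]) / (nxt[0] - prev[-1])
    elif nxt.size:
        if reference is None:
            raise NumericsError("previous trough unobserved and no reference period")
        p = 1.0 - (nxt[0] - at_time) / reference.period
    elif prev.size:
        if reference is None:
            raise NumericsError("next trough unobserved and no reference period")
        p = (at_time - prev[-1]) / reference.period
    else:
        raise NumericsError("no marker troughs observed; cannot estimate progress")
    return float(min(max(p % 1.0 if p >= 1.0 or p < 0.0 else p, 0.0), 1.0 - 1e-12))


def _default_period(trajectory: Trajectory) -> float:
    return max(float(trajectory.times[-1]) / 3.0, 1.0)


# ------------------------------------- division probability vs progress


@dataclass(frozen=True)
class ProgressCurve:
    """Division probability per cycle-progress bin (0.01-wide bins)."""

    bin_lefts: np.ndarray
    p_divide: np.ndarray
    n_effective: np.ndarray
    method: str  # 'kde' or 'binned'


def division_probability_by_progress(
    progress: np.ndarray,
    divided: np.ndarray,
    bin_width: float = 0.01,
    min_group_kde: int = 5,
) -> ProgressCurve:
    """Estimate P(divide | progress) on a fixed progress grid.

    Cells are split into dividing and non-dividing groups; a Gaussian KDE
    (Scott bandwidth) estimates each group's progress density and the
    probability per bin is the dividing group's share of the combined density
    weighted by group sizes.  Groups smaller than ``min_group_kde`` fall back
    to direct binning (method flag 'binned').
    """
    progress = np.asarray(progress, float)
    divided = np.asarray(divided, bool)
    if progress.size == 0 or progress.shape != divided.shape:
        raise InputError("progress and outcome arrays must be equal-length, non-empty")
    lefts = np.arange(0.0, 1.0, bin_width)
    centers = lefts + bin_width / 2.0
    div, non = progress[divided], progress[~divided]
    use_kde = min(div.size, non.size) >= min_group_kde or (
        max(div.size, non.size) >= min_group_kde and min(div.size, non.size) == 0
    )
    if use_kde:
        f_div = _group_density(div, centers)
        f_non = _group_density(non, centers)
        w_div = div.size * f_div
        w_non = non.size * f_non
        total = w_div + w_non
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(total > 1e-12, w_div / np.where(total > 0, total, 1.0), np.nan)
        return ProgressCurve(lefts, p, total * bin_width, "kde")
    idx = np.clip((progress / bin_width).astype(int), 0, lefts.size - 1)
    n_tot = np.bincount(idx, minlength=lefts.size).astype(float)
    n_div = np.bincount(idx[divided], minlength=lefts.size).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_tot > 0, n_div / np.where(n_tot > 0, n_tot, 1.0), np.nan)
    return ProgressCurve(lefts, p, n_tot, "binned")


def _group_density(samples: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Gaussian KDE of a cycle-progress sample, periodic on [0, 1).

    Progress is circular (0.99 and 0.01 are one grid step apart), so the
    density is evaluated with wrap-around replicas; this keeps mass from
    leaking past the 0/1 boundary and distorting probabilities near it.
    """
    if samples.size == 0:
        return np.zeros_like(grid)
    if samples.size < 2 or float(np.std(samples)) < 1e-12:
        # degenerate group: narrow Gaussian at the common value
        h = 0.01
        return sum(
            np.exp(-0.5 * ((grid + k - samples.mean()) / h) ** 2)
            / (h * np.sqrt(2 * np.pi))
            for k in (-1.0, 0.0, 1.0)
        )
    kde = gaussian_kde(samples)
    return kde(grid) + kde(grid - 1.0) + kde(grid + 1.0)


def crossing_progress(curve: ProgressCurve, level: float = 0.5) -> float | None:
    """Progress at the first upward crossing of ``level``, interpolated
    between bin centers; None if the curve never rises through it."""
    centers = curve.bin_lefts + np.median(np.diff(curve.bin_lefts)) / 2.0
    p = curve.p_divide
    ok = np.isfinite(p)
    c, v = centers[ok], p[ok]
    for i in range(1, v.size):
        if v[i - 1] < level <= v[i]:
            frac = (level - v[i - 1]) / (v[i] - v[i - 1])
            return float(c[i - 1] + frac * (c[i] - c[i - 1]))
    return None


def progress_at_dose(rep: ReplicateResult, reference: Reference) -> np.ndarray:
    """Cycle progress of each Gen-1 cell at drug addition (t = 0).

    Estimated from the cell's growth-stimulated Gen-0 trajectory at the
    asynchronization sample point, i.e. from its pre-dose marker dynamics.
    """
    pool = rep.pool
    out = np.empty(len(pool.gen0_trajectories))
    for i, traj in enumerate(pool.gen0_trajectories):
        out[i] = cycle_progress(
            traj, pool.specs, reference, at_time=float(pool.sample_times[i])
        )
    return out


def division_probability_analysis(
    result: PopulationResult,
    params: MinimalModelParams | None = None,
    reference: Reference | None = None,
) -> dict:
    """Pooled Gen-1/Gen-2 division-probability-vs-progress curves.

    Progress is measured at dose time for every Gen-1 mother; Gen-2 outcomes
    are attributed to the mother's progress (the axis of interest is the
    cycle position when the drug arrived).
    """
    params = params if params is not None else MinimalModelParams()
    if reference is None:
        reference = deterministic_reference(params)
    prog1, out1, prog2, out2 = [], [], [], []
    for rep in result.replicates:
        progress = progress_at_dose(rep, reference)
        lin = rep.lineage
        for root in lin.roots():
            p = progress[root.index]
            prog1.append(p)
            out1.append(root.fate == "divided")
            for child in lin.children(root.cell_id):
                prog2.append(p)
                out2.append(child.fate == "divided")
    curve1 = division_probability_by_progress(np.asarray(prog1), np.asarray(out1))
    curve2 = (
        division_probability_by_progress(np.asarray(prog2), np.asarray(out2))
        if prog2
        else None
    )
    return {
        "progress_gen1": np.asarray(prog1),
        "divided_gen1": np.asarray(out1),
        "progress_gen2": np.asarray(prog2),
        "divided_gen2": np.asarray(out2),
        "curve_gen1": curve1,
        "curve_gen2": curve2,
    }


# ----------------------------------------------------------------- sweeps


def _set_param_path(params: MinimalModelParams, path: str, value):
    parts = path.split(".")
    if len(parts) == 1:
        if not hasattr(params, parts[0]):
            raise ConfigurationError(f"unknown parameter path {path!r}")
        return dataclasses.replace(params, **{parts[0]: value})
    head, rest = parts[0], ".".join(parts[1:])
    child = getattr(params, head, None)
    if child is None or not dataclasses.is_dataclass(child):
        raise ConfigurationError(f"unknown parameter path {path!r}")
    return dataclasses.replace(params, **{head: _set_param_path(child, rest, value)})


def sweep_division_probability(
    params: MinimalModelParams,
    parameter_path: str,
    values: Sequence[float],
    n_cells: int,
    duration_h: float = 72.0,
    seed: int = 0,
    drug=None,
) -> list[float]:
    """Fraction of Gen-1 cells with at least one division, per swept value."""
    if n_cells < 1:
        raise InputError("n_cells must be >= 1")
    out = []
    for v in values:
        p = _set_param_path(params, parameter_path, v)
        res = simulate_population(
            seed=seed,
            n_start=n_cells,
            duration_h=duration_h,
            params=p,
            drug=drug,
            keep_trajectories=False,
        )
        lin = res.replicates[0].lineage
        n_div = sum(1 for r in lin.roots() if r.fate == "divided")
        out.append(n_div / n_cells)
    return out
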
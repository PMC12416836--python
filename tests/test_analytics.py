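"""Lineage analytics: census identity, GR metric identities, doubling time,
death windows, Newick round-trips, progress estimation and KDE curves."""

import dataclasses

import dendropy
import numpy as np
import pytest

import lineagesim as ls
from lineagesim.analytics import (
    ProgressCurve,
    Reference,
    _averaged_marker,
    death_fraction_window,
    final_count,
    progress_at_dose,
)
from lineagesim.errors import ConfigurationError, InputError, NumericsError
from lineagesim.fixtures import make_fixture, make_random_lineage
from lineagesim.population import CellRecord, LineageTable


# ------------------------------------------------------------ alive counts


def test_alive_count_trivial_cases():
    lin = LineageTable(
        [CellRecord(1, 0, None, 0.0, 72.0, "censored")], duration=72.0
    )
    grid = np.linspace(0, 72, 10)
    assert np.all(ls.alive_count_curve(lin, grid) == 1)

    div = LineageTable(
        [
            CellRecord(1, 0, None, 0.0, 10.0, "divided", 10.0),
            CellRecord(2, 0, (1, 0), 10.0, 72.0, "censored"),
            CellRecord(2, 1, (1, 0), 10.0, 72.0, "censored"),
        ],
        duration=72.0,
    )
    assert ls.alive_count_curve(div, np.array([5.0]))[0] == 1
    assert ls.alive_count_curve(div, np.array([15.0]))[0] == 2


def test_alive_count_rejects_grid_beyond_duration():
    lin = LineageTable([CellRecord(1, 0, None, 0.0, 72.0, "censored")], duration=72.0)
    with pytest.raises(InputError):
        ls.alive_count_curve(lin, np.array([80.0]))


def test_census_identity_on_random_lineages():
    """alive(t) = n_start + divisions_before(t) - deaths_before(t) on 100
    randomly generated lineages."""
    grid = np.linspace(0.0, 72.0, 25)
    for seed in range(100):
        lin = make_random_lineage(seed=seed, n_start=5)
        counts = ls.alive_count_curve(lin, grid)
        for t, c in zip(grid, counts):
            divs = sum(
                1 for r in lin.records if r.fate == "divided" and r.end_time <= t
            )
            deaths = sum(1 for r in lin.records if r.fate == "died" and r.end_time <= t)
            assert c == 5 + divs - deaths


# ------------------------------------------------------------ doubling time


def test_doubling_time_closed_form_exponential():
    t = np.linspace(0, 96, 961)
    curve = 100 * 2 ** (t / 48.0)
    assert ls.doubling_time(curve, t, 100) == pytest.approx(48.0, abs=0.2)


def test_doubling_time_flat_curve_is_none():
    t = np.linspace(0, 72, 73)
    assert ls.doubling_time(np.full_like(t, 100.0), t, 100) is None


def test_doubling_time_exact_step():
    t = np.array([0.0, 30.0, 60.0])
    curve = np.array([100.0, 200.0, 200.0])
    assert ls.doubling_time(curve, t, 100) == pytest.approx(30.0)


# --------------------------------------------------------------- GR metric


def test_gr_identities_exact():
    assert ls.gr_value(400, 400, 100) == pytest.approx(1.0)
    assert ls.gr_value(100, 400, 100) == pytest.approx(0.0)
    assert ls.gr_value(25, 400, 100) == pytest.approx(-0.5)


def test_gr_error_cases():
    with pytest.raises(InputError):
        ls.gr_value(0, 400, 100)
    with pytest.raises(NumericsError):
        ls.gr_value(200, 100, 100)


def test_dose_response_controls_give_gr_one():
    lin = make_random_lineage(seed=1, n_start=8)
    tables = {}
    for rep in range(3):
        l = make_random_lineage(seed=rep, n_start=8)
        tables[(0.0, rep)] = l
        tables[(5.0, rep)] = l  # "treated" identical to control
    table, summary = ls.dose_response(tables)
    treated = table[table.concentration_nM == 5.0]
    assert np.allclose(treated.GRvalue, 1.0)
    assert summary.loc[summary.concentration_nM == 5.0, "se"].iloc[0] == pytest.approx(0.0)


def test_dose_response_requires_controls():
    with pytest.raises(InputError):
        ls.dose_response({(5.0, 0): make_random_lineage(seed=0, n_start=5)})


# ---------------------------------------------------------- death fraction


def test_death_fraction_window_cases():
    none = LineageTable([CellRecord(1, 0, None, 0.0, 72.0, "censored")], duration=72.0)
    assert death_fraction_window(none)[0] == 0.0

    all_die = LineageTable(
        [CellRecord(1, i, None, 0.0, 71.5, "died") for i in range(4)], duration=72.0
    )
    frac, deaths, at_risk = death_fraction_window(all_die)
    assert (frac, deaths, at_risk) == (1.0, 4, 4)

    records = [CellRecord(1, i, None, 0.0, 72.0, "censored") for i in range(47)]
    records += [CellRecord(1, 47 + i, None, 0.0, 71.2 + 0.1 * i, "died") for i in range(3)]
    mixed = LineageTable(records, duration=72.0)
    frac, deaths, at_risk = death_fraction_window(mixed)
    assert deaths == 3 and at_risk == 50
    assert frac == pytest.approx(0.06)


# ------------------------------------------------------ dendrogram, newick


def test_single_cell_layout_and_newick():
    lin = LineageTable([CellRecord(1, 0, None, 0.0, 72.0, "censored")], duration=72.0)
    segments = ls.dendrogram_layout(lin)
    assert len(segments) == 1 and segments[0].kind == "cell"
    assert ls.export_newick(lin) == "g1_i0:72;"


def test_one_division_branch_lengths():
    lin = LineageTable(
        [
            CellRecord(1, 0, None, 0.0, 24.0, "divided", 24.0),
            CellRecord(2, 0, (1, 0), 24.0, 72.0, "censored"),
            CellRecord(2, 1, (1, 0), 24.0, 72.0, "censored"),
        ],
        duration=72.0,
    )
    tree = dendropy.Tree.get(data=ls.export_newick(lin), schema="newick")
    lengths = sorted(e.length for e in tree.edges() if e.length is not None)
    assert lengths == pytest.approx([24.0, 48.0, 48.0])


def test_newick_round_trip_preserves_topology_and_length():
    lin = make_random_lineage(seed=4, n_start=6)
    text = ls.export_newick(lin)
    total = 0.0
    n_leaves = 0
    for line in text.splitlines():
        tree = dendropy.Tree.get(data=line, schema="newick")
        total += tree.length()
        n_leaves += len(tree.leaf_nodes())
    counts = lin.counts()
    assert n_leaves == counts["censored"] + counts["died"]
    direct = sum(r.lifetime for r in lin.records)
    assert total == pytest.approx(direct, rel=1e-9)


def test_dendrogram_segments_cover_every_cell(control_result):
    lin = control_result.replicates[0].lineage
    segments = ls.dendrogram_layout(lin)
    cell_segments = [s for s in segments if s.kind == "cell"]
    assert len(cell_segments) == len(lin)
    division_segments = [s for s in segments if s.kind == "division"]
    assert len(division_segments) == lin.counts()["divided"]


# --------------------------------------------------------- cycle progress


def test_progress_zero_at_trough_and_half_between(noise_free, reference):
    traj = ls.run_single_cell(ls.serum_starved_state(noise_free), 72.0, noise_free, rng=0)
    ref = ls.deterministic_reference(noise_free)
    t0, t1 = ref.trough_times[0], ref.trough_times[1]
    assert ls.cycle_progress(traj, reference=ref, at_time=t0) == pytest.approx(0.0, abs=1e-6)
    assert ls.cycle_progress(traj, reference=ref, at_time=(t0 + t1) / 2) == pytest.approx(
        0.5, abs=0.005
    )


def test_progress_monotone_between_troughs(noise_free):
    traj = ls.run_single_cell(ls.serum_starved_state(noise_free), 72.0, noise_free, rng=0)
    ref = ls.deterministic_reference(noise_free)
    ts = np.linspace(ref.trough_times[0] + 0.2, ref.trough_times[1] - 0.2, 15)
    ps = [ls.cycle_progress(traj, reference=ref, at_time=t) for t in ts]
    assert np.all(np.diff(ps) > 0)


def test_progress_undefined_for_flat_markers():
    params = dataclasses.replace(ls.MinimalModelParams(), GF=0.0, noise=False)
    traj = ls.run_single_cell(ls.serum_starved_state(params), 24.0, params, rng=0)
    with pytest.raises(NumericsError):
        ls.cycle_progress(traj, at_time=5.0)


def test_progress_matches_true_phase_noise_free(noise_free):
    """Estimated progress equals the trough-referenced phase fraction."""
    ref = ls.deterministic_reference(noise_free)
    drug = ls.builtin_drug("palbociclib", 1900.0)
    res = ls.simulate_population(
        seed=3, n_start=50, duration_h=72.0, params=noise_free, drug=drug
    )
    rep = res.replicates[0]
    est = progress_at_dose(rep, ref)
    true_tau = (rep.pool.states[:, 0] - noise_free.cycle_start_phase) % 1.0
    err = np.abs((est - true_tau + 0.5) % 1.0 - 0.5)
    assert err.max() < 0.01


# ------------------------------------------- division probability curves


def test_all_dividers_give_unit_probability():
    rng = np.random.default_rng(0)
    progress = rng.uniform(0, 1, 200)
    curve = ls.division_probability_by_progress(progress, np.ones(200, bool))
    populated = curve.n_effective > 0.05
    assert np.all(curve.p_divide[populated] == pytest.approx(1.0))


def test_step_outcome_crossing_recovered():
    rng = np.random.default_rng(1)
    progress = rng.uniform(0, 1, 500)
    divided = progress >= 0.1
    curve = ls.division_probability_by_progress(progress, divided)
    x = ls.crossing_progress(curve)
    assert x == pytest.approx(0.1, abs=0.03)


def test_kde_curve_agrees_with_coarse_binning():
    rng = np.random.default_rng(2)
    progress = rng.uniform(0, 1, 500)
    p_true = 1.0 / (1.0 + np.exp(-(progress - 0.5) / 0.15))
    divided = rng.random(500) < p_true
    kde = ls.division_probability_by_progress(progress, divided)
    # 0.05-bin empirical frequencies
    for left in np.arange(0.1, 0.9, 0.05):
        sel = (progress >= left) & (progress < left + 0.05)
        if sel.sum() < 10:
            continue
        emp = divided[sel].mean()
        in_bin = (kde.bin_lefts >= left) & (kde.bin_lefts < left + 0.05)
        # allow for the binned oracle's own binomial sampling error
        se = np.sqrt(max(emp * (1 - emp), 0.05) / sel.sum())
        assert np.nanmean(kde.p_divide[in_bin]) == pytest.approx(emp, abs=0.1 + 2.5 * se)


def test_small_groups_fall_back_to_binning():
    progress = np.array([0.1, 0.2, 0.6, 0.7])
    divided = np.array([False, False, True, True])
    curve = ls.division_probability_by_progress(progress, divided)
    assert curve.method == "binned"


def test_empty_progress_rejected():
    with pytest.raises(InputError):
        ls.division_probability_by_progress(np.array([]), np.array([], bool))


# ----------------------------------------------------------------- sweeps


def test_growth_factor_sweep_is_on_off(params):
    probs = ls.sweep_division_probability(params, "GF", [0.0, 1.0], n_cells=15, seed=5)
    assert probs[0] == 0.0
    assert probs[1] > 0.8


def test_speed_coupling_sweep_nondecreasing(noise_free):
    probs = ls.sweep_division_probability(
        noise_free, "b_E", [0.2, 1.5], n_cells=40, duration_h=12.0, seed=6
    )
    assert probs[0] <= probs[1]
    assert probs[1] > probs[0]  # stronger coupling, faster cycling


def test_sweep_input_validation(params):
    with pytest.raises(InputError):
        ls.sweep_division_probability(params, "GF", [0.0], n_cells=0)
    with pytest.raises(ConfigurationError):
        ls.sweep_division_probability(params, "no.such.path", [1.0], n_cells=3)
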
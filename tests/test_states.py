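"""State-matrix compilation, z-scoring, PCA/PLSR recovery and projection."""

import numpy as np
import pandas as pd
import pytest

import lineagesim as ls
from lineagesim.errors import ConfigurationError, InputError, SchemaError
from lineagesim.fixtures import make_fixture
from lineagesim.states import (
    categorize_divisions,
    compile_state_matrix,
    pca_fit,
    plsr_cv_r2,
    plsr_fit,
    project,
    top_loadings,
    zscore_apply,
    zscore_fit,
)


def _planted_data(seed=0, n=1000, p=12, snr=3.0):
    rng = np.random.default_rng(seed)
    d = rng.normal(size=p)
    d /= np.linalg.norm(d)
    z = rng.normal(size=n)
    X = snr * np.outer(z, d) + rng.normal(size=(n, p))
    species = tuple(f"s{i}" for i in range(p))
    return X, z, d, species


def _cos(a, b):
    return abs(float(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b)))


# ----------------------------------------------------------- compilation


def test_state_matrix_one_row_per_mother(control_result):
    sm = compile_state_matrix(control_result.replicates)
    assert sm.X.shape[0] == 20
    assert sm.provenance.shape[0] == 20
    assert np.all(sm.y >= 0)
    lin = control_result.replicates[0].lineage
    # subtree oracle: recount divisions per mother directly
    for row, root in zip(range(20), sorted(lin.roots(), key=lambda r: r.index)):
        direct = sum(1 for r in lin.subtree(root.cell_id) if r.fate == "divided")
        assert sm.y[row] == direct


def test_subtree_division_count_on_known_fixture():
    # 1 mother: root divides, both daughters divide, both granddaughters of
    # the first daughter divide -> 7 division events in the subtree
    fx = make_fixture(
        n_roots=1,
        division_times={
            (1, 0): 10.0,
            (2, 0): 25.0,
            (2, 1): 30.0,
            (3, 0): 45.0,
            (3, 1): 47.0,
            (3, 2): 50.0,
            (3, 3): 52.0,
        },
    )

    class _Rep:
        lineage = fx.lineage
        trajectories = fx.trajectories
        specs = fx.specs

    sm = compile_state_matrix([_Rep()])
    assert sm.y[0] == 7
    assert sm.category[0] == "moderate"


def test_division_categories_half_open_boundaries():
    cats = categorize_divisions(np.array([0, 5, 6, 15, 16, 40]))
    assert list(cats) == ["low", "low", "moderate", "moderate", "high", "high"]


def test_missing_trajectory_names_cell(control_result):
    rep = control_result.replicates[0]

    class _Broken:
        lineage = rep.lineage
        trajectories = {}
        specs = rep.specs

    with pytest.raises(InputError, match=r"\(1, 0\)"):
        compile_state_matrix([_Broken()])


# -------------------------------------------------------------- z-scoring


def test_zscore_drops_constant_columns():
    X = np.column_stack([np.random.default_rng(0).normal(size=50), np.full(50, 7.0)])
    scaler = zscore_fit(X, ("a", "const"))
    assert scaler.dropped == ("const",)
    Xz = zscore_apply(X, scaler, ("a", "const"))
    assert Xz.shape == (50, 1)
    assert abs(Xz.mean()) < 1e-12
    assert Xz.std() == pytest.approx(1.0)


def test_zscore_refit_on_transformed_is_identity():
    rng = np.random.default_rng(1)
    X = rng.normal(5.0, 2.0, size=(100, 4))
    species = tuple("abcd")
    scaler = zscore_fit(X, species)
    Xz = zscore_apply(X, scaler, species)
    refit = zscore_fit(Xz, scaler.species)
    assert np.allclose(refit.mean, 0.0, atol=1e-12)
    assert np.allclose(refit.sd, 1.0, atol=1e-12)


def test_zscore_requires_two_rows():
    with pytest.raises(InputError):
        zscore_fit(np.ones((1, 3)), ("a", "b", "c"))


# ------------------------------------------------------------------- PCA


def test_pca_recovers_planted_direction():
    X, z, d, species = _planted_data(seed=3)
    scaler = zscore_fit(X, species)
    Xz = zscore_apply(X, scaler, species)
    fit = pca_fit(Xz, scaler.species, n_components=4)
    assert _cos(fit.components[0], d) > 0.95
    # variance accounting: ratios sum to fraction of total variance captured
    assert np.all(np.diff(fit.explained_variance_ratio) <= 1e-12)
    full = pca_fit(Xz, scaler.species)
    assert np.sum(full.explained_variance) == pytest.approx(
        np.sum(Xz.var(axis=0, ddof=1)), rel=1e-9
    )


def test_isotropic_noise_has_flat_spectrum():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(2000, 6))
    species = tuple(f"s{i}" for i in range(6))
    fit = pca_fit(X - X.mean(0), species)
    assert fit.explained_variance_ratio[0] / fit.explained_variance_ratio[-1] < 1.3


def test_projection_identities():
    X, z, d, species = _planted_data(seed=5, n=400)
    scaler = zscore_fit(X, species)
    Xz = zscore_apply(X, scaler, species)
    fit = pca_fit(Xz, scaler.species, n_components=3)
    # training data projects onto stored scores
    assert np.allclose(project(X, scaler, fit, species), fit.scores, atol=1e-9)
    # the column-mean row maps to the origin
    mean_row = X.mean(axis=0, keepdims=True)
    assert np.allclose(project(mean_row, scaler, fit, species), 0.0, atol=1e-9)


def test_projection_shift_along_planted_direction_moves_first_score():
    X, z, d, species = _planted_data(seed=6, n=600, snr=4.0)
    scaler = zscore_fit(X, species)
    Xz = zscore_apply(X, scaler, species)
    fit = pca_fit(Xz, scaler.species, n_components=3)
    shifted = X + 2.0 * d
    delta = project(shifted, scaler, fit, species) - project(X, scaler, fit, species)
    assert np.abs(delta[:, 0]).mean() > 10 * np.abs(delta[:, 1:]).mean()


def test_projection_species_mismatch_names_missing():
    X, _, _, species = _planted_data(n=50)
    scaler = zscore_fit(X, species)
    fit = pca_fit(zscore_apply(X, scaler, species), scaler.species)
    with pytest.raises(SchemaError, match="s0"):
        project(X[:, 1:], scaler, fit, species[1:])


def test_top_loadings_clipped_with_warning():
    X, _, _, species = _planted_data(n=100, p=5)
    fit = pca_fit(X - X.mean(0), species)
    with pytest.warns(UserWarning):
        table = top_loadings(fit, 0, k=20)
    assert len(table) == 5


# ------------------------------------------------------------------ PLSR


def test_plsr_single_informative_column_dominates():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(300, 5))
    y = 3.0 * X[:, 2] + rng.normal(0, 0.1, 300)
    species = tuple(f"s{i}" for i in range(5))
    fit = plsr_fit(X - X.mean(0), y, species, n_components=2)
    table = top_loadings(fit, 0, k=5)
    assert table.species.iloc[0] == "s2"


def test_plsr_recovers_direction_pca_ranks_second():
    rng = np.random.default_rng(8)
    n, p = 1000, 10
    d = np.zeros(p)
    d[0] = 1.0
    nuisance = np.zeros(p)
    nuisance[1] = 1.0
    z = rng.normal(size=n)
    X = (
        3.0 * np.outer(z, d)
        + 6.0 * np.outer(rng.normal(size=n), nuisance)  # larger, y-unrelated
        + rng.normal(size=(n, p))
    )
    y = z
    species = tuple(f"s{i}" for i in range(p))
    Xc = X - X.mean(0)
    pca = pca_fit(Xc, species)
    assert _cos(pca.components[0], nuisance) > 0.95  # PCA ranks nuisance first
    pls = plsr_fit(Xc, y, species, n_components=2)
    assert _cos(pls.x_loadings[:, 0], d) > 0.95


def test_plsr_constant_response_rejected():
    X = np.random.default_rng(9).normal(size=(50, 3))
    with pytest.raises(ConfigurationError):
        plsr_fit(X, np.ones(50), ("a", "b", "c"))


def test_plsr_cv_r2_nonpositive_for_unrelated_response():
    rng = np.random.default_rng(10)
    X = rng.normal(size=(200, 6))
    y = rng.normal(size=200)
    assert plsr_cv_r2(X - X.mean(0), y) < 0.1


def test_expression_pathway_tops_division_loadings():
    """On a control population the heritable expression state (gene state,
    transcripts, smoothed expression activity) carries the division-count
    signal: all three occupy the top loadings of PLSR component 1."""
    res = ls.simulate_population(seed=11, n_start=40, duration_h=72.0)
    sm = compile_state_matrix(res.replicates)
    scaler = zscore_fit(sm.X, sm.species)
    Xz = zscore_apply(sm.X, scaler, sm.species)
    fit = plsr_fit(Xz, sm.y, scaler.species, n_components=2)
    top3 = set(top_loadings(fit, 0, k=3).species)
    assert "expression_activity" in top3
    assert {"gene_state", "transcripts"} & top3
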
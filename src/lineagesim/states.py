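"""Mother-cell initial-state heterogeneity analysis.

Compiles the Gen-1 initial conditions of a set of simulations into a
cells-by-species matrix, labels each mother with the total number of
division events in her lineage subtree, and relates states to proliferative
outcome by PCA (with top-loading inspection and projection of held-out
conditions onto the control-fitted axes) and single-response PLSR.

Standardization, PCA and PLSR are delegated to scikit-learn; this module
owns the matrix compilation, the zero-variance handling, the division-count
categories and the projection bookkeeping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA

from .errors import ConfigurationError, InputError, SchemaError
from .population import LineageTable, ReplicateResult

__all__ = [
    "StateMatrix",
    "Scaler",
    "FittedProjection",
    "compile_state_matrix",
    "categorize_divisions",
    "zscore_fit",
    "zscore_apply",
    "pca_fit",
    "top_loadings",
    "project",
    "plsr_fit",
    "plsr_cv_r2",
]

#: Division-count category boundaries, half-open: low [0, 6), moderate
#: [6, 16), high [16, inf).
CATEGORY_BOUNDS = (6, 16)


def categorize_divisions(y: np.ndarray, bounds: tuple[int, int] = CATEGORY_BOUNDS):
    y = np.asarray(y)
    lo, hi = bounds
    return np.where(y < lo, "low", np.where(y < hi, "moderate", "high"))


@dataclass
class StateMatrix:
    """Gen-1 mother states with division-count labels and row provenance."""

    X: np.ndarray
    species: tuple[str, ...]
    y: np.ndarray
    category: np.ndarray
    provenance: pd.DataFrame  # columns: drug, dose, replicate, generation, index

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.species))
        df["n_divisions"] = self.y
        df["category"] = self.category
        return pd.concat([self.provenance.reset_index(drop=True), df], axis=1)


def _subtree_divisions(lineage: LineageTable, root_id, window=None) -> int:
    n = 0
    for rec in lineage.subtree(root_id):
        if rec.fate == "divided":
            if window is None or (window[0] <= rec.division_time <= window[1]):
                n += 1
    return n


def compile_state_matrix(
    replicates: list[ReplicateResult],
    window: tuple[float, float] | None = None,
) -> StateMatrix:
    """One row per Gen-1 mother across all supplied replicate results.

    ``y`` counts every division event in the mother's subtree (the mother's
    own included), optionally restricted to a time window.
    """
    if not replicates:
        raise InputError("no replicate results supplied")
    species = replicates[0].specs.species_all
    rows, ys, prov = [], [], []
    for rep in replicates:
        lin = rep.lineage
        for root in sorted(lin.roots(), key=lambda r: r.index):
            traj = rep.trajectories.get(root.cell_id)
            if traj is None:
                raise InputError(
                    f"missing trajectory for Gen-1 cell {root.cell_id} "
                    f"(replicate {lin.replicate})"
                )
            if traj.specs.species_all != species:
                raise SchemaError("replicates have inconsistent species lists")
            rows.append(traj.states[0])
            ys.append(_subtree_divisions(lin, root.cell_id, window))
            prov.append(
                {
                    "drug": lin.drug,
                    "dose": lin.dose,
                    "replicate": lin.replicate,
                    "generation": root.generation,
                    "index": root.index,
                }
            )
    X = np.stack(rows)
    y = np.asarray(ys, dtype=int)
    return StateMatrix(X, species, y, categorize_divisions(y), pd.DataFrame(prov))


# ---------------------------------------------------------------- scaling


@dataclass(frozen=True)
class Scaler:
    """Column means/sds of the fitting data; zero-variance columns dropped."""

    species: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray
    dropped: tuple[str, ...]


def zscore_fit(X: np.ndarray, species: tuple[str, ...]) -> Scaler:
    X = np.asarray(X, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InputError("z-scoring requires a 2-D matrix with >= 2 rows")
    if X.shape[1] != len(species):
        raise InputError("species list does not match matrix width")
    sd = X.std(axis=0, ddof=0)
    keep = sd > 1e-12
    return Scaler(
        species=tuple(s for s, k in zip(species, keep) if k),
        mean=X.mean(axis=0)[keep],
        sd=sd[keep],
        dropped=tuple(s for s, k in zip(species, keep) if not k),
    )


def zscore_apply(X: np.ndarray, scaler: Scaler, species: tuple[str, ...]) -> np.ndarray:
    X = np.asarray(X, float)
    missing = [s for s in scaler.species if s not in species]
    if missing:
        raise SchemaError(f"matrix lacks species required by the scaler: {missing}")
    cols = [species.index(s) for s in scaler.species]
    return (X[:, cols] - scaler.mean) / scaler.sd


# ------------------------------------------------------------------- PCA


@dataclass
class FittedProjection:
    """A fitted linear projection (PCA or PLSR) of a z-scored state matrix."""

    kind: str
    species: tuple[str, ...]
    components: np.ndarray  # (k, p), rows unit-norm for PCA
    scores: np.ndarray  # training scores (n, k)
    explained_variance_ratio: np.ndarray | None = None
    explained_variance: np.ndarray | None = None
    x_loadings: np.ndarray | None = None  # (p, k) for PLSR
    model: object = field(default=None, repr=False)


def pca_fit(Xz: np.ndarray, species: tuple[str, ...], n_components: int | None = None):
    """Thin-SVD PCA of a z-scored matrix."""
    Xz = np.asarray(Xz, float)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Xz)
    return FittedProjection(
        kind="pca",
        species=tuple(species),
        components=pca.components_,
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_,
        explained_variance=pca.explained_variance_,
        model=pca,
    )


def top_loadings(fit: FittedProjection, component: int = 0, k: int = 20) -> pd.DataFrame:
    """Species ranked by absolute loading on one component, signs retained."""
    if fit.kind == "pca":
        vec = fit.components[component]
    else:
        vec = fit.x_loadings[:, component]
    if k > len(fit.species):
        warnings.warn(
            f"requested top {k} loadings but only {len(fit.species)} species; clipping",
            stacklevel=2,
        )
        k = len(fit.species)
    order = np.argsort(-np.abs(vec))[:k]
    return pd.DataFrame(
        {"species": [fit.species[i] for i in order], "loading": vec[order]}
    )


def project(
    X_new: np.ndarray,
    scaler: Scaler,
    fit: FittedProjection,
    species: tuple[str, ...],
) -> np.ndarray:
    """Apply a control-fitted scaler and rotation to new states (no refit)."""
    Xz = zscore_apply(X_new, scaler, species)
    if fit.kind == "pca":
        return Xz @ fit.components.T
    return fit.model.transform(Xz)


# ------------------------------------------------------------------ PLSR


def plsr_fit(
    Xz: np.ndarray,
    y: np.ndarray,
    species: tuple[str, ...],
    n_components: int = 2,
) -> FittedProjection:
    """Single-response PLS regression; components maximize covariance with y."""
    y = np.asarray(y, float)
    if float(np.std(y)) < 1e-12:
        raise ConfigurationError("PLSR response is constant; fit is degenerate")
    pls = PLSRegression(n_components=n_components, scale=False)
    scores = pls.fit_transform(Xz, y)[0]
    return FittedProjection(
        kind="plsr",
        species=tuple(species),
        components=pls.x_weights_.T,
        scores=scores,
        x_loadings=pls.x_loadings_,
        model=pls,
    )


def plsr_cv_r2(
    Xz: np.ndarray, y: np.ndarray, n_components: int = 2, n_splits: int = 5
) -> float:
    """K-fold cross-validated R^2 of a PLSR fit (<= 0 when y is unrelated)."""
    from sklearn.model_selection import KFold, cross_val_score

    cv = KFold(n_splits=n_splits, shuffle=True, random_state=0)
    scores = cross_val_score(
        PLSRegression(n_components=n_components, scale=False), Xz, y, cv=cv, scoring="r2"
    )
    return float(np.mean(scores))
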
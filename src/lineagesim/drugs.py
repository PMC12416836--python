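"""Pharmacodynamic drug modules: transport, target binding, occupancy.

Each drug is a small mass-action reaction set attachable to a cell model:

* first-order entry/exit across the membrane with one rate constant
  (0.01 s^-1 for all built-ins), against a clamped extracellular reservoir;
* reversible binding ``D + T <-> TD`` with rates ``kon``/``koff`` (so
  Kd = koff/kon), or irreversible binding (koff = 0);
* optional first-order degradation of the bound complex at the target's own
  turnover rate, balanced by constant synthesis so the total target pool is
  stationary.

Built-in parameter sets cover four kinase inhibitors: alpelisib (PI-3K,
Kd 2.4 nM), palbociclib (CDK4/6, Kd 1.9 nM), trametinib (MEK, Kd 0.35 nM) —
all with kon = 1e-3 nM^-1 s^-1 — and neratinib (EGFR-family, irreversible,
kon = 1e-4 nM^-1 s^-1).  A bound target loses its activity; the cycling-speed
coupling lives in the cell model (free-target fraction, linear or Hill).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InputError

__all__ = [
    "DrugParams",
    "BUILTIN_DRUGS",
    "builtin_drug",
    "pd_derivatives",
    "simulate_pd",
    "equilibrium_occupancy",
    "titrate_kd",
    "occupancy_free_fraction",
]

#: Default total target pool (nM) used when a host model does not declare one.
DEFAULT_TARGET_TOTAL_NM = 100.0

#: Membrane (and nuclear, collapsed) transport rate shared by all built-ins.
TRANSPORT_RATE_PER_S = 0.01


@dataclass(frozen=True)
class DrugParams:
    """Constants of one pharmacodynamic module (rates per second, conc in nM)."""

    name: str
    k_transport: float = TRANSPORT_RATE_PER_S
    kon: float = 1e-3
    koff: float = 0.0
    irreversible: bool = False
    k_deg: float = 0.0
    dose_ext: float = 0.0
    target_total: float = DEFAULT_TARGET_TOTAL_NM

    def __post_init__(self) -> None:
        for field in ("k_transport", "kon", "koff", "k_deg", "dose_ext", "target_total"):
            if getattr(self, field) < 0:
                raise ConfigurationError(f"drug parameter {field!r} must be >= 0")
        if self.irreversible != (self.koff == 0.0):
            raise ConfigurationError(
                "irreversible flag must match koff == 0 "
                f"(got irreversible={self.irreversible}, koff={self.koff})"
            )

    @property
    def kd(self) -> float:
        """Dissociation constant koff/kon (nM); 0 for irreversible binders."""
        if self.kon == 0:
            raise ConfigurationError("kd undefined for kon = 0")
        return self.koff / self.kon

    def with_dose(self, dose_nM: float) -> "DrugParams":
        return dataclasses.replace(self, dose_ext=float(dose_nM))


BUILTIN_DRUGS: dict[str, DrugParams] = {
    "alpelisib": DrugParams("alpelisib", kon=1e-3, koff=2.4e-3),
    "palbociclib": DrugParams("palbociclib", kon=1e-3, koff=1.9e-3),
    "trametinib": DrugParams("trametinib", kon=1e-3, koff=3.5e-4),
    "neratinib": DrugParams("neratinib", kon=1e-4, koff=0.0, irreversible=True),
}


def builtin_drug(name: str, dose_nM: float = 0.0) -> DrugParams:
    """Return the built-in parameter set for one of the four inhibitors."""
    try:
        base = BUILTIN_DRUGS[name]
    except KeyError:
        valid = ", ".join(sorted(BUILTIN_DRUGS))
        raise LookupError(f"unknown drug {name!r}; valid names: {valid}") from None
    return base.with_dose(dose_nM)


def pd_derivatives(
    D_ext: float,
    D_in: np.ndarray | float,
    T_free: np.ndarray | float,
    TD: np.ndarray | float,
    params: DrugParams,
):
    """Time derivatives (per second) of intracellular drug, free target, complex.

    The extracellular pool is clamped (infinite reservoir).  Degradation of the
    bound complex is balanced by synthesis fixed at ``k_deg * target_total`` so
    the total target pool is stationary.
    """
    if np.any(np.asarray(D_in) < 0) or np.any(np.asarray(T_free) < 0) or np.any(
        np.asarray(TD) < 0
    ):
        raise InputError("drug/target concentrations must be >= 0")
    bind = params.kon * D_in * T_free
    unbind = params.koff * TD
    dD_in = params.k_transport * (D_ext - D_in) - bind + unbind
    dT_free = -bind + unbind + params.k_deg * (params.target_total - T_free - TD)
    dTD = bind - unbind - params.k_deg * TD
    return dD_in, dT_free, dTD


def _rk4_step(y, dt, deriv):
    k1 = deriv(y)
    k2 = deriv([y[i] + 0.5 * dt * k1[i] for i in range(3)])
    k3 = deriv([y[i] + 0.5 * dt * k2[i] for i in range(3)])
    k4 = deriv([y[i] + dt * k3[i] for i in range(3)])
    return [
        y[i] + dt / 6.0 * (k1[i] + 2 * k2[i] + 2 * k3[i] + k4[i]) for i in range(3)
    ]


def simulate_pd(
    params: DrugParams,
    duration_s: float,
    *,
    dt_s: float | None = None,
    D_in0: float | np.ndarray = 0.0,
    T_free0: float | np.ndarray | None = None,
    TD0: float | np.ndarray = 0.0,
    clamp_D_in: float | None = None,
    record_every: int = 1,
    dose_ext: float | np.ndarray | None = None,
):
    """Integrate the drug subsystem alone with a fine fixed-step RK4 scheme.

    Vectorized over doses: ``dose_ext`` may be an array, in which case the
    state arrays broadcast.  ``clamp_D_in`` pins the intracellular drug at a
    constant value (used for pseudo-first-order binding measurements).

    Returns ``(times_s, D_in, T_free, TD)`` where the state arrays have shape
    ``(n_rec,) + broadcast_shape``.
    """
    D_ext = params.dose_ext if dose_ext is None else np.asarray(dose_ext, float)
    T0 = params.target_total if T_free0 is None else T_free0
    rate_max = (
        params.k_transport
        + params.kon * (np.max(np.atleast_1d(D_ext)) + params.target_total)
        + params.koff
        + params.k_deg
    )
    if dt_s is None:
        dt_s = min(1.0, 0.5 / rate_max) if rate_max > 0 else 1.0
    n_steps = max(1, int(np.ceil(duration_s / dt_s)))

    shape = np.broadcast(
        np.asarray(D_ext, float), np.asarray(D_in0, float), np.asarray(T0, float)
    ).shape
    y = [
        np.broadcast_to(np.asarray(v, float), shape).copy()
        for v in (D_in0 if clamp_D_in is None else clamp_D_in, T0, TD0)
    ]

    def deriv(state):
        dD, dT, dTD = pd_derivatives(D_ext, state[0], state[1], state[2], params)
        if clamp_D_in is not None:
            dD = np.zeros_like(np.asarray(dD, float))
        return [np.asarray(dD, float), np.asarray(dT, float), np.asarray(dTD, float)]

    n_rec = n_steps // record_every + 1 + (1 if n_steps % record_every else 0)
    times = np.empty(n_rec)
    out = [np.empty((n_rec,) + shape) for _ in range(3)]
    times[0] = 0.0
    for j in range(3):
        out[j][0] = y[j]
    r = 1
    for k in range(1, n_steps + 1):
        y = _rk4_step(y, dt_s, deriv)
        y = [np.maximum(v, 0.0) for v in y]
        if (k % record_every == 0 or k == n_steps) and r < n_rec:
            times[r] = k * dt_s
            for j in range(3):
                out[j][r] = y[j]
            r += 1
    return times[:r], out[0][:r], out[1][:r], out[2][:r]


def equilibrium_occupancy(params: DrugParams, dose_nM, duration_s: float = 86400.0):
    """Simulated equilibrium target occupancy TD/(T_free+TD) at given dose(s)."""
    doses = np.atleast_1d(np.asarray(dose_nM, float))
    _, _, T_free, TD = simulate_pd(
        params, duration_s, dose_ext=doses, record_every=10**9
    )
    occ = TD[-1] / (T_free[-1] + TD[-1])
    return occ if np.ndim(dose_nM) else float(occ[0])


def titrate_kd(params: DrugParams, conc_grid_nM, duration_s: float = 86400.0) -> float:
    """Estimate the half-occupancy concentration from an equilibrium titration.

    Each dose in ``conc_grid_nM`` is simulated to equilibrium (with transport)
    and the concentration at 50% occupancy is interpolated on a log-dose axis.
    For a reversible binder with no target turnover this equals koff/kon.
    """
    if params.irreversible:
        raise ConfigurationError(
            "titration half-occupancy is only defined for reversible drugs"
        )
    grid = np.sort(np.asarray(conc_grid_nM, float))
    if grid.size < 2 or np.any(grid <= 0):
        raise InputError("concentration grid must hold >= 2 positive doses")
    occ = equilibrium_occupancy(params, grid, duration_s=duration_s)
    if occ[0] > 0.5 or occ[-1] < 0.5:
        raise InputError(
            "concentration grid does not bracket half-occupancy "
            f"(occupancy spans [{occ[0]:.3g}, {occ[-1]:.3g}])"
        )
    return float(np.exp(np.interp(0.5, occ, np.log(grid))))


def occupancy_free_fraction(T_free, TD):
    """Fraction of the target pool left unbound; 1 where the pool is empty."""
    total = np.asarray(T_free, float) + np.asarray(TD, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(total > 0, np.asarray(T_free, float) / np.where(total > 0, total, 1.0), 1.0)
    return f
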
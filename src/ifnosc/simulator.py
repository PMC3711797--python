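"""Time integration of the kinetic model and trajectory containers.

The system is stiff (rates span 7e-4 to 1.3e3 per minute, species span 1 to
1e5 molecules), so integration uses a stiff-capable solver (LSODA by
default) with a tight relative tolerance and per-species absolute
tolerances scaled to the initial magnitudes.  Output grids are produced by
the solver's dense interpolation only, so the solution is independent of
the requested output step.

Figures in this domain are conventionally shown "max-normalized": each
series divided by its own maximum over the simulated window, which is what
:func:`normalize` implements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import IntegrationFailureError, UsageError
from .model_core import (SPECIES, KnockoutSpec, ParameterSet, StateVector,
                         jacobian, rhs)

__all__ = [
    "Trajectory",
    "NormalizedTrajectory",
    "simulate",
    "receptor_closed_form",
    "derived_series",
    "normalize",
    "DERIVED_SERIES",
]

log = logging.getLogger(__name__)

#: Observable series derived from the raw species.
DERIVED_SERIES = {
    "pSTAT1_total": ("Apc", "Apn"),
    "STAT1_protein_total": ("A", "Apc", "Apn"),
}

DEFAULT_T_END = 480.0   # minutes; the first 8 h after stimulation
DEFAULT_DT_OUT = 1.0    # minutes
DEFAULT_RTOL = 1e-8


def _default_atol(y0: np.ndarray) -> np.ndarray:
    # Species span 1..1e5 molecules; scale the absolute tolerance per species.
    return 1e-6 * np.maximum(np.abs(y0), 1.0)


@dataclass(frozen=True)
class Trajectory:
    """Dense time course of all nine species on a uniform grid.

    ``states`` has shape ``(len(times), 9)`` in the canonical species order.
    Provenance (parameters, initial state, knockout, solver settings) is
    carried along so every figure or CSV can be traced to its inputs.
    """

    times: np.ndarray
    states: np.ndarray
    params: ParameterSet = None
    initial: StateVector = None
    knockout: KnockoutSpec = field(default_factory=KnockoutSpec)
    solver_options: dict = field(default_factory=dict)

    def species(self, name: str) -> np.ndarray:
        """Series for a raw species or a derived observable."""
        if name in DERIVED_SERIES:
            return sum(self.species(s) for s in DERIVED_SERIES[name])
        try:
            idx = SPECIES.index(name)
        except ValueError:
            raise UsageError(
                f"unknown series {name!r}; expected one of {SPECIES + tuple(DERIVED_SERIES)}"
            ) from None
        return self.states[:, idx]

    series = species  # alias: derived observables read naturally

    def to_frame(self, run_id: str = "run") -> pd.DataFrame:
        """Tidy long-form table: time_min, species, value, run_id."""
        n = len(self.times)
        return pd.DataFrame({
            "time_min": np.tile(self.times, len(SPECIES)),
            "species": np.repeat(SPECIES, n),
            "value": self.states.T.reshape(-1),
            "run_id": run_id,
        })


@dataclass(frozen=True)
class NormalizedTrajectory:
    """Per-series max-normalized view of a trajectory.

    Every selected series is divided by its own maximum over the window, so
    each normalized series peaks at exactly 1 (an identically-zero series
    stays 0 and its factor is recorded as 0).
    """

    times: np.ndarray
    data: dict
    factors: dict

    def series(self, name: str) -> np.ndarray:
        return self.data[name]


def _integrate(p, y0_arr, ko, t_eval, clamp_S=False, rtol=DEFAULT_RTOL,
               atol=None, method="LSODA"):
    """Low-level solve returning the state matrix on ``t_eval``."""
    if atol is None:
        atol = _default_atol(y0_arr)
    def jac(t, y, p_, ko_, cl_):
        J = jacobian(y, p_, ko_)
        if cl_:
            J[0, :] = 0.0  # S held constant: its row vanishes
        return J

    sol = solve_ivp(
        rhs, (t_eval[0], t_eval[-1]), y0_arr, t_eval=t_eval, method=method,
        rtol=rtol, atol=atol, args=(p, ko, clamp_S), jac=jac,
    )
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else None
        raise IntegrationFailureError(
            f"ODE solver failed: {sol.message}", last_good_time=last)
    states = sol.y.T
    # Stiff solvers may undershoot zero by a hair; clip within tolerance,
    # warn on larger undershoot, and fail on anything substantial.
    atol = np.broadcast_to(np.asarray(atol, dtype=float), (len(SPECIES),))
    low = states.min(axis=0)
    for j, nm in enumerate(SPECIES):
        if low[j] < 0:
            if low[j] < -1e6 * atol[j]:
                raise IntegrationFailureError(
                    f"species {nm} went substantially negative ({low[j]:.3g})")
            if low[j] < -atol[j]:
                log.warning("clipping negative undershoot of %s (min %.3g) to 0", nm, low[j])
    return t_eval, np.clip(states, 0.0, None)


def simulate(p: ParameterSet = None, y0: StateVector = None,
             ko: KnockoutSpec = None, t_end: float = DEFAULT_T_END,
             dt_out: float = DEFAULT_DT_OUT, clamp_S: bool = False,
             rtol: float = DEFAULT_RTOL, atol=None,
             method: str = "LSODA") -> Trajectory:
    """Integrate the model over ``[0, t_end]`` minutes.

    Returns the trajectory on the uniform grid ``{0, dt_out, ..., t_end}``;
    the grid is filled from the solver's dense output, so refining
    ``dt_out`` does not change values at shared grid points.
    """
    if t_end <= 0 or dt_out <= 0:
        raise UsageError("t_end and dt_out must be > 0")
    p = p or ParameterSet()
    y0 = y0 or StateVector.default_initial()
    ko = ko or KnockoutSpec()
    n_steps = int(round(t_end / dt_out))
    t_eval = np.linspace(0.0, n_steps * dt_out, n_steps + 1)
    y0_arr = y0.to_array()
    times, states = _integrate(p, y0_arr, ko, t_eval, clamp_S=clamp_S,
                               rtol=rtol, atol=atol, method=method)
    states = states.copy()
    states[0] = y0_arr  # the initial condition is exact by construction
    return Trajectory(times=times, states=states, params=p, initial=y0,
                      knockout=ko,
                      solver_options={"method": method, "rtol": rtol,
                                      "clamp_S": clamp_S, "dt_out": dt_out})


def receptor_closed_form(S0: float, p: ParameterSet, t):
    """Closed-form activated-receptor level.

    ``dS/dt = b_S - lam_S*S`` decouples from the rest of the network, so
    ``S(t) = b_S/lam_S + (S0 - b_S/lam_S) * exp(-lam_S*t)``; with the
    reference ``b_S = 0`` this is a pure exponential decay.  The degenerate
    ``lam_S = 0`` case is the linear ramp ``S0 + b_S*t``.
    """
    if S0 < 0:
        raise UsageError("S0 must be >= 0")
    t = np.asarray(t, dtype=float)
    if p.lam_S == 0.0:
        out = S0 + p.b_S * t
    else:
        s_inf = p.b_S / p.lam_S
        out = s_inf + (S0 - s_inf) * np.exp(-p.lam_S * t)
    return out if out.shape else float(out)


def derived_series(traj: Trajectory, which: str) -> np.ndarray:
    """Observable combinations measured in the assays.

    ``pSTAT1_total`` is nuclear plus cytoplasmic phosphorylated STAT1
    (``Apc + Apn``); ``STAT1_protein_total`` additionally includes the
    unphosphorylated pool (``A + Apc + Apn``).
    """
    if which not in DERIVED_SERIES:
        raise UsageError(f"unknown derived series {which!r}")
    return traj.species(which)


def normalize(traj, series_names=None) -> NormalizedTrajectory:
    """Divide each selected series by its own maximum over the window.

    Accepts a :class:`Trajectory` or an already-normalized trajectory
    (normalization is idempotent).  Scaling factors are recorded; an
    identically-zero series passes through with factor 0.
    """
    if series_names is None:
        series_names = (SPECIES + tuple(DERIVED_SERIES)
                        if isinstance(traj, Trajectory) else tuple(traj.data))
    data, factors = {}, {}
    for nm in series_names:
        s = np.asarray(traj.series(nm), dtype=float)
        m = float(s.max()) if s.size else 0.0
        if m > 0:
            data[nm] = s / m
            factors[nm] = m
        else:
            data[nm] = s.copy()
            factors[nm] = 0.0
    return NormalizedTrajectory(times=np.asarray(traj.times), data=data, factors=factors)
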
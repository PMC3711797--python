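"""Steady-state stability analysis: damped-oscillatory vs overdamped regimes.

The transient response to a pulse of IFN-beta rings (a second pSTAT1 peak
~200 min after the first) or relaxes monotonically depending on where the
kinetic parameters sit.  The two regimes are told apart by linearizing the
clamped system -- activated receptor S held at its initial value -- at its
steady state and asking whether the leading eigenvalue carries an imaginary
part: an underdamped focus rings, an overdamped node does not.

Two linearizations are offered.

``method="fast_module"`` (default).  On the 8-hour observation window the
total STAT1 protein pool and the transcriptional STAT1-production branch
(a, f, F) are slow: their degradation half-lives range from 1 to 24 hours.
The ringing visible in pSTAT1 is a property of the fast
phosphorylation/shuttling/SOCS1 module, so the default classifier
linearizes that module -- states (Apc, Apn, r, R) with the STAT1 pool
conserved at its initial total and S clamped -- at its quasi-steady state.
Its leading eigenvalue pair at the reference parameters has period
2*pi/|Im| ~ 190 min, matching the observed inter-peak spacing.

``method="full"``.  The textbook construction: steady state of all eight
free species under clamped S, eigenvalues of the full 8x8 Jacobian.  At a
permanently clamped receptor level the STAT1 pool slowly inflates through
the IRF1 positive feedback, and the leading eigenvalue of the resulting
steady state is always the near-decoupled slow STAT1-protein drift
(~ -lam_STAT, purely real) -- a spectator mode that says nothing about the
ringing.  The full spectrum is returned so the oscillatory pair can still
be inspected, but regime classification with this method is dominated by
the spectator mode; see docs/methods.md.

2D parameter scans sweep two rates over log-spaced grids and record
|Im(leading eigenvalue)| per cell, the phase-diagram construction used for
the (b_ph, b_deph) and (b_imp, b_exp) planes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import root

from .errors import SteadyStateError, UsageError
from .model_core import (SPECIES, KnockoutSpec, ParameterSet, StateVector,
                         _phi_partials, hill_activation, hill_derivative,
                         phosphorylation_flux, rhs, jacobian)
from .simulator import _integrate

__all__ = [
    "StabilityResult",
    "StabilityMap",
    "clamped_steady_state",
    "classify_regime",
    "stability_scan_2d",
    "transient_peak_count",
]

DEFAULT_IM_TOL = 1e-5   # 1/min; far below any oscillation resolvable in 480 min
_FREE = SPECIES[1:]     # the eight species free under clamped S


# ----------------------------------------------------------------- full system

def _clamped_rhs(y8, p, S_fixed, ko):
    # Newton iterates may probe negative copy numbers; evaluate the model
    # at the clipped state and add a linear pull-back so the residual keeps
    # a consistent gradient outside the physical orthant.
    y8 = np.asarray(y8, dtype=float)
    yc = np.clip(y8, 0.0, None)
    out = rhs(0.0, np.concatenate(([S_fixed], yc)), p, ko, clamp_S=True)[1:]
    return out + np.minimum(y8, 0.0)


def _clamped_jac(y8, p, S_fixed, ko):
    y8 = np.asarray(y8, dtype=float)
    yc = np.clip(y8, 0.0, None)
    J = jacobian(np.concatenate(([S_fixed], yc)), p, ko, clamp_S=True)
    return J + np.diag((y8 < 0.0).astype(float))


def _residual_ok(res, y8, scale):
    tol = 1e-8 * np.maximum(np.abs(y8), scale)
    return np.all(np.abs(res) < np.maximum(tol, 1e-10))


def clamped_steady_state(p: ParameterSet = None, S_fixed: float = 1000.0,
                         ko: KnockoutSpec = None, y0: StateVector = None,
                         seed_state=None) -> StateVector:
    """Steady state of the eight free species with S clamped at ``S_fixed``.

    Newton iteration (with the analytic Jacobian) is seeded from the time
    average of a long clamped integration over [2000, 4000] min, with
    multi-start fallback from scaled perturbations of that seed.  An
    explicit ``seed_state`` (length-8 array) short-circuits the
    integration seed; scans use it to warm-start from a neighbouring cell.
    """
    if S_fixed < 0:
        raise UsageError("S_fixed must be >= 0")
    p = p or ParameterSet()
    ko = ko or KnockoutSpec()
    y0 = y0 or StateVector.default_initial()

    seeds = []
    if seed_state is not None:
        seeds.append(np.asarray(seed_state, dtype=float))

    def integration_seed():
        y_full = y0.to_array().copy()
        y_full[0] = S_fixed
        t_eval = np.linspace(0.0, 4000.0, 401)
        _, states = _integrate(p, y_full, ko, t_eval, clamp_S=True,
                               rtol=1e-9, atol=None)
        return states[t_eval >= 2000.0, 1:].mean(axis=0)

    base = None
    for attempt in range(2):  # explicit seed first, then the integration seed
        if attempt == 1 or not seeds:
            base = integration_seed()
            seeds.append(base)
        for scale in (1.0, 0.5, 2.0, 0.1, 10.0):
            guess = np.clip(seeds[-1] * scale, 0.0, None)
            sol = root(_clamped_rhs, guess, args=(p, S_fixed, ko),
                       jac=_clamped_jac, method="hybr")
            y8 = sol.x
            if np.any(y8 < -1e-6):
                continue
            y8 = np.clip(y8, 0.0, None)
            res = _clamped_rhs(y8, p, S_fixed, ko)
            if _residual_ok(res, y8, scale=1.0):
                return StateVector.from_array(np.concatenate(([S_fixed], y8)))
        if seed_state is None:
            break  # the integration seed was already tried with all scales
    raise SteadyStateError(
        f"no clamped steady state found at S={S_fixed} after all Newton starts")


# ----------------------------------------------------------------- fast module

def _fast_rhs(y4, p, S_fixed, A_tot, ko):
    y4 = np.asarray(y4, dtype=float)
    Apc, Apn, r, R = np.clip(y4, 0.0, None)
    A = A_tot - Apc - Apn
    phi = phosphorylation_flux(max(A, 0.0), S_fixed, R, p, ko)
    out = np.array([
        phi - (p.b_imp + p.b_deph) * Apc,
        p.b_imp * Apc - p.b_exp * Apn,
        p.b_r * hill_activation(Apn, p.k_r, p.n) - p.lam_r * r,
        p.b_R * r - p.lam_R * R,
    ])
    return out + np.minimum(y4, 0.0)


def _fast_jac(y4, p, S_fixed, A_tot, ko):
    y4 = np.asarray(y4, dtype=float)
    Apc, Apn, r, R = np.clip(y4, 0.0, None)
    A = max(A_tot - Apc - Apn, 0.0)
    dphi_dA, _, dphi_dR = _phi_partials(A, S_fixed, R, p, ko)
    J = np.zeros((4, 4))
    J[0, 0] = -dphi_dA - (p.b_imp + p.b_deph)   # d(A)/d(Apc) = -1
    J[0, 1] = -dphi_dA
    J[0, 3] = dphi_dR
    J[1, 0] = p.b_imp
    J[1, 1] = -p.b_exp
    J[2, 1] = p.b_r * hill_derivative(Apn, p.k_r, p.n)
    J[2, 2] = -p.lam_r
    J[3, 2] = p.b_R
    J[3, 3] = -p.lam_R
    return J + np.diag((y4 < 0.0).astype(float))


def _fast_steady_state(p, S_fixed, A_tot, ko, seed_state=None):
    seeds = []
    if seed_state is not None:
        seeds.append(np.asarray(seed_state, dtype=float))

    def integration_seed():
        from scipy.integrate import solve_ivp
        y4 = np.array([10.0, 1.0, 1.0, 1.0])
        sol = solve_ivp(lambda t, y: _fast_rhs(y, p, S_fixed, A_tot, ko),
                        (0.0, 8000.0), y4, method="LSODA",
                        rtol=1e-9, atol=1e-8, dense_output=True)
        if not sol.success:
            raise SteadyStateError("fast-module relaxation integration failed")
        ts = np.linspace(4000.0, 8000.0, 200)
        return np.clip(sol.sol(ts).mean(axis=1), 0.0, None)

    for attempt in range(2):
        if attempt == 1 or not seeds:
            seeds.append(integration_seed())
        for scale in (1.0, 0.5, 2.0, 0.1, 10.0):
            guess = np.clip(seeds[-1] * scale, 0.0, None)
            sol = root(_fast_rhs, guess, args=(p, S_fixed, A_tot, ko),
                       jac=_fast_jac, method="hybr")
            y4 = sol.x
            if np.any(y4 < -1e-6) or y4[0] + y4[1] > A_tot:
                continue
            y4 = np.clip(y4, 0.0, None)
            res = _fast_rhs(y4, p, S_fixed, A_tot, ko)
            if _residual_ok(res, y4, scale=1.0):
                return y4
        if seed_state is None:
            break
    raise SteadyStateError(
        f"no fast-module steady state found at S={S_fixed} after all starts")


# -------------------------------------------------------------- classification

@dataclass(frozen=True)
class StabilityResult:
    """Outcome of a single-point stability classification."""

    steady_state: StateVector
    leading_eigenvalue: complex
    eigenvalues: np.ndarray
    classification: str            # "oscillatory" | "non_oscillatory"
    converged: bool
    residual_norm: float           # max-norm of the rhs at the steady state
    method: str
    im_tol: float


def _leading(eigs: np.ndarray) -> complex:
    """Eigenvalue with maximum real part, ties broken by larger |Im|."""
    order = np.lexsort((np.abs(eigs.imag), eigs.real))
    return complex(eigs[order[-1]])


def classify_regime(p: ParameterSet = None, S_fixed: float = 1000.0,
                    ko: KnockoutSpec = None, im_tol: float = DEFAULT_IM_TOL,
                    method: str = "fast_module", y0: StateVector = None,
                    seed_state=None) -> StabilityResult:
    """Classify the clamped-receptor response as oscillatory or not.

    The regime is oscillatory when the leading eigenvalue (maximum real
    part; ties broken towards larger |Im|) of the chosen linearization has
    ``|Im| > im_tol``.  See the module docstring for the two methods.
    """
    p = p or ParameterSet()
    ko = ko or KnockoutSpec()
    y0 = y0 or StateVector.default_initial()
    if method == "full":
        ss = clamped_steady_state(p, S_fixed, ko, y0=y0, seed_state=seed_state)
        J = _clamped_jac(ss.to_array()[1:], p, S_fixed, ko)
        resid = float(np.max(np.abs(_clamped_rhs(ss.to_array()[1:], p, S_fixed, ko))))
    elif method == "fast_module":
        A_tot = y0.A + y0.Apc + y0.Apn
        y4 = _fast_steady_state(p, S_fixed, A_tot, ko, seed_state=seed_state)
        J = _fast_jac(y4, p, S_fixed, A_tot, ko)
        resid = float(np.max(np.abs(_fast_rhs(y4, p, S_fixed, A_tot, ko))))
        Apc, Apn, r, R = y4
        ss = StateVector(S=S_fixed, A=max(A_tot - Apc - Apn, 0.0), Apc=Apc,
                         Apn=Apn, r=r, R=R, f=y0.f, F=y0.F, a=y0.a)
    else:
        raise UsageError(f"unknown method {method!r}; expected 'fast_module' or 'full'")
    eigs = np.linalg.eigvals(J)
    lead = _leading(eigs)
    cls = "oscillatory" if abs(lead.imag) > im_tol else "non_oscillatory"
    return StabilityResult(steady_state=ss, leading_eigenvalue=lead,
                           eigenvalues=eigs, classification=cls,
                           converged=True, residual_norm=resid,
                           method=method, im_tol=im_tol)


# ------------------------------------------------------------------- 2D scans

@dataclass(frozen=True)
class StabilityMap:
    """2D grid of |Im(leading eigenvalue)| with regime classifications.

    ``im_abs`` and ``oscillatory`` have shape ``(len(x_values),
    len(y_values))`` indexed ``[i, j]`` = (x_values[i], y_values[j]).
    Unresolved cells (steady state not found) carry NaN in ``im_abs`` and
    False in ``converged``; they are flagged, never silently dropped.
    """

    param_x: str
    param_y: str
    x_values: np.ndarray
    y_values: np.ndarray
    im_abs: np.ndarray
    re_leading: np.ndarray
    oscillatory: np.ndarray
    converged: np.ndarray
    basal_point: tuple
    method: str
    im_tol: float
    S_fixed: float

    def to_frame(self) -> pd.DataFrame:
        """Long-form table (param_x_value, param_y_value, im_abs,
        re_leading, classification) in deterministic cell order."""
        rows = []
        for i, xv in enumerate(self.x_values):
            for j, yv in enumerate(self.y_values):
                if self.converged[i, j]:
                    cls = "oscillatory" if self.oscillatory[i, j] else "non_oscillatory"
                else:
                    cls = "unresolved"
                rows.append((xv, yv, self.im_abs[i, j], self.re_leading[i, j], cls))
        return pd.DataFrame(rows, columns=["param_x_value", "param_y_value",
                                           "im_abs", "re_leading", "classification"])


def _default_range(basal: float):
    # One decade each side of the basal value (two decades total).
    return basal / 10.0, basal * 10.0


def stability_scan_2d(p: ParameterSet = None, param_x: str = "b_ph",
                      param_y: str = "b_deph", ranges=None,
                      resolution: int = 20, S_fixed: float = 1000.0,
                      ko: KnockoutSpec = None, im_tol: float = DEFAULT_IM_TOL,
                      method: str = "fast_module",
                      y0: StateVector = None) -> StabilityMap:
    """Classify every cell of a log-spaced 2D parameter grid.

    All other parameters stay at their basal values.  Cells are visited in
    deterministic row-major order, warm-starting each Newton solve from the
    previous resolved cell.
    """
    p = p or ParameterSet()
    ko = ko or KnockoutSpec()
    if resolution < 1:
        raise UsageError("resolution must be >= 1")
    for nm in (param_x, param_y):
        if nm not in ParameterSet.perturbable_names():
            raise UsageError(f"unknown or non-scannable parameter {nm!r}")
    basal_x, basal_y = getattr(p, param_x), getattr(p, param_y)
    if ranges is None:
        ranges = (_default_range(basal_x), _default_range(basal_y))
    (x_lo, x_hi), (y_lo, y_hi) = ranges
    if resolution == 1:
        x_values = np.array([basal_x])
        y_values = np.array([basal_y])
    else:
        x_values = np.geomspace(x_lo, x_hi, resolution)
        y_values = np.geomspace(y_lo, y_hi, resolution)

    shape = (len(x_values), len(y_values))
    im_abs = np.full(shape, np.nan)
    re_lead = np.full(shape, np.nan)
    osc = np.zeros(shape, dtype=bool)
    conv = np.zeros(shape, dtype=bool)
    warm = None
    for i, xv in enumerate(x_values):
        for j, yv in enumerate(y_values):
            pij = p.replace(**{param_x: float(xv), param_y: float(yv)})
            try:
                res = classify_regime(pij, S_fixed=S_fixed, ko=ko,
                                      im_tol=im_tol, method=method, y0=y0,
                                      seed_state=warm)
            except SteadyStateError:
                warm = None
                continue
            lead = res.leading_eigenvalue
            im_abs[i, j] = abs(lead.imag)
            re_lead[i, j] = lead.real
            osc[i, j] = res.classification == "oscillatory"
            conv[i, j] = True
            if res.method == "fast_module":
                s = res.steady_state
                warm = np.array([s.Apc, s.Apn, s.r, s.R])
            else:
                warm = res.steady_state.to_array()[1:]
    return StabilityMap(param_x=param_x, param_y=param_y, x_values=x_values,
                        y_values=y_values, im_abs=im_abs, re_leading=re_lead,
                        oscillatory=osc, converged=conv,
                        basal_point=(basal_x, basal_y), method=method,
                        im_tol=im_tol, S_fixed=S_fixed)


def transient_peak_count(p: ParameterSet = None, ko: KnockoutSpec = None,
                         y0: StateVector = None, series: str = "pSTAT1_total",
                         t_end: float = 480.0,
                         min_prominence_fraction: float = 0.02) -> int:
    """Number of retained peaks of a series in the full (decaying-receptor)
    transient -- the time-domain oscillation phenotype: >= 2 retained peaks
    is the damped-oscillatory response, <= 1 the overdamped one."""
    from .metrics import find_local_maxima
    from .simulator import simulate
    traj = simulate(p=p, y0=y0, ko=ko, t_end=t_end)
    return len(find_local_maxima(traj.times, traj.series(series),
                                 min_prominence_fraction))
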
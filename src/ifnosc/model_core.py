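"""Core kinetic model of IFN-beta-driven JAK/STAT signaling in macrophages.

The model is a nine-species ODE network describing the transient response of
RAW 264.7 macrophages to a pulse of type I interferon:

* ``S``    -- activated IFN receptor; produced at rate ``b_S`` (zero for a
  single stimulation pulse) and internalized/degraded at rate ``lam_S``, so
  the external drive decays exponentially.
* ``A``    -- unphosphorylated cytoplasmic STAT1 protein.
* ``Apc``  -- tyrosine-phosphorylated STAT1 in the cytoplasm.
* ``Apn``  -- phosphorylated STAT1 in the nucleus, the transcriptionally
  active pool (STAT1 homodimers on GAS promoter elements).
* ``r, R`` -- SOCS1 mRNA and protein.  SOCS1 competitively inhibits further
  STAT1 phosphorylation: the negative feedback loop.
* ``f, F`` -- IRF1 mRNA and protein.  IRF1 activates STAT1 transcription:
  the positive feedback loop.
* ``a``    -- STAT1 mRNA, with basal production ``B_STAT``.

Units are fixed throughout the package: time in minutes, species in
molecules per cell, first-order rates in 1/min.

Gene activation uses Hill functions ``(x/k)^h / (1 + (x/k)^h)`` and the
phosphorylation flux uses a competitive-inhibition saturation in which
substrate (``A/k_A``) and inhibitor (``(R/k_I)^q``) terms share the
denominator.  Feedback knockouts are implemented structurally (term removal,
the ``k_I -> inf`` and ``k_F -> 0`` limits) rather than by storing extreme
threshold values, which keeps the right-hand side finite for every state.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from typing import Iterable

import numpy as np

from .errors import InvalidParameterError, InvalidStateError, IntegrationFailureError, UsageError

__all__ = [
    "SPECIES",
    "ParameterSet",
    "StateVector",
    "KnockoutSpec",
    "hill_activation",
    "hill_derivative",
    "phosphorylation_flux",
    "rhs",
    "jacobian",
    "apply_knockout",
]

#: Canonical species ordering used by every array in the package.
SPECIES = ("S", "A", "Apc", "Apn", "r", "R", "f", "F", "a")

_HILL_EXPONENTS = ("q", "n", "m", "u")
_THRESHOLDS = ("k_A", "k_I", "k_r", "k_f", "k_F")


@dataclass(frozen=True)
class ParameterSet:
    """The 28 rate constants, thresholds and Hill exponents of the model.

    Defaults are the published reference parameterization for IFN-beta
    stimulated RAW 264.7 macrophages.  Rates are 1/min, thresholds are
    molecules/cell, Hill exponents are dimensionless positive integers.
    """

    b_S: float = 0.0          # receptor production (0: single pulse)
    lam_S: float = 0.0229     # receptor internalization/degradation
    b_ph: float = 1.3e3       # STAT1 phosphorylation
    b_deph: float = 0.036     # pSTAT1 dephosphorylation
    b_imp: float = 0.013      # nuclear import of pSTAT1
    b_exp: float = 0.048      # nuclear export (returns to the A pool)
    b_A: float = 65.0         # STAT1 translation
    b_R: float = 1.0e2        # SOCS1 translation
    b_F: float = 1.0e1        # IRF1 translation
    b_a: float = 0.1          # STAT1 transcription (IRF1-activated)
    b_r: float = 12.8         # SOCS1 transcription
    b_f: float = 2.7          # IRF1 transcription
    B_STAT: float = 0.0062    # basal STAT1 mRNA production
    k_A: float = 4680.0       # half-maximal phosphorylation threshold
    k_I: float = 82680.0      # SOCS1 inhibition threshold
    k_r: float = 23400.0      # SOCS1 promoter activation threshold
    k_f: float = 7366.0       # IRF1 promoter activation threshold
    k_F: float = 1.3e5        # STAT1 promoter activation threshold (by IRF1)
    q: int = 4                # SOCS1 inhibition cooperativity
    n: int = 3                # STAT1 on SOCS1 promoter
    m: int = 2                # STAT1 on IRF1 promoter
    u: int = 1                # IRF1 on STAT1 promoter
    lam_STAT: float = 0.0007  # STAT1 protein degradation (24 h half-life)
    lam_r: float = 0.0347     # SOCS1 mRNA degradation
    lam_R: float = 0.0231     # SOCS1 protein degradation
    lam_f: float = 0.0173     # IRF1 mRNA degradation
    lam_F: float = 0.0116     # IRF1 protein degradation
    lam_a: float = 0.0058     # STAT1 mRNA degradation

    def __post_init__(self):
        for f_ in fields(self):
            v = getattr(self, f_.name)
            if f_.name in _HILL_EXPONENTS:
                if not float(v).is_integer() or int(v) < 1:
                    raise InvalidParameterError(
                        f"Hill exponent {f_.name} must be an integer >= 1, got {v!r}")
                object.__setattr__(self, f_.name, int(v))
                continue
            v = float(v)
            if not np.isfinite(v):
                raise InvalidParameterError(f"parameter {f_.name} is not finite: {v!r}")
            if v < 0:
                raise InvalidParameterError(f"parameter {f_.name} must be >= 0, got {v!r}")
            if f_.name in _THRESHOLDS and v <= 0:
                raise InvalidParameterError(f"threshold {f_.name} must be > 0, got {v!r}")
            object.__setattr__(self, f_.name, v)

    def replace(self, **changes) -> "ParameterSet":
        """Return a copy with the given parameters replaced."""
        unknown = set(changes) - {f_.name for f_ in fields(self)}
        if unknown:
            raise UsageError(f"unknown parameter name(s): {sorted(unknown)}")
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict:
        return {f_.name: getattr(self, f_.name) for f_ in fields(self)}

    @classmethod
    def names(cls) -> tuple:
        return tuple(f_.name for f_ in fields(cls))

    @classmethod
    def perturbable_names(cls) -> tuple:
        """Real-valued parameters (Hill exponents excluded) eligible for
        the one-at-a-time sensitivity perturbation."""
        return tuple(nm for nm in cls.names() if nm not in _HILL_EXPONENTS)


@dataclass(frozen=True)
class StateVector:
    """One point of the model state, molecules/cell, all non-negative."""

    S: float
    A: float
    Apc: float
    Apn: float
    r: float
    R: float
    f: float
    F: float
    a: float

    def __post_init__(self):
        for name in SPECIES:
            v = float(getattr(self, name))
            if not np.isfinite(v):
                raise InvalidStateError(f"species {name} is not finite: {v!r}")
            if v < 0:
                raise InvalidStateError(f"species {name} must be >= 0, got {v!r}")
            object.__setattr__(self, name, v)

    @classmethod
    def default_initial(cls) -> "StateVector":
        """Reference initial conditions: a resting cell with a full STAT1
        pool (1e5 molecules) hit by a pulse activating 1000 receptors."""
        return cls(S=1000.0, A=1.0e5, Apc=10.0, Apn=1.0,
                   r=1.0, R=1.0, f=1.0, F=1.0, a=1.0)

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, nm) for nm in SPECIES], dtype=float)

    @classmethod
    def from_array(cls, y: Iterable[float]) -> "StateVector":
        y = np.asarray(y, dtype=float)
        if y.shape != (len(SPECIES),):
            raise InvalidStateError(f"expected {len(SPECIES)} species, got shape {y.shape}")
        return cls(**dict(zip(SPECIES, y)))

    def replace(self, **changes) -> "StateVector":
        unknown = set(changes) - set(SPECIES)
        if unknown:
            raise UsageError(f"unknown species name(s): {sorted(unknown)}")
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class KnockoutSpec:
    """Structural feedback knockouts.

    ``socs1_feedback_off`` removes the SOCS1 inhibition term from the
    phosphorylation flux (the ``k_I -> inf`` limit).  ``irf1_feedback_off``
    replaces the IRF1 activation Hill term of STAT1 transcription by the
    constant 1 (the ``k_F -> 0`` saturation limit), removing the dependence
    of STAT1 mRNA production on IRF1.
    """

    socs1_feedback_off: bool = False
    irf1_feedback_off: bool = False


_NO_KO = KnockoutSpec()


def apply_knockout(p: ParameterSet, which: str = "none"):
    """Return ``(p, KnockoutSpec)`` for a named feedback knockout.

    Knockouts never modify the numeric parameter set; they flag structural
    term removal in :func:`rhs`, which is the numerically safe realization
    of the ``k_I -> inf`` / ``k_F -> 0`` limits.
    """
    if which == "none":
        return p, KnockoutSpec()
    if which == "socs1":
        return p, KnockoutSpec(socs1_feedback_off=True)
    if which == "irf1":
        return p, KnockoutSpec(irf1_feedback_off=True)
    raise UsageError(f"unknown knockout {which!r}; expected 'socs1', 'irf1' or 'none'")


def hill_activation(x, k, h):
    """Hill activation ``(x/k)^h / (1 + (x/k)^h)``.

    Strictly increasing in ``x``; 0 at ``x = 0``; 1/2 at ``x = k``; tends to
    1 as ``x -> inf``.  ``x`` may be a scalar or array.
    """
    if not (np.isfinite(k) and k > 0):
        raise InvalidParameterError(f"Hill threshold must be > 0, got {k!r}")
    if not float(h).is_integer() or h < 1:
        raise InvalidParameterError(f"Hill exponent must be an integer >= 1, got {h!r}")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise InvalidStateError("Hill activation input must be >= 0")
    z = (x / k) ** int(h)
    out = z / (1.0 + z)
    return out if out.shape else float(out)


def hill_derivative(x, k, h):
    """d/dx of :func:`hill_activation`: ``h*(x/k)^(h-1) / (k*(1+(x/k)^h)^2)``."""
    h = int(h)
    x = np.asarray(x, dtype=float)
    z = (x / k) ** h
    out = h * (x / k) ** (h - 1) / (k * (1.0 + z) ** 2)
    return out if out.shape else float(out)


def _phi_terms(A, S, R, p: ParameterSet, ko: KnockoutSpec):
    """Phosphorylation flux and its saturation denominator."""
    inhib = 0.0 if ko.socs1_feedback_off else (R / p.k_I) ** p.q
    denom = 1.0 + A / p.k_A + inhib
    return p.b_ph * S * (A / p.k_A) / denom, denom


def phosphorylation_flux(A, S, R, p: ParameterSet, ko: KnockoutSpec = _NO_KO):
    """STAT1 phosphorylation flux, molecules/min.

    ``b_ph * S * (A/k_A) / (1 + A/k_A + (R/k_I)^q)`` -- Michaelis-type
    saturation in the substrate A with competitive inhibition by the SOCS1
    protein R.  With the SOCS1 feedback off the inhibition term is removed
    entirely.  Non-negative; zero when ``S = 0`` or ``A = 0``;
    non-increasing in R.
    """
    if A < 0 or S < 0 or R < 0:
        raise InvalidStateError("phosphorylation flux inputs must be >= 0")
    phi, _ = _phi_terms(A, S, R, p, ko)
    return phi


def rhs(t, y, p: ParameterSet, ko: KnockoutSpec = _NO_KO, clamp_S: bool = False):
    """Right-hand side of the nine-ODE system, molecules/min per species.

    ``clamp_S`` holds the activated-receptor level constant (dS/dt = 0),
    the convention used for steady-state/stability analysis.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        bad = [SPECIES[i] for i in np.flatnonzero(~np.isfinite(y))]
        raise IntegrationFailureError(
            f"non-finite state at t={t}: species {', '.join(bad)}", last_good_time=t)
    S, A, Apc, Apn, r, R, f, F, a = y
    # stiff solvers probe transiently negative trial states; the nonlinear
    # saturation terms are evaluated at the clipped state, the linear terms
    # as-is, so roots and integration remain well defined
    Sp, Ap, Apnp, Rp, Fp = (max(v, 0.0) for v in (S, A, Apn, R, F))
    phi, _ = _phi_terms(Ap, Sp, Rp, p, ko)

    dS = 0.0 if clamp_S else p.b_S - p.lam_S * S
    dA = p.b_exp * Apn + p.b_deph * Apc + p.b_A * a - phi - p.lam_STAT * A
    dApc = phi - (p.b_imp + p.b_deph + p.lam_STAT) * Apc
    dApn = p.b_imp * Apc - (p.b_exp + p.lam_STAT) * Apn
    dr = p.b_r * hill_activation(Apnp, p.k_r, p.n) - p.lam_r * r
    dR = p.b_R * r - p.lam_R * R
    df = p.b_f * hill_activation(Apnp, p.k_f, p.m) - p.lam_f * f
    dF = p.b_F * f - p.lam_F * F
    stat1_promoter = 1.0 if ko.irf1_feedback_off else hill_activation(Fp, p.k_F, p.u)
    da = p.b_a * stat1_promoter - p.lam_a * a + p.B_STAT
    return np.array([dS, dA, dApc, dApn, dr, dR, df, dF, da])


def _phi_partials(A, S, R, p: ParameterSet, ko: KnockoutSpec):
    """(dPhi/dA, dPhi/dS, dPhi/dR) of the phosphorylation flux."""
    inhib = 0.0 if ko.socs1_feedback_off else (R / p.k_I) ** p.q
    denom = 1.0 + A / p.k_A + inhib
    dA = p.b_ph * S * (1.0 + inhib) / (p.k_A * denom ** 2)
    dS = p.b_ph * (A / p.k_A) / denom
    if ko.socs1_feedback_off:
        dR = 0.0
    else:
        dR = -p.b_ph * S * (A / p.k_A) * p.q * (R / p.k_I) ** (p.q - 1) / (p.k_I * denom ** 2)
    return dA, dS, dR


def jacobian(y, p: ParameterSet, ko: KnockoutSpec = _NO_KO, clamp_S: bool = False):
    """Analytic Jacobian of :func:`rhs` at state ``y``, 1/min.

    Returns the full 9x9 matrix, or the 8x8 matrix of the free species when
    ``clamp_S`` is set (S enters as a fixed external constant; its row and
    column are removed).
    """
    y = np.asarray(y, dtype=float)
    S, A, Apc, Apn, r, R, f, F, a = y
    dphi_dA, dphi_dS, dphi_dR = _phi_partials(A, S, R, p, ko)
    i = {nm: k for k, nm in enumerate(SPECIES)}
    J = np.zeros((9, 9))

    J[i["S"], i["S"]] = -p.lam_S
    J[i["A"], i["A"]] = -dphi_dA - p.lam_STAT
    J[i["A"], i["S"]] = -dphi_dS
    J[i["A"], i["R"]] = -dphi_dR
    J[i["A"], i["Apc"]] = p.b_deph
    J[i["A"], i["Apn"]] = p.b_exp
    J[i["A"], i["a"]] = p.b_A
    J[i["Apc"], i["A"]] = dphi_dA
    J[i["Apc"], i["S"]] = dphi_dS
    J[i["Apc"], i["R"]] = dphi_dR
    J[i["Apc"], i["Apc"]] = -(p.b_imp + p.b_deph + p.lam_STAT)
    J[i["Apn"], i["Apc"]] = p.b_imp
    J[i["Apn"], i["Apn"]] = -(p.b_exp + p.lam_STAT)
    J[i["r"], i["Apn"]] = p.b_r * hill_derivative(Apn, p.k_r, p.n)
    J[i["r"], i["r"]] = -p.lam_r
    J[i["R"], i["r"]] = p.b_R
    J[i["R"], i["R"]] = -p.lam_R
    J[i["f"], i["Apn"]] = p.b_f * hill_derivative(Apn, p.k_f, p.m)
    J[i["f"], i["f"]] = -p.lam_f
    J[i["F"], i["f"]] = p.b_F
    J[i["F"], i["F"]] = -p.lam_F
    if not ko.irf1_feedback_off:
        J[i["a"], i["F"]] = p.b_a * hill_derivative(F, p.k_F, p.u)
    J[i["a"], i["a"]] = -p.lam_a

    if clamp_S:
        return J[1:, 1:].copy()
    return J
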
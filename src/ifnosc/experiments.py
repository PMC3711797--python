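"""In-silico experiments: basal response, feedback knockouts, receptor sweeps.

These are the scripted, fully deterministic pipeline stages that reproduce
the model's headline behaviours:

* the basal damped-oscillatory response (second pSTAT1 peak ~200 min,
  SOCS1 mRNA peaks ~90 and ~250 min, bell-shaped IRF1 mRNA decaying to
  half-max ~350 min, slow late rise of STAT1 mRNA and protein);
* removing the SOCS1 negative feedback, which abolishes the oscillation
  and leaves a 4-5 h plateau of high pSTAT1;
* removing the IRF1 positive feedback, which leaves the oscillation intact
  but abolishes the late rise of STAT1 expression;
* sweeping the initial number of activated receptors, which shrinks the
  second peaks of pSTAT1 and SOCS1 mRNA, the SOCS1 peak vanishing first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import UsageError
from .metrics import Peak, find_local_maxima, half_max_decay_time, high_plateau_duration
from .model_core import ParameterSet, StateVector, apply_knockout
from .simulator import Trajectory, simulate

__all__ = [
    "BasalResult",
    "KnockoutResult",
    "ReceptorSweepResult",
    "basal_experiment",
    "run_knockout_experiment",
    "receptor_sweep",
    "rise_time",
    "DEFAULT_SWEEP_S0",
]

#: Default initial-receptor sweep (molecules/cell); includes the published
#: reference value (1000) and the half-dose example (500).
DEFAULT_SWEEP_S0 = (50.0, 125.0, 250.0, 500.0, 1000.0)

RISE_THRESHOLD = 1.05  # "begins to rise": first crossing of 105% of t=0 value


def rise_time(times, values, threshold: float = RISE_THRESHOLD) -> Optional[float]:
    """First time the series exceeds ``threshold`` times its initial value,
    or None if it never does."""
    values = np.asarray(values, dtype=float)
    above = np.flatnonzero(values > threshold * values[0])
    return float(np.asarray(times)[above[0]]) if above.size else None


def _nth_peak(peaks, k):
    return peaks[k] if len(peaks) > k else None


@dataclass(frozen=True)
class BasalResult:
    """Headline metrics of the reference simulation over [0, 480] min."""

    trajectory: Trajectory
    pstat1_peaks: tuple                  # retained peaks of Apc+Apn
    socs1_mrna_peaks: tuple              # retained peaks of r
    irf1_mrna_half_decay_time: Optional[float]
    stat1_mrna_rise_time: Optional[float]
    stat1_protein_rise_time: Optional[float]

    @property
    def pstat1_first_peak(self) -> Optional[Peak]:
        return _nth_peak(self.pstat1_peaks, 0)

    @property
    def pstat1_second_peak(self) -> Optional[Peak]:
        return _nth_peak(self.pstat1_peaks, 1)

    def metrics_frame(self) -> pd.DataFrame:
        rows = [
            ("first_peak_time", "pSTAT1_total",
             self.pstat1_first_peak.time if self.pstat1_first_peak else np.nan, "min"),
            ("second_peak_time", "pSTAT1_total",
             self.pstat1_second_peak.time if self.pstat1_second_peak else np.nan, "min"),
            ("second_peak_value", "pSTAT1_total",
             self.pstat1_second_peak.value if self.pstat1_second_peak else np.nan,
             "molecules"),
            ("half_max_decay_time", "f", self.irf1_mrna_half_decay_time, "min"),
            ("rise_time", "a", self.stat1_mrna_rise_time, "min"),
            ("rise_time", "STAT1_protein_total", self.stat1_protein_rise_time, "min"),
        ]
        for k, pk in enumerate(self.socs1_mrna_peaks):
            rows.append((f"peak{k + 1}_time", "r", pk.time, "min"))
        return pd.DataFrame(rows, columns=["metric", "series", "value", "units"])


def basal_experiment(p: ParameterSet = None, y0: StateVector = None,
                     t_end: float = 480.0, dt_out: float = 1.0) -> BasalResult:
    """Run the reference simulation and extract its headline features."""
    traj = simulate(p=p, y0=y0, t_end=t_end, dt_out=dt_out)
    t = traj.times
    return BasalResult(
        trajectory=traj,
        pstat1_peaks=tuple(find_local_maxima(t, traj.series("pSTAT1_total"))),
        socs1_mrna_peaks=tuple(find_local_maxima(t, traj.series("r"))),
        irf1_mrna_half_decay_time=half_max_decay_time(t, traj.series("f")),
        stat1_mrna_rise_time=rise_time(t, traj.series("a")),
        stat1_protein_rise_time=rise_time(t, traj.series("STAT1_protein_total")),
    )


@dataclass(frozen=True)
class KnockoutResult:
    """Paired basal/knockout trajectories with per-series peak metrics.

    ``metrics`` maps run ("basal" | "knockout") -> series -> dict with
    ``peaks`` (retained) and ``plateau_min`` (total minutes at >= 50% of
    the series maximum).
    """

    which: str
    basal: Trajectory
    knockout: Trajectory
    metrics: dict

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for run, per_series in self.metrics.items():
            for series, m in per_series.items():
                rows.append((run, series, len(m["peaks"]), m["plateau_min"]))
        return pd.DataFrame(rows, columns=["run", "series", "n_peaks",
                                           "plateau_min_at_half_max"])


_KO_SERIES = ("pSTAT1_total", "r", "a")


def run_knockout_experiment(which: str, p: ParameterSet = None,
                            y0: StateVector = None, t_end: float = 480.0,
                            dt_out: float = 1.0) -> KnockoutResult:
    """Simulate a feedback knockout next to the basal model on one grid."""
    if which not in ("socs1", "irf1"):
        raise UsageError(f"unknown knockout {which!r}; expected 'socs1' or 'irf1'")
    p = p or ParameterSet()
    y0 = y0 or StateVector.default_initial()
    p_ko, ko = apply_knockout(p, which)
    basal = simulate(p=p, y0=y0, t_end=t_end, dt_out=dt_out)
    knockout = simulate(p=p_ko, y0=y0, ko=ko, t_end=t_end, dt_out=dt_out)
    metrics = {}
    for run_name, traj in (("basal", basal), ("knockout", knockout)):
        per_series = {}
        for nm in _KO_SERIES:
            s = traj.series(nm)
            per_series[nm] = {
                "peaks": tuple(find_local_maxima(traj.times, s)),
                "plateau_min": high_plateau_duration(traj.times, s, 0.5),
            }
        metrics[run_name] = per_series
    return KnockoutResult(which=which, basal=basal, knockout=knockout,
                          metrics=metrics)


@dataclass(frozen=True)
class ReceptorSweepResult:
    """Per-S0 trajectories and the second-peak amplitude table.

    ``table`` is sorted by S0 with NaN for an absent second peak.
    """

    trajectories: dict
    table: pd.DataFrame


def receptor_sweep(S0_values=DEFAULT_SWEEP_S0, p: ParameterSet = None,
                   y0: StateVector = None, t_end: float = 480.0,
                   dt_out: float = 1.0) -> ReceptorSweepResult:
    """Repeat the basal simulation for several initial receptor levels."""
    p = p or ParameterSet()
    y0 = y0 or StateVector.default_initial()
    if any(s0 < 0 for s0 in S0_values):
        raise UsageError("all S0 values must be >= 0")
    trajectories = {}
    rows = []
    for s0 in sorted(float(v) for v in S0_values):
        traj = simulate(p=p, y0=y0.replace(S=s0), t_end=t_end, dt_out=dt_out)
        trajectories[s0] = traj
        row = {"S0": s0}
        for nm, col in (("pSTAT1_total", "pstat1"), ("r", "socs1_mrna")):
            pk = _nth_peak(find_local_maxima(traj.times, traj.series(nm)), 1)
            row[f"{col}_second_peak_time"] = pk.time if pk else np.nan
            row[f"{col}_second_peak_value"] = pk.value if pk else np.nan
        rows.append(row)
    return ReceptorSweepResult(trajectories=trajectories,
                               table=pd.DataFrame(rows).sort_values("S0",
                                                                    ignore_index=True))
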
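"""One-at-a-time +/-20% parameter perturbation envelopes.

Robustness of the simulated time courses is summarized by re-running the
model with every real-valued parameter scaled by (1 +/- fraction), one at a
time, and taking the pointwise min/max across all runs (basal included).
The Hill exponents are integers and are excluded from perturbation.  All
runs are normalized by the *basal* run's per-series maximum so the envelope
shares the basal curve's scale and brackets it by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd

from .errors import IntegrationFailureError, UsageError
from .model_core import KnockoutSpec, ParameterSet, StateVector
from .simulator import simulate

__all__ = ["SensitivityEnvelope", "sensitivity_envelope", "DEFAULT_SERIES"]

log = logging.getLogger(__name__)

#: Series observed in the assays: total pSTAT1 and STAT1 protein, SOCS1
#: protein, and STAT1/IRF1/SOCS1 mRNA.
DEFAULT_SERIES = ("pSTAT1_total", "STAT1_protein_total", "R", "a", "f", "r")


@dataclass(frozen=True)
class SensitivityEnvelope:
    """Pointwise envelope over all perturbed runs, basal-normalized.

    ``basal``, ``lower``, ``upper`` map series name -> array on ``times``.
    ``runs`` lists the (parameter, direction) pairs simulated; ``failed``
    the runs excluded because integration did not converge.
    """

    times: np.ndarray
    basal: dict
    lower: dict
    upper: dict
    runs: tuple
    failed: tuple
    fraction: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for nm in self.basal:
            for k, t in enumerate(self.times):
                rows.append((t, nm, self.basal[nm][k], self.lower[nm][k],
                             self.upper[nm][k]))
        return pd.DataFrame(rows, columns=["time_min", "series", "basal",
                                           "lower", "upper"])


def sensitivity_envelope(p: ParameterSet = None, y0: StateVector = None,
                         fraction: float = 0.2, series_names=DEFAULT_SERIES,
                         ko: KnockoutSpec = None, t_end: float = 480.0,
                         dt_out: float = 1.0) -> SensitivityEnvelope:
    """Envelope of all one-parameter +/-``fraction`` perturbations.

    Exactly ``2 * len(perturbable parameters)`` perturbed runs are
    attempted; a run that fails to integrate is flagged and excluded with a
    warning rather than aborting the envelope.
    """
    if not 0 < fraction < 1:
        raise UsageError("fraction must be in (0, 1)")
    p = p or ParameterSet()
    y0 = y0 or StateVector.default_initial()

    basal_traj = simulate(p=p, y0=y0, ko=ko, t_end=t_end, dt_out=dt_out)
    basal_raw = {nm: basal_traj.series(nm) for nm in series_names}
    scale = {nm: (s.max() if s.max() > 0 else 1.0) for nm, s in basal_raw.items()}
    basal = {nm: basal_raw[nm] / scale[nm] for nm in series_names}
    lower = {nm: basal[nm].copy() for nm in series_names}
    upper = {nm: basal[nm].copy() for nm in series_names}

    runs, failed = [], []
    for name in ParameterSet.perturbable_names():
        for direction in (+1, -1):
            factor = 1.0 + direction * fraction
            pp = p.replace(**{name: getattr(p, name) * factor})
            try:
                traj = simulate(p=pp, y0=y0, ko=ko, t_end=t_end, dt_out=dt_out)
            except IntegrationFailureError as exc:
                log.warning("perturbed run %s %+d%% failed and was excluded: %s",
                            name, int(direction * fraction * 100), exc)
                failed.append((name, direction))
                continue
            runs.append((name, direction))
            for nm in series_names:
                s = traj.series(nm) / scale[nm]
                np.minimum(lower[nm], s, out=lower[nm])
                np.maximum(upper[nm], s, out=upper[nm])
    return SensitivityEnvelope(times=basal_traj.times, basal=basal,
                               lower=lower, upper=upper, runs=tuple(runs),
                               failed=tuple(failed), fraction=fraction)
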
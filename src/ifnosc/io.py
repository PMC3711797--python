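"""Configuration loading and trajectory CSV round-trips.

Configuration is a flat YAML mapping whose keys are the kinetic-parameter
symbols (``b_ph: 1300``), species initial values prefixed ``init_``
(``init_S: 500``) and the run options ``t_end`` / ``dt_out``.  Command-line
``NAME=VALUE`` overrides are applied after the file.  Unknown keys are
rejected loudly, and the fully resolved configuration can be echoed to a
provenance sidecar next to every CSV output.

Trajectories are written as tidy CSV with the fixed schema
``time_min, species, value, run_id``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import (ConfigError, InvalidParameterError, InvalidStateError,
                     ParseError)
from .model_core import SPECIES, ParameterSet, StateVector
from .simulator import Trajectory

__all__ = [
    "load_config",
    "resolved_config",
    "write_trajectory",
    "read_trajectory",
    "write_provenance",
]

_OPTION_KEYS = {"t_end", "dt_out"}
TRAJECTORY_COLUMNS = ["time_min", "species", "value", "run_id"]


def _parse_value(key, raw):
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise ConfigError(f"non-numeric value for {key!r}: {raw!r}") from None


def load_config(path=None, overrides=()):
    """Resolve ``(ParameterSet, StateVector, options)`` from defaults,
    an optional YAML file, and ``NAME=VALUE`` override strings, in order."""
    params = {}
    inits = {}
    options = {}

    def apply(key, value):
        if key in ParameterSet.names():
            params[key] = _parse_value(key, value)
        elif key.startswith("init_") and key[5:] in SPECIES:
            inits[key[5:]] = _parse_value(key, value)
        elif key in _OPTION_KEYS:
            options[key] = _parse_value(key, value)
        else:
            raise ConfigError(f"unknown configuration key {key!r}")

    if path is not None:
        text = Path(path).read_text()
        try:
            doc = yaml.safe_load(text) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"invalid YAML in {path}: {exc}") from None
        if not isinstance(doc, dict):
            raise ConfigError(f"configuration {path} must be a flat mapping")
        for key, value in doc.items():
            apply(str(key), value)
    for item in overrides:
        if "=" not in item:
            raise ConfigError(f"override {item!r} is not NAME=VALUE")
        key, _, value = item.partition("=")
        apply(key.strip(), value.strip())

    try:
        p = ParameterSet().replace(**params)
        y0 = StateVector.default_initial().replace(**inits)
    except (InvalidParameterError, InvalidStateError) as exc:
        raise ConfigError(str(exc)) from None
    return p, y0, options


def resolved_config(p: ParameterSet, y0: StateVector, options=None) -> dict:
    """The fully resolved configuration, ready for a provenance sidecar."""
    out = dict(p.as_dict())
    out.update({f"init_{nm}": getattr(y0, nm) for nm in SPECIES})
    if options:
        out.update(options)
    return out


def write_provenance(path, p: ParameterSet, y0: StateVector, options=None,
                     extra=None):
    doc = resolved_config(p, y0, options)
    if extra:
        doc.update(extra)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def write_trajectory(traj: Trajectory, path, run_id: str = "run",
                     provenance: bool = True):
    """Write a trajectory as tidy CSV (plus a YAML provenance sidecar)."""
    path = Path(path)
    frame = traj.to_frame(run_id=run_id)
    frame.to_csv(path, index=False, float_format="%.17g")
    if provenance and traj.params is not None:
        write_provenance(f"{path}.provenance.yaml", traj.params, traj.initial,
                         traj.solver_options)
    return path


def read_trajectory(path) -> Trajectory:
    """Read a tidy trajectory CSV back into a :class:`Trajectory`.

    The schema is validated; the first offending line is reported by
    number.  Provenance is not reconstructed from the sidecar.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype={"time_min": float, "species": str,
                                         "value": float, "run_id": str})
    except ValueError as exc:
        raise ParseError(f"malformed trajectory CSV {path}: {exc}") from None
    if list(frame.columns) != TRAJECTORY_COLUMNS:
        raise ParseError(
            f"bad header in {path}: expected {TRAJECTORY_COLUMNS}, "
            f"got {list(frame.columns)}", line=1)
    bad = ~frame["species"].isin(SPECIES)
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"unknown species {frame['species'].iloc[idx]!r} in {path}",
            line=idx + 2)
    if frame[["time_min", "value"]].isna().any().any():
        idx = int(frame[["time_min", "value"]].isna().any(axis=1).to_numpy().argmax())
        raise ParseError(f"missing numeric value in {path}", line=idx + 2)
    wide = frame.pivot_table(index="time_min", columns="species",
                             values="value", sort=True)
    missing = set(SPECIES) - set(wide.columns)
    if missing:
        raise ParseError(f"species missing from {path}: {sorted(missing)}")
    times = wide.index.to_numpy(dtype=float)
    states = wide.loc[:, list(SPECIES)].to_numpy(dtype=float)
    return Trajectory(times=times, states=states)
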
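"""Plain-text formats: TSV traces, JSON manifests and reports.

Traces are two-column TSV files with a ``#``-prefixed metadata header::

    # kind: energy
    # replica_id: bd0_F0.42_r0001
    # true_rupture_time: 1.2345
    # scenario: {"b_d": 0, ...}
    time\tenergy_kT
    0\t-0.31
    ...

Round-trips are lossless at full double precision (%.17g).  A thin
column-extraction adapter for whitespace-delimited thermo-style logs is
also provided.
"""

from __future__ import annotations

import json
import logging
from typing import Optional, Union

import numpy as np

from .mechanics import ScenarioConfig
from .synthetic import DistanceTrace, EnergyTrace, EnsembleManifest

logger = logging.getLogger("dsbkinetics")

_COLUMNS = {"energy": ("time", "energy_kT"),
            "distance": ("time", "min_distance_nm")}


class TraceParseError(ValueError):
    """Malformed trace file; the message names the offending line."""


def write_trace(path: str, trace: Union[EnergyTrace, DistanceTrace]) -> str:
    """Write one trace as TSV with a metadata header."""
    if isinstance(trace, EnergyTrace):
        kind, values = "energy", trace.energies
    else:
        kind, values = "distance", trace.min_distance
    cols = _COLUMNS[kind]
    with open(path, "w") as fh:
        fh.write(f"# kind: {kind}\n")
        if trace.replica_id is not None:
            fh.write(f"# replica_id: {trace.replica_id}\n")
        if trace.true_rupture_time is not None:
            fh.write(f"# true_rupture_time: {trace.true_rupture_time!r}\n")
        if trace.scenario is not None:
            fh.write(f"# scenario: {json.dumps(trace.scenario.to_dict())}\n")
        fh.write("\t".join(cols) + "\n")
        for t, v in zip(trace.times, values):
            fh.write(f"{t:.17g}\t{v:.17g}\n")
    return path


def read_trace(path: str) -> Union[EnergyTrace, DistanceTrace]:
    """Read a TSV trace, validating the header and time monotonicity."""
    meta = {}
    times, values = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if ":" not in line:
                    raise TraceParseError(
                        f"{path}:{lineno}: malformed metadata line")
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
                continue
            parts = line.split("\t")
            if parts[0] == "time":   # column header
                continue
            if len(parts) != 2:
                raise TraceParseError(
                    f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                times.append(float(parts[0]))
                values.append(float(parts[1]))
            except ValueError:
                raise TraceParseError(
                    f"{path}:{lineno}: non-numeric value") from None

    kind = meta.get("kind")
    if kind not in _COLUMNS:
        logger.warning("%s: missing/unknown 'kind' metadata; "
                       "defaulting to energy", path)
        kind = "energy"
    t = np.asarray(times)
    if t.size >= 2 and not np.all(np.diff(t) > 0):
        bad = int(np.nonzero(np.diff(t) <= 0)[0][0]) + 2
        raise TraceParseError(
            f"{path}: time column not strictly increasing at data row {bad}")

    scenario = None
    if "scenario" in meta:
        scenario = ScenarioConfig.from_dict(json.loads(meta["scenario"]))
    truth = (float(meta["true_rupture_time"])
             if "true_rupture_time" in meta else None)
    rid = meta.get("replica_id")
    cls = EnergyTrace if kind == "energy" else DistanceTrace
    kwargs = {"times": t, "scenario": scenario, "replica_id": rid,
              "true_rupture_time": truth}
    if kind == "energy":
        kwargs["energies"] = np.asarray(values)
    else:
        kwargs["min_distance"] = np.asarray(values)
    return cls(**kwargs)


def read_manifest(path: str) -> EnsembleManifest:
    with open(path) as fh:
        return EnsembleManifest.from_json(fh.read())


def write_json(path: str, obj: dict) -> str:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_jsonable)
    return path


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dict__"):
        return vars(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def read_thermo_log(path: str, time_col: int, value_col: int,
                    comment: str = "#") -> tuple:
    """Extract (time, value) columns from a whitespace-delimited log.

    Generic adapter for thermo-style output; returns two float arrays.
    """
    data = np.loadtxt(path, comments=comment, usecols=(time_col, value_col),
                      ndmin=2)
    return data[:, 0], data[:, 1]
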
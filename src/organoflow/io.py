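"""Reading and writing parameter sets, solutions and metrics.

Parameter sets are flat YAML or JSON mappings whose keys are exactly the
dataclass field names.  Solutions are tidy CSV (one row per grid point and
time) with a single ``# organoflow-meta: {...}`` JSON comment line carrying
the coefficients and provenance, so a saved 1D solution can be reloaded and
its metrics recomputed without the original config.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .full2d import Field2DSolution
from .longwave import Field1DSolution
from .metrics import MetricSeries
from .params import DimensionalParameters, DimensionlessGroups, LongwaveCoefficients

__all__ = [
    "load_parameters",
    "save_parameters",
    "solution_to_frame",
    "save_solution",
    "load_solution_1d",
    "save_metrics",
]

_META_PREFIX = "# organoflow-meta: "


def load_parameters(path, kind: str = "dimensional"):
    """Load a parameter set from a flat YAML/JSON file.

    ``kind`` selects the target type: "dimensional" or "dimensionless".
    Unknown keys raise, naming the offending field.
    """
    cls = {"dimensional": DimensionalParameters, "dimensionless": DimensionlessGroups}[kind]
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path} does not contain a flat parameter mapping")
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown parameter field(s) {sorted(unknown)} for {cls.__name__}")
    return cls(**{k: float(v) for k, v in data.items()})


def save_parameters(params, path) -> None:
    """Write a parameter dataclass as flat YAML (or JSON for .json paths)."""
    data = dataclasses.asdict(params)
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def solution_to_frame(sol) -> pd.DataFrame:
    """Tidy DataFrame of a 1D or 2D solution (columns T, X[, Z], C, W)."""
    if isinstance(sol, Field2DSolution):
        t, x, z = np.meshgrid(sol.times, sol.grid.X, sol.grid.Z, indexing="ij")
        return pd.DataFrame(
            {
                "T": t.ravel(),
                "X": x.ravel(),
                "Z": z.ravel(),
                "C": sol.C.ravel(),
                "W": sol.W.ravel(),
            }
        )
    t, x = np.meshgrid(sol.times, sol.X, indexing="ij")
    return pd.DataFrame(
        {"T": t.ravel(), "X": x.ravel(), "C": sol.C.ravel(), "W": sol.W.ravel()}
    )


def save_solution(sol, path) -> None:
    """Write a solution as tidy CSV with a JSON metadata header line."""
    frame = solution_to_frame(sol)
    if isinstance(sol, Field2DSolution):
        meta = {"kind": "2d", "groups": dataclasses.asdict(sol.groups)}
    else:
        meta = {
            "kind": "1d",
            "provenance": sol.provenance,
            "coeffs": dataclasses.asdict(sol.coeffs),
        }
    with open(path, "w") as fh:
        fh.write(_META_PREFIX + json.dumps(meta) + "\n")
        frame.to_csv(fh, index=False)


def load_solution_1d(path) -> Field1DSolution:
    """Reload a 1D solution written by :func:`save_solution`."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith(_META_PREFIX):
        raise ValueError(f"{path} is missing the organoflow metadata header")
    meta = json.loads(first[len(_META_PREFIX):])
    if meta.get("kind") != "1d":
        raise ValueError(f"{path} holds a {meta.get('kind')} solution, expected 1d")
    frame = pd.read_csv(path, comment="#")
    times = np.unique(frame["T"].to_numpy())
    X = np.unique(frame["X"].to_numpy())
    shape = (len(times), len(X))
    pivot = frame.sort_values(["T", "X"])
    return Field1DSolution(
        X=X,
        times=times,
        C=pivot["C"].to_numpy().reshape(shape),
        W=pivot["W"].to_numpy().reshape(shape),
        coeffs=LongwaveCoefficients(**meta["coeffs"]),
        provenance=meta.get("provenance", "longwave"),
    )


def save_metrics(series: MetricSeries, csv_path, summary_path=None) -> None:
    """Metric series as tidy CSV plus an optional scalar-summary JSON."""
    frame = pd.DataFrame(
        {
            "T": series.times,
            "Q": series.Q,
            "W_max": series.W_max,
            "X_max": series.X_max,
            "C_min": series.C_min,
            "P_U": series.P_U,
            "W_outlet": series.W_outlet,
        }
    )
    frame.to_csv(csv_path, index=False)
    if summary_path is not None:
        Path(summary_path).write_text(json.dumps(series.summary(), indent=2) + "\n")
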
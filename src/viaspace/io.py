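"""Persistence: viable sets and trajectories as CSV, manifests as JSON.

All tabular artifacts are plain CSV with a one-line ``#`` unit comment;
parameter columns always follow the :class:`~viaspace.models.ParameterSpace`
order and stay in original parameter units (never PCA coordinates).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ga import ViableSet
from .models import ParameterSpace, Trajectory

__all__ = [
    "save_viable_set",
    "load_viable_set",
    "save_trajectory",
    "load_trajectory",
    "save_manifest",
    "load_manifest",
]

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


def save_viable_set(vs: ViableSet, space: ParameterSpace, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(vs.points, columns=list(space.names))
    df["cost"] = vs.costs
    df["label"] = vs.labels or [""] * len(vs)
    with open(path, "w") as fh:
        fh.write("# rates in 1/h, concentrations in nM; cost per its cost function\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def load_viable_set(path: str | Path, space: ParameterSpace) -> ViableSet:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [n for n in space.names if n not in df.columns]
    if missing:
        raise ValueError(f"viable-set file lacks parameter columns {missing}")
    labels = (
        df["label"].fillna("").astype(str).tolist() if "label" in df.columns else []
    )
    return ViableSet(
        points=df[list(space.names)].to_numpy(dtype=float),
        costs=df["cost"].to_numpy(dtype=float)
        if "cost" in df.columns
        else np.zeros(len(df)),
        labels=labels,
    )


def save_trajectory(traj: Trajectory, path: str | Path) -> None:
    df = pd.DataFrame(traj.y, columns=list(traj.species))
    df.insert(0, "time", traj.t)
    with open(path, "w") as fh:
        fh.write("# time in h, concentrations in nM\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def load_trajectory(path: str | Path) -> Trajectory:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    species = tuple(c for c in df.columns if c != "time")
    return Trajectory(t=df["time"].to_numpy(dtype=float),
                      y=df[list(species)].to_numpy(dtype=float), species=species)


def save_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=_jsonable)
        fh.write("\n")


def load_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
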
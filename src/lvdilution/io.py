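"""Readers and writers for the package's file formats.

Formats are deliberately plain: YAML/JSON for parameters, schedules and
manifests, tidy UTF-8 CSV (comma, header row, '.' decimal) for trajectories,
diagrams, counts and OD curves.  Every writer round-trips through its
matching reader.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .infer import ODCurve
from .params import (
    CommunityParams,
    DilutionSchedule,
    normalize_dilution_factor,
    rate_to_per_day,
)
from .simulate import BifurcationDiagram, Trajectory

log = logging.getLogger("lvdilution")


def _load_structured(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _dump_structured(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(obj, sort_keys=False))


# ---------------------------------------------------------------------------
# community parameters
# ---------------------------------------------------------------------------

def read_params(path) -> CommunityParams:
    """Read a parameter file.

    Schema::

        species:
          - {name: Pp, r: 0.75, unit: 1/hour, K: 1.2}   # K optional
          - {name: Pv, r: 0.50, unit: 1/hour}
        alpha:            # row i = affected species, column j = competitor
          - [1.0, 1.68]
          - [0.88, 1.0]
    """
    data = _load_structured(path)
    if not isinstance(data, dict) or "species" not in data or "alpha" not in data:
        raise ValidationError(f"{path}: parameter file needs 'species' and 'alpha' keys")
    species = data["species"]
    if not isinstance(species, list) or not species:
        raise ValidationError(f"{path}: 'species' must be a non-empty list")
    names, r, K = [], [], []
    for entry in species:
        try:
            names.append(str(entry["name"]))
            unit = entry.get("unit", "1/day")
            r.append(rate_to_per_day(float(entry["r"]), unit))
        except (KeyError, TypeError, ValueError) as exc:
            raise ValidationError(f"{path}: bad species entry {entry!r}: {exc}") from exc
        K.append(float(entry["K"]) if "K" in entry else np.nan)
    alpha = np.asarray(data["alpha"], dtype=float)
    K_arr = None if np.isnan(K).any() else np.asarray(K)
    if np.isnan(K).any() and not np.isnan(K).all():
        raise ValidationError(f"{path}: give K for every species or for none")
    return CommunityParams(tuple(names), np.asarray(r), alpha, K=K_arr)


def write_params(params: CommunityParams, path) -> None:
    data = {
        "species": [
            {
                "name": n,
                "r": float(params.r[k]),
                "unit": "1/day",
                **({"K": float(params.K[k])} if params.K is not None else {}),
            }
            for k, n in enumerate(params.species_names)
        ],
        "alpha": [[float(x) for x in row] for row in params.alpha],
    }
    _dump_structured(data, path)


# ---------------------------------------------------------------------------
# dilution schedules
# ---------------------------------------------------------------------------

def read_schedule(path) -> DilutionSchedule:
    """Read a schedule: either a bare list of DFs or {dfs: [...], cycle_hours: h}.

    Entries below 1 are read as fraction-kept notation (10^-3 of the culture
    transferred == 10^3-fold dilution) and normalized, with a log record of
    the conversion.
    """
    data = _load_structured(path)
    if isinstance(data, list):
        dfs, cycle_hours = data, 24.0
    elif isinstance(data, dict) and "dfs" in data:
        dfs = data["dfs"]
        cycle_hours = float(data.get("cycle_hours", 24.0))
    else:
        raise ValidationError(f"{path}: schedule must be a list or have a 'dfs' key")
    norm = []
    for d in dfs:
        nd = normalize_dilution_factor(float(d))
        if nd != d:
            log.info("normalized fraction-kept dilution %g to fold dilution %g", d, nd)
        norm.append(nd)
    return DilutionSchedule(tuple(norm), cycle_hours=cycle_hours)


def write_schedule(schedule: DilutionSchedule, path) -> None:
    _dump_structured(
        {"dfs": [float(d) for d in schedule.dfs], "cycle_hours": schedule.cycle_hours}, path
    )


# ---------------------------------------------------------------------------
# trajectories and diagrams
# ---------------------------------------------------------------------------

def write_trajectory(traj: Trajectory, path) -> None:
    """Tidy CSV plus a .meta.json sidecar (schedule, convergence flag)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    traj.to_frame().to_csv(path, index=False)
    meta = {
        "species": list(traj.species_names),
        "schedule": {"dfs": list(traj.schedule.dfs), "cycle_hours": traj.schedule.cycle_hours},
        "converged": traj.converged,
    }
    _dump_structured(meta, path.with_suffix(path.suffix + ".meta.json"))


def read_trajectory(path) -> Trajectory:
    path = Path(path)
    frame = pd.read_csv(path)
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    species = tuple(meta["species"])
    wide = frame.pivot(index="cycle", columns="species", values="abundance")[list(species)]
    dfs_applied = (
        frame[frame.species == species[0]].sort_values("cycle")["df_applied"].to_numpy()[1:]
    )
    dfs_applied = dfs_applied[~np.isnan(dfs_applied)]
    return Trajectory(
        species_names=species,
        abundances=wide.sort_index().to_numpy(),
        dfs_applied=dfs_applied,
        schedule=DilutionSchedule(
            tuple(meta["schedule"]["dfs"]), cycle_hours=meta["schedule"]["cycle_hours"]
        ),
        converged=bool(meta["converged"]),
    )


def write_bifurcation(diagram: BifurcationDiagram, path, endpoint_path=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    diagram.to_frame().to_csv(path, index=False)
    if endpoint_path is not None:
        diagram.endpoint_frame().to_csv(endpoint_path, index=False)


def read_bifurcation_frame(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = {"df", "branch_type", "fraction"} - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: bifurcation CSV missing columns {sorted(missing)}")
    return frame


# ---------------------------------------------------------------------------
# observations: colony counts and OD curves
# ---------------------------------------------------------------------------

COUNT_COLUMNS = ["day", "condition", "replicate", "species", "colonies"]


def write_counts(counts: pd.DataFrame, path) -> None:
    missing = set(COUNT_COLUMNS) - set(counts.columns)
    if missing:
        raise ValidationError(f"count table missing columns {sorted(missing)}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    counts[COUNT_COLUMNS].to_csv(path, index=False)


def read_counts(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(COUNT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: count table missing columns {sorted(missing)}")
    if (frame.colonies < 0).any() or (frame.colonies % 1 != 0).any():
        raise ValidationError(f"{path}: colony counts must be non-negative integers")
    return frame


OD_COLUMNS = ["time_h", "well", "species", "od", "equalized_od", "inoculum_dilution"]


def write_od_curves(curves: list[ODCurve], path) -> None:
    rows = []
    for c in curves:
        for t, od in zip(c.times_h, c.od):
            rows.append(
                {
                    "time_h": t,
                    "well": c.replicate,
                    "species": c.species,
                    "od": od,
                    "equalized_od": c.equalized_od,
                    "inoculum_dilution": c.inoculum_dilution,
                }
            )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=OD_COLUMNS).to_csv(path, index=False)


def read_od_curves(path) -> list[ODCurve]:
    frame = pd.read_csv(path)
    missing = set(OD_COLUMNS) - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: OD table missing columns {sorted(missing)}")
    curves = []
    for well, sub in frame.groupby("well", sort=False):
        sub = sub.sort_values("time_h")
        curves.append(
            ODCurve(
                times_h=sub.time_h.to_numpy(),
                od=sub.od.to_numpy(),
                equalized_od=float(sub.equalized_od.iloc[0]),
                inoculum_dilution=float(sub.inoculum_dilution.iloc[0]),
                species=str(sub.species.iloc[0]),
                replicate=str(well),
            )
        )
    return curves


def write_manifest(manifest: dict, path) -> None:
    _dump_structured(manifest, Path(path))
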
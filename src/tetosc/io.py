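"""Readers and writers: trace CSV, trajectory CSV, flat-text ensemble
dialect, and YAML/JSON configuration files.

Trace CSV schema: columns ``cell_id,time_min,intensity``; an empty
intensity field marks a missing frame.  Trajectory CSV is tidy:
``sim_id,time_min,species,count``.  The flat-text ensemble dialect writes
``particles.txt`` (one whitespace-delimited row of the 11 sampled rates
per simulation, in canonical rate order) and ``trajectories.txt`` (one row
per recorded time point, simulation-major: sim index, time, then the seven
species counts in canonical species order).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .network import (
    ParameterPrior,
    RATE_SYMBOLS,
    RateParameters,
    SPECIES,
    SpeciesState,
)
from .ode import ContinuousTrajectory
from .ssa import EnsembleResult, Trajectory
from .traces import FluorescenceTrace


class TraceParseError(ValueError):
    """Malformed trace CSV; the message names the offending line."""


def write_traces(traces, path) -> None:
    """Write traces as cell_id,time_min,intensity (empty field = missing)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["cell_id", "time_min", "intensity"])
        for tr in traces:
            for t, v, miss in zip(tr.times, tr.intensities, tr.missing):
                w.writerow([tr.cell_id, f"{t:g}", "" if miss else f"{v:.10g}"])


def read_traces(path) -> list[FluorescenceTrace]:
    """Parse a trace CSV back into per-cell traces (lossless round-trip)."""
    path = Path(path)
    rows: dict[str, list[tuple[float, float, bool, int]]] = {}
    order: list[str] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:3]] != ["cell_id", "time_min", "intensity"]:
            raise TraceParseError(
                f"{path}:1: expected header cell_id,time_min,intensity"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not f.strip() for f in row):
                continue
            if len(row) < 3:
                raise TraceParseError(f"{path}:{lineno}: expected 3 fields, got {len(row)}")
            cid, t_str, v_str = row[0], row[1].strip(), row[2].strip()
            try:
                t = float(t_str)
            except ValueError:
                raise TraceParseError(f"{path}:{lineno}: bad time {t_str!r}") from None
            if v_str == "":
                v, miss = float("nan"), True
            else:
                try:
                    v = float(v_str)
                except ValueError:
                    raise TraceParseError(
                        f"{path}:{lineno}: bad intensity {v_str!r}"
                    ) from None
                miss = False
            if cid not in rows:
                rows[cid] = []
                order.append(cid)
            rows[cid].append((t, v, miss, lineno))

    traces = []
    for cid in order:
        recs = rows[cid]
        times = np.array([r[0] for r in recs])
        vals = np.array([r[1] for r in recs])
        mask = np.array([r[2] for r in recs])
        if len(times) >= 3:
            d = np.diff(times)
            if (d <= 0).any() or not np.allclose(d, d[0], rtol=1e-9, atol=1e-9):
                bad = int(np.flatnonzero(~np.isclose(d, d[0]))[0]) + 1 \
                    if (d > 0).all() else int(np.flatnonzero(d <= 0)[0]) + 1
                raise TraceParseError(
                    f"{path}:{recs[bad][3]}: non-uniform time grid for cell {cid!r}"
                )
        traces.append(FluorescenceTrace(cell_id=cid, times=times,
                                        intensities=vals, missing=mask))
    return traces


def trajectory_frame(traj: Trajectory | ContinuousTrajectory,
                     sim_id: str | int = 0) -> pd.DataFrame:
    """Tidy long-format view of one trajectory."""
    vals = traj.counts if isinstance(traj, Trajectory) else traj.values
    n = len(traj.times)
    return pd.DataFrame({
        "sim_id": np.repeat(str(sim_id), n * len(SPECIES)),
        "time_min": np.tile(traj.times, len(SPECIES)),
        "species": np.repeat(SPECIES, n),
        "count": np.concatenate([vals[:, i] for i in range(len(SPECIES))]),
    })


def write_trajectories_csv(ensemble: EnsembleResult, path) -> None:
    frames = [trajectory_frame(tr, i) for i, tr in enumerate(ensemble.trajectories)]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_ode_csv(traj: ContinuousTrajectory, path) -> None:
    trajectory_frame(traj, "ode").to_csv(path, index=False)


def write_flat_ensemble(ensemble: EnsembleResult, out_dir) -> None:
    """Write particles.txt and trajectories.txt for an ensemble.

    particles.txt: row i holds the 11 rates of simulation i (k1 k2 k3 k4 o1
    o2 d1 d2 d3 d4 d5).  trajectories.txt: simulation-major rows of
    ``sim time mRNA_tetR TetR TetR2 tetO tetO_TetR2 mRNA_eGFP eGFP``.
    """
    if ensemble.n == 0:
        raise ValueError("cannot write an empty ensemble")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with (out_dir / "particles.txt").open("w") as fh:
        for params in ensemble.parameters:
            fh.write(" ".join(f"{v:.10g}" for v in params.as_array()) + "\n")
    with (out_dir / "trajectories.txt").open("w") as fh:
        for i, traj in enumerate(ensemble.trajectories):
            for g in range(len(traj.times)):
                counts = " ".join(str(int(c)) for c in traj.counts[g])
                fh.write(f"{i} {traj.times[g]:g} {counts}\n")


# -- configuration files -----------------------------------------------------

def load_config(path) -> dict:
    """Read a YAML or JSON config file into a dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def prior_from_config(cfg: dict) -> ParameterPrior:
    """Build a prior from a config dict.

    Recognised keys (all optional): ``prior`` mapping rate -> [lower, upper],
    ``fixed`` mapping rate -> value, ``S`` (Hill constant).
    """
    from .network import _DEFAULT_BOUNDS, D5_DEFAULT  # defaults live with the model

    bounds = dict(_DEFAULT_BOUNDS)
    fixed = {"d5": D5_DEFAULT}
    for sym, rng in (cfg.get("prior") or {}).items():
        bounds[sym] = (float(rng[0]), float(rng[1]))
        fixed.pop(sym, None)
    for sym, val in (cfg.get("fixed") or {}).items():
        fixed[sym] = float(val)
        bounds.pop(sym, None)
    return ParameterPrior(bounds=bounds, fixed=fixed, S=float(cfg.get("S", 0.0)))


def initial_state_from_config(cfg: dict) -> SpeciesState | str:
    """An explicit species mapping, or a scenario tag string."""
    init = cfg.get("initial_condition", "default_zero")
    if isinstance(init, str):
        return init
    return SpeciesState(**{k: int(v) for k, v in init.items()})


def write_summary_json(summaries: dict, path) -> None:
    Path(path).write_text(json.dumps(summaries, indent=2, sort_keys=True) + "\n")
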
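"""Plain-CSV session bundles and results serialization.

A session bundle directory contains::

    schedule.csv   lap_index, subtask, cue_state, origin, destination, correct, delay
    tracking.csv   t, x, y, head_direction_deg
    spikes.csv     unit_id, t
    units.csv      unit_id, spike_width_ms, class
    tuning.json    generator ground truth (field centers, gains)
    manifest.json  package version, master seed, derived component seeds

Bundles are written atomically (into a temporary sibling directory renamed
on success) so a failed run leaves no partial output.
"""

from __future__ import annotations

import json
import os
import shutil
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .taskmodel import MazeGeometry, Lap, LapSchedule, SpikeTrain, TrackingSeries
from .session import Session, SEED_OFFSETS, lap_table


def write_bundle(session: Session, outdir, config=None):
    outdir = Path(outdir)
    outdir.parent.mkdir(parents=True, exist_ok=True)
    tmp = Path(tempfile.mkdtemp(prefix=outdir.name + ".", dir=outdir.parent))
    try:
        lap_table(session.schedule).to_csv(tmp / "schedule.csv", index=False)
        tr = session.tracking
        pd.DataFrame({"t": tr.t, "x": tr.x, "y": tr.y,
                      "head_direction_deg": tr.head_direction}).to_csv(
            tmp / "tracking.csv", index=False, float_format="%.5f")
        pd.concat([pd.DataFrame({"unit_id": s.unit_id, "t": s.spike_times})
                   for s in session.spikes], ignore_index=True).to_csv(
            tmp / "spikes.csv", index=False, float_format="%.5f")
        session.units.drop(columns=["mean_rate_hz"]).to_csv(
            tmp / "units.csv", index=False)
        if session.tuning is not None:
            with open(tmp / "tuning.json", "w") as fh:
                json.dump(tuning_ground_truth(session.tuning), fh, indent=1)
        manifest = {
            "package_version": __version__,
            "master_seed": session.master_seed,
            "component_seeds": {k: [session.master_seed, v]
                                for k, v in SEED_OFFSETS.items()},
            "n_laps": len(session.schedule),
            "trial_types": sorted({l.trial_type for l in session.schedule
                                   if l.trial_type}),
            "config": config.to_dict() if config is not None else None,
        }
        with open(tmp / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        if outdir.exists():
            shutil.rmtree(outdir)
        os.replace(tmp, outdir)
    except BaseException:
        shutil.rmtree(tmp, ignore_errors=True)
        raise
    return outdir


def tuning_ground_truth(tuning):
    return {
        "params": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(tuning.params).items()} if tuning.params else None,
        "cells": [{
            "unit_id": c.unit_id,
            "class": c.cell_class,
            "uniform_rate": c.uniform_rate,
            "demand_gain": c.demand_gain,
            "prospective_gain": c.prospective_gain,
            "fields": {"".join(j): [{"center": list(f.center), "width": f.width,
                                     "peak": f.peak} for f in fs]
                       for j, fs in c.fields.items()},
        } for c in tuning],
    }


def read_bundle(indir, fs: float = None) -> Session:
    indir = Path(indir)
    for name in ("schedule.csv", "tracking.csv", "spikes.csv", "units.csv"):
        if not (indir / name).exists():
            raise FileNotFoundError(f"bundle is missing {indir / name}")
    sched_df = pd.read_csv(indir / "schedule.csv")
    laps = [Lap(int(r.lap_index), r.subtask, r.cue_state,
                (r.origin, r.destination), bool(r.correct), bool(r.delay))
            for r in sched_df.itertuples()]
    tr_df = pd.read_csv(indir / "tracking.csv")
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(tr_df["t"].values)))
    tracking = TrackingSeries(tr_df["t"].values, tr_df["x"].values,
                              tr_df["y"].values,
                              tr_df["head_direction_deg"].values, fs=fs)
    spk = pd.read_csv(indir / "spikes.csv")
    units = pd.read_csv(indir / "units.csv")
    trains = []
    for _, r in units.iterrows():
        t = np.sort(spk.loc[spk["unit_id"] == r["unit_id"], "t"].values)
        trains.append(SpikeTrain(int(r["unit_id"]), t, float(r["spike_width_ms"]),
                                 str(r["class"])))
    seed = 0
    man = indir / "manifest.json"
    if man.exists():
        seed = json.loads(man.read_text()).get("master_seed", 0)
    return Session(MazeGeometry(), LapSchedule(laps), None, tracking, trains,
                   master_seed=seed)


def write_linearized(linearized, outdir):
    """Per-lap linearized covariates: ``linearized/<lap>.csv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for lin in linearized:
        pd.DataFrame({
            "bin_index": np.arange(lin.n_bins),
            "arclength_cm": lin.centers,
            "occupancy_s": lin.occupancy,
            "speed_cms": lin.speed,
            "hd_deg": lin.head_direction,
            "lateral_cm": lin.lateral,
            "visited": lin.visited.astype(int),
        }).to_csv(outdir / f"{lin.lap_index}.csv", index=False,
                  float_format="%.4f")
    return outdir


def write_trajectories(ts, outdir):
    """Per-lap smoothed-count matrices (bins x cells): ``trajectories/<lap>.csv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cols = [str(c) for c in ts.cell_ids]
    for li in range(ts.n_laps):
        pd.DataFrame(ts.X[li], columns=cols).to_csv(
            outdir / f"{ts.laps['lap_index'].iloc[li]}.csv", index=False,
            float_format="%.5f")
    return outdir


def write_ratemap_csv(rate_map, path):
    """Rate grid as CSV; unvisited bins carry the sentinel -1."""
    grid = np.where(rate_map.visited, rate_map.rates, -1.0)
    np.savetxt(path, grid, delimiter=",", fmt="%.4f")


def read_ratemap_csv(path):
    grid = np.loadtxt(path, delimiter=",")
    return np.where(grid < 0, np.nan, grid)
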
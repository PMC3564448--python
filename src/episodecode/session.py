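"""Session-level orchestration: simulate a full task session and run the
standard analysis cascade (segmentation, linearization, immobility
filtering, unit selection, rate maps, similarity, ANCOVA screen,
trajectories).

Every stochastic stage draws from a seed derived from the session master
seed by a fixed component offset, so a session is fully reproducible from
one integer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .taskmodel import (
    MazeGeometry, LapSchedule, TrackingParams, TrackingSeries, TuningModel,
    TuningParams, SpikeTrain, generate_schedule, simulate_tracking,
    generate_tuning, simulate_spikes, DEFAULT_BLOCKS, TRIAL_TYPES,
)
from . import behavior, placefields, ensemble
from .taskmodel.geometry import Rect

#: fixed per-component seed offsets (combined with the master seed)
SEED_OFFSETS = {"schedule": 1, "tuning": 2, "tracking": 3, "spikes": 4,
                "analysis": 5}


def component_seed(master: int, component: str):
    """Deterministic per-component seed: entropy = (master, fixed offset)."""
    return [int(master), SEED_OFFSETS[component]]


@dataclass
class Session:
    """A simulated recording session: behavior plus spike trains."""

    geometry: MazeGeometry
    schedule: LapSchedule
    tuning: TuningModel
    tracking: TrackingSeries
    spikes: list  # list[SpikeTrain]
    master_seed: int = 0

    @property
    def units(self) -> pd.DataFrame:
        dur = self.tracking.duration
        return pd.DataFrame({
            "unit_id": [s.unit_id for s in self.spikes],
            "spike_width_ms": [s.spike_width_ms for s in self.spikes],
            "mean_rate_hz": [s.mean_rate(dur) for s in self.spikes],
            "class": [s.cell_class for s in self.spikes],
        })


def simulate_session(blocks=DEFAULT_BLOCKS, error_rate: float = 0.0,
                     geometry: Optional[MazeGeometry] = None,
                     tracking_params: Optional[TrackingParams] = None,
                     tuning_params: Optional[TuningParams] = None,
                     seed: int = 0) -> Session:
    """Generate schedule, tuning, tracking and spikes for one session."""
    geometry = geometry or MazeGeometry()
    schedule = generate_schedule(blocks, error_rate,
                                 seed=component_seed(seed, "schedule"))
    tuning = generate_tuning(geometry, tuning_params,
                             seed=component_seed(seed, "tuning"))
    tracking = simulate_tracking(schedule, geometry, tracking_params,
                                 seed=component_seed(seed, "tracking"))
    spikes = simulate_spikes(tracking, schedule, tuning,
                             seed=component_seed(seed, "spikes"),
                             geometry=geometry)
    return Session(geometry, schedule, tuning, tracking, spikes, seed)


def lap_table(schedule: LapSchedule) -> pd.DataFrame:
    return pd.DataFrame({
        "lap_index": [l.lap_index for l in schedule],
        "subtask": [l.subtask for l in schedule],
        "cue_state": [l.cue_state for l in schedule],
        "origin": [l.journey[0] for l in schedule],
        "destination": [l.journey[1] for l in schedule],
        "trial_type": [l.trial_type for l in schedule],
        "correct": [l.correct for l in schedule],
        "delay": [l.delay for l in schedule],
    })


@dataclass
class PreparedSession:
    """Session after behavioral preprocessing and unit selection."""

    session: Session
    laps: pd.DataFrame
    slices: list  # behavior.LapSlice per lap
    linearized: list  # behavior.LinearizedLap per lap
    spikes: list  # immobility-filtered spike trains (all units)
    units: pd.DataFrame  # with 'call' column from classify_units
    stem_rect: Rect
    stem_interval: tuple
    si_table: pd.DataFrame = None
    place_cells: list = field(default_factory=list)

    def spike_trains_for(self, unit_ids):
        by_id = {s.unit_id: s for s in self.spikes}
        return [by_id[u] for u in unit_ids]

    def trial_type_mask(self, trial_types, lap_subset=None, moving_only=True,
                        speed_threshold: float = 5.0):
        """Tracking-sample mask for the correct laps of given trial types."""
        tr = self.session.tracking
        mask = np.zeros(len(tr), bool)
        for lap, sl in zip(self.session.schedule, self.slices):
            if not lap.correct or lap.trial_type not in trial_types:
                continue
            if lap_subset is not None and lap.lap_index not in lap_subset:
                continue
            mask[sl.i0:sl.i1] = True
        if moving_only:
            mask &= tr.speed() >= speed_threshold
        return mask


def prepare_session(session: Session, immobility_cms: float = 5.0,
                    si_threshold: float = 1.0) -> PreparedSession:
    """Run the behavioral cascade and unit/place-cell selection."""
    geom = session.geometry
    slices = behavior.segment_laps(session.tracking, session.schedule, geom)
    linearized = [
        behavior.linearize(session.tracking, sl, geom.ideal_path(*lap.journey))
        for lap, sl in zip(session.schedule, slices)]
    spikes_f = [behavior.filter_immobility(s, session.tracking, immobility_cms)
                for s in session.spikes]
    units = session.units
    units["call"] = [placefields.classify_units(w, r) for w, r in
                     zip(units["spike_width_ms"], units["mean_rate_hz"])]
    stem = geom.zones["central_stem"]
    prep = PreparedSession(session, lap_table(session.schedule), slices,
                           linearized, spikes_f, units, stem,
                           geom.stem_arc_interval())
    prep.si_table = spatial_information_table(prep)
    prep.place_cells = placefields.select_place_cells(prep.si_table, si_threshold)
    return prep


def spatial_information_table(prep: PreparedSession) -> pd.DataFrame:
    """Skaggs information per pyramidal unit per trial type."""
    pyr = prep.units.loc[prep.units["call"] == "pyramidal", "unit_id"]
    rows = []
    for tt in TRIAL_TYPES:
        mask = prep.trial_type_mask({tt})
        if not mask.any():
            continue
        mapper = placefields.RateMapper(prep.session.tracking, mask)
        for st in prep.spike_trains_for(pyr):
            m = mapper.map(st)
            try:
                si = placefields.spatial_information(m)
            except placefields.UndefinedStatisticError:
                si = 0.0
            rows.append({"unit_id": st.unit_id, "trial_type": tt,
                         "spatial_information": si})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# similarity

#: journey pairs (R-L vs L-R within subtask) and demand pairs (within journey)
CROSS_JOURNEY_PAIRS = (("VD1", "VD3"), ("SA1", "SA2"), ("DA1", "DA2"))
CROSS_DEMAND_PAIRS = (("VD1", "SA1"), ("VD1", "DA1"), ("SA1", "DA1"),
                      ("VD3", "SA2"), ("VD3", "DA2"), ("SA2", "DA2"))


def similarity_table(prep: PreparedSession, units=None,
                     method: str = "spearman") -> pd.DataFrame:
    """Spatial (r_s) and rate (r_r) similarity per cell and comparison class.

    * within: first vs second half of each trial type's correct laps
      (repeated exposures to an identical trial type);
    * cross_journey: R-L vs L-R within each subtask;
    * cross_demand: subtask pairs within a journey.

    The ROI is the central stem; undefined scores (no joint coverage or no
    rate) are skipped.
    """
    units = list(units if units is not None else prep.place_cells)
    trains = prep.spike_trains_for(units)
    tr = prep.session.tracking
    mappers = {}
    for tt in TRIAL_TYPES:
        idx = [l.lap_index for l in prep.session.schedule
               if l.correct and l.trial_type == tt]
        if len(idx) < 2:
            continue
        half = len(idx) // 2
        mappers[tt] = placefields.RateMapper(tr, prep.trial_type_mask({tt}))
        mappers[tt + "/1"] = placefields.RateMapper(
            tr, prep.trial_type_mask({tt}, lap_subset=set(idx[:half])))
        mappers[tt + "/2"] = placefields.RateMapper(
            tr, prep.trial_type_mask({tt}, lap_subset=set(idx[half:])))
    maps = {key: {st.unit_id: mp.map(st) for st in trains}
            for key, mp in mappers.items()}

    def rows_for(pair_list, klass):
        out = []
        for a, b in pair_list:
            if a not in maps or b not in maps:
                continue
            for u in units:
                ma, mb = maps[a][u], maps[b][u]
                try:
                    rs = placefields.spatial_similarity(ma, mb, prep.stem_rect,
                                                        method)
                    rr = placefields.rate_similarity(
                        ma.roi_mean_rate(prep.stem_rect),
                        mb.roi_mean_rate(prep.stem_rect))
                except placefields.UndefinedStatisticError:
                    continue
                out.append({"comparison_class": klass, "pair": f"{a}|{b}",
                            "unit_id": u, "r_s": rs, "r_r": rr})
        return out

    rows = rows_for([(t + "/1", t + "/2") for t in TRIAL_TYPES], "within")
    rows += rows_for(CROSS_JOURNEY_PAIRS, "cross_journey")
    rows += rows_for(CROSS_DEMAND_PAIRS, "cross_demand")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ANCOVA screen

#: comparisons: journeys within each subtask; demands within each journey
ANCOVA_COMPARISONS = (
    ("journeys_within_VD", ("VD1", "VD2", "VD3", "VD4")),
    ("journeys_within_SA", ("SA1", "SA2")),
    ("journeys_within_DA", ("DA1", "DA2")),
    ("demands_within_RL", ("VD1", "SA1", "DA1")),
    ("demands_within_LR", ("VD3", "SA2", "DA2")),
)


def stem_observations(prep: PreparedSession, units=None) -> pd.DataFrame:
    """Per-lap central-stem observations: firing rate per cell plus the
    behavioral covariates (mean running speed, head direction, lateral
    position over the stem traversal)."""
    units = list(units if units is not None else prep.place_cells)
    trains = prep.spike_trains_for(units)
    s0, s1 = prep.stem_interval
    rows = []
    for lap, lin in zip(prep.session.schedule, prep.linearized):
        if not lap.correct or lap.trial_type is None:
            continue
        c = lin.centers
        stem_bins = (c >= s0) & (c <= s1) & lin.visited
        occ = lin.occupancy[stem_bins]
        T = occ.sum()
        if T <= 0:
            continue
        w = occ / T
        hd = np.radians(lin.head_direction[stem_bins])
        base = {
            "lap_index": lap.lap_index, "trial_type": lap.trial_type,
            "speed": float(np.sum(w * lin.speed[stem_bins])),
            "head_direction": float(np.degrees(np.arctan2(
                np.sum(w * np.sin(hd)), np.sum(w * np.cos(hd)))) % 360.0),
            "lateral": float(np.sum(w * lin.lateral[stem_bins])),
        }
        t0, t1 = lin.sample_t[0], lin.sample_t[-1]
        for st in trains:
            ts = st.between(t0, t1 + 1e-9)
            arc = lin.arc_at(ts)
            k = np.count_nonzero((arc >= s0) & (arc <= s1))
            rows.append({**base, "unit_id": st.unit_id, "rate": k / T})
    return pd.DataFrame(rows)


def ancova_table(prep: PreparedSession, units=None, alpha: float = 0.05,
                 observations: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Differential-firing screen: one ANCOVA per cell per comparison."""
    units = list(units if units is not None else prep.place_cells)
    obs = observations if observations is not None else stem_observations(prep, units)
    rows = []
    for u in units:
        cell_obs = obs[obs["unit_id"] == u]
        for name, types in ANCOVA_COMPARISONS:
            sub = cell_obs[cell_obs["trial_type"].isin(types)].copy()
            if sub["trial_type"].nunique() < 2:
                continue
            sub["condition"] = sub["trial_type"]
            try:
                res = placefields.ancova_screen(sub, u, name, alpha)
            except ValueError:
                continue
            rows.append({"unit_id": u, "comparison": name, "p": res.p_value,
                         "significant": res.significant})
    return pd.DataFrame(rows)


def differential_cells(ancova: pd.DataFrame):
    """Cells significant in at least one journey or demand comparison."""
    if ancova.empty:
        return []
    sig = ancova.groupby("unit_id")["significant"].any()
    return sorted(sig.index[sig].tolist())


def build_trajectory_set(prep: PreparedSession, units=None,
                         sd_cm: float = 5.0) -> ensemble.TrajectorySet:
    """Ensemble trajectories for the selected units (default: place cells)."""
    units = list(units if units is not None else prep.place_cells)
    ts = ensemble.build_trajectories(
        prep.spike_trains_for(units), prep.linearized, prep.laps, sd_cm)
    ts.stem_interval = prep.stem_interval
    return ts
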
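"""Behavioral preprocessing: lap segmentation, path linearization, turn-onset
detection and immobility filtering.

Linearization projects each tracking sample onto the lap's idealized path
(nearest point on the densified polyline) and accumulates per-bin behavioral
covariates on an ~0.35 cm arc-length grid. Samples more than 5 cm from the
path are treated as off-track (unvisited).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .taskmodel.geometry import MazeGeometry, Polyline
from .taskmodel.schedule import LapSchedule
from .taskmodel.tracking import TrackingSeries
from .taskmodel.spikes import SpikeTrain

OFF_PATH_CM = 5.0  # samples farther than this from the ideal path are unvisited


class SegmentationError(RuntimeError):
    pass


@dataclass
class LapSlice:
    """One lap's contiguous sample range [i0, i1) within a tracking series."""

    lap_index: int
    i0: int
    i1: int

    def times(self, tracking):
        return tracking.t[self.i0], tracking.t[self.i1 - 1]


def segment_laps(tracking: TrackingSeries, schedule: LapSchedule,
                 geometry: MazeGeometry, speed_threshold: float = 2.0,
                 min_dwell_s: float = 0.2):
    """Split a session into one slice per lap.

    Lap boundaries are the stationary reward-zone dwells (speed below
    ``speed_threshold`` while inside a reward zone): each lap runs from the
    end of one dwell to the start of the next.
    """
    if len(tracking) == 0:
        raise SegmentationError("empty tracking")
    in_rz = (geometry.in_zone("reward_zone_L", tracking.x, tracking.y)
             | geometry.in_zone("reward_zone_R", tracking.x, tracking.y))
    dwell = in_rz & (tracking.speed() < speed_threshold)
    # contiguous dwell runs of at least min_dwell_s
    edges = np.flatnonzero(np.diff(dwell.astype(int)))
    starts = np.concatenate([[0] if dwell[0] else [], edges[~dwell[edges]] + 1]).astype(int)
    ends = np.concatenate([edges[dwell[edges]] + 1, [len(dwell)] if dwell[-1] else []]).astype(int)
    keep = (tracking.t[ends - 1] - tracking.t[starts]) >= min_dwell_s
    starts, ends = starts[keep], ends[keep]
    if len(starts) < len(schedule):
        raise SegmentationError(
            f"found {len(starts)} reward-zone dwells for {len(schedule)} laps")
    slices = [LapSlice(k, int(ends[k]), int(starts[k + 1]))
              for k in range(len(starts) - 1)]
    if len(starts) == len(schedule):  # no terminal dwell: last lap runs to the end
        slices.append(LapSlice(len(starts) - 1, int(ends[-1]), len(dwell)))
    if len(slices) != len(schedule):
        raise SegmentationError(
            f"segmented {len(slices)} laps but schedule has {len(schedule)}")
    return slices


def bin_pitch(length: float, target: float = 0.35):
    """Bin pitch dividing ``length`` into an integer number of ~target bins."""
    m = max(1, int(round(length / target)))
    return length / m, m


@dataclass
class LinearizedLap:
    """Per-bin behavioral covariates of one lap on the arc-length grid."""

    lap_index: int
    pitch: float
    bin_edges: np.ndarray  # m + 1 arc-length edges, cm
    occupancy: np.ndarray  # s per bin
    speed: np.ndarray  # mean cm/s per bin (nan when unvisited)
    head_direction: np.ndarray  # circular mean deg per bin
    lateral: np.ndarray  # mean signed offset cm per bin
    visited: np.ndarray  # bool per bin
    # per-sample projections (used downstream to place spikes on the arc)
    sample_t: np.ndarray = field(repr=False, default=None)
    sample_arc: np.ndarray = field(repr=False, default=None)
    sample_ok: np.ndarray = field(repr=False, default=None)

    @property
    def n_bins(self):
        return len(self.occupancy)

    @property
    def centers(self):
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def arc_at(self, times):
        """Arc-length position at arbitrary times within the lap."""
        return np.interp(times, self.sample_t, self.sample_arc)


def linearize(tracking: TrackingSeries, lap: LapSlice, ideal_path: Polyline,
              pitch_target: float = 0.35) -> LinearizedLap:
    """Project one lap onto its idealized path and bin the covariates."""
    if lap.i1 <= lap.i0:
        raise SegmentationError("empty lap slice")
    sl = slice(lap.i0, lap.i1)
    pts = np.stack([tracking.x[sl], tracking.y[sl]], axis=1)
    arc, lat, dist = ideal_path.project(pts)
    ok = dist <= OFF_PATH_CM
    pitch, m = bin_pitch(ideal_path.length, pitch_target)
    edges = np.arange(m + 1) * pitch
    idx = np.minimum((arc / pitch).astype(int), m - 1)
    dt = 1.0 / tracking.fs
    occ = np.bincount(idx[ok], minlength=m) * dt
    visited = occ > 0

    def binmean(values, weights=None):
        w = np.ones(ok.sum()) if weights is None else weights
        tot = np.bincount(idx[ok], weights=w * values[ok], minlength=m)
        cnt = np.bincount(idx[ok], weights=w, minlength=m)
        out = np.full(m, np.nan)
        out[visited] = tot[visited] / cnt[visited]
        return out

    sp = tracking.speed()[sl]
    hd = np.radians(tracking.head_direction[sl])
    hd_mean = np.degrees(np.arctan2(binmean(np.sin(hd)), binmean(np.cos(hd)))) % 360.0
    hd_mean[~visited] = np.nan
    return LinearizedLap(
        lap.lap_index, pitch, edges, occ, binmean(sp), hd_mean, binmean(lat),
        visited, sample_t=tracking.t[sl], sample_arc=arc, sample_ok=ok)


@dataclass
class TurnOnset:
    lap_index: int
    arclength: float
    x: float
    y: float
    found: bool


def angular_velocity(tracking: TrackingSeries, smooth_samples: int = 5):
    """|d(head direction)/dt| in revolutions/s, boxcar smoothed."""
    hd = np.unwrap(tracking.head_direction, period=360.0)
    w = np.gradient(hd, tracking.t) / 360.0
    if smooth_samples > 1:
        k = np.ones(smooth_samples) / smooth_samples
        w = np.convolve(w, k, mode="same")
    return np.abs(w)


def detect_turn_onset(tracking: TrackingSeries, lap: LapSlice,
                      geometry: MazeGeometry, ideal_path: Polyline = None,
                      threshold: float = 0.12, smooth_samples: int = 5) -> TurnOnset:
    """Last stem/junction location where angular velocity drops below threshold.

    The turn onset proxies the moment of the behavioral decision: the final
    point in the central stem or upper junction where the head is still
    steady (< 0.12 rev/s) before the turning rotation begins.
    """
    sl = slice(lap.i0, lap.i1)
    x, y = tracking.x[sl], tracking.y[sl]
    in_zone = (geometry.in_zone("central_stem", x, y)
               | geometry.in_zone("upper_junction", x, y))
    if not in_zone.any():
        raise SegmentationError("lap has no central-stem samples")
    omega = angular_velocity(tracking, smooth_samples)[sl]
    ok = in_zone & (omega < threshold)
    if not ok.any():
        return TurnOnset(lap.lap_index, np.nan, np.nan, np.nan, False)
    k = int(np.flatnonzero(ok)[-1])
    arc = np.nan
    if ideal_path is not None:
        arc = float(ideal_path.project([[x[k], y[k]]])[0][0])
    return TurnOnset(lap.lap_index, arc, float(x[k]), float(y[k]), True)


def filter_immobility(spikes: SpikeTrain, tracking: TrackingSeries,
                      speed_threshold: float = 5.0) -> SpikeTrain:
    """Drop spikes emitted while the rat moved slower than the threshold."""
    if speed_threshold <= 0:
        raise ValueError("speed threshold must be > 0")
    if spikes.n == 0:
        return spikes
    sp = np.interp(spikes.spike_times, tracking.t, tracking.speed())
    return SpikeTrain(spikes.unit_id, spikes.spike_times[sp >= speed_threshold],
                      spikes.spike_width_ms, spikes.cell_class)
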
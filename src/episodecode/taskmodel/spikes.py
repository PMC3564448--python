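"""Inhomogeneous-Poisson spike generation on the simulated session.

For each cell the firing rate is evaluated at every tracking sample from the
cell's tuning for the current lap's trial type (zero between laps), linearly
interpolated in time, and spikes are drawn by thinning: a homogeneous
Poisson stream at the session-wide peak rate is subsampled with acceptance
probability lambda(t) / lambda_max.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schedule import LapSchedule
from .tracking import TrackingSeries
from .tuning import TuningModel, CellTuning


@dataclass
class SpikeTrain:
    unit_id: int
    spike_times: np.ndarray  # s, sorted ascending
    spike_width_ms: float = 0.8
    cell_class: str = "pyramidal"

    def __post_init__(self):
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if len(self.spike_times) and np.any(np.diff(self.spike_times) < 0):
            raise ValueError("spike times must be sorted ascending")

    @property
    def n(self):
        return len(self.spike_times)

    def mean_rate(self, duration):
        return self.n / duration if duration > 0 else 0.0

    def between(self, t0, t1):
        """Spike times in the half-open window [t0, t1)."""
        i0, i1 = np.searchsorted(self.spike_times, [t0, t1])
        return self.spike_times[i0:i1]


def _sample_rates(cell: CellTuning, tracking: TrackingSeries,
                  schedule: LapSchedule, turn_entries=None):
    """Per-tracking-sample firing rate for one cell (0 outside laps)."""
    lam = np.zeros(len(tracking))
    for lap, (i0, i1) in zip(schedule, tracking.lap_slices):
        pre = None
        if cell.prospective_gain and turn_entries is not None:
            pre = np.arange(i0, i1) < turn_entries[lap.lap_index]
        lam[i0:i1] = cell.rate_at(lap.journey, lap.subtask,
                                  tracking.x[i0:i1], tracking.y[i0:i1], pre_turn=pre)
    return lam


def _turn_entries(tracking: TrackingSeries, geometry):
    """First sample index of each lap inside the upper junction (turn region)."""
    zone = geometry.zones["upper_junction"]
    entries = []
    for i0, i1 in tracking.lap_slices:
        inside = zone.contains(tracking.x[i0:i1], tracking.y[i0:i1])
        k = np.argmax(inside) if inside.any() else (i1 - i0)
        entries.append(i0 + k)
    return np.asarray(entries)


def simulate_spikes(tracking: TrackingSeries, schedule: LapSchedule,
                    tuning: TuningModel, seed=0, geometry=None):
    """Draw spike trains for every cell in the tuning model.

    ``geometry`` is only needed when prospective (pre-turn) modulation is
    active, to locate each lap's entry into the turn region.
    """
    if tracking.lap_slices is None or len(tracking.lap_slices) != len(schedule):
        raise ValueError("tracking lap slices do not match the schedule")
    rng = np.random.default_rng(seed)
    turn_entries = None
    if geometry is not None and any(c.prospective_gain for c in tuning):
        turn_entries = _turn_entries(tracking, geometry)
    T = float(tracking.t[-1])
    trains = []
    for cell in tuning:
        lam = _sample_rates(cell, tracking, schedule, turn_entries)
        lam_max = float(lam.max())
        if lam_max <= 0:
            trains.append(SpikeTrain(cell.unit_id, np.empty(0),
                                     cell.spike_width_ms, cell.cell_class))
            continue
        n_cand = rng.poisson(lam_max * T)
        cand = np.sort(rng.uniform(0.0, T, n_cand))
        accept = rng.uniform(0.0, lam_max, n_cand) < np.interp(cand, tracking.t, lam)
        trains.append(SpikeTrain(cell.unit_id, cand[accept],
                                 cell.spike_width_ms, cell.cell_class))
    return trains
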
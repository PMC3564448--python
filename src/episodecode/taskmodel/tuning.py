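"""Place-cell tuning with controlled journey (global) and task-demand (rate)
remapping.

Each simulated pyramidal cell carries one or more isotropic Gaussian place
fields per journey. Remapping is controlled along two axes:

* ``journey_mode='global'`` draws field locations independently for each
  journey, so both firing location and rate change between journeys (global
  remapping). ``journey_mode='none'`` shares one field set across journeys.
* ``demand_mode='rate'`` keeps field locations fixed within a journey but
  multiplies rates by a per-cell, per-subtask factor drawn from
  ``{s, 1/s}`` with ``s = demand_scale`` (VD is the unit-gain reference), so
  only rates change between task demands (rate remapping).
  ``demand_mode='none'`` uses unit gain everywhere.

``journey_key='origin'`` ties fields to the origin side only (both
destinations share fields), with centers restricted to the origin arm and
stem; combined with ``prospective_gain`` it injects destination-dependent
rate modulation *before* the turn while keeping the spatial code
destination-blind — the substrate for prospective-coding analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import MazeGeometry, LEFT, RIGHT
from .schedule import JOURNEYS, SUBTASKS


@dataclass
class PlaceField:
    """Isotropic Gaussian firing field: rate = peak * exp(-d^2 / (2 width^2))."""

    center: tuple  # (x, y) cm
    width: float  # cm (Gaussian SD)
    peak: float  # Hz

    def rate(self, x, y):
        d2 = (np.asarray(x) - self.center[0]) ** 2 + (np.asarray(y) - self.center[1]) ** 2
        return self.peak * np.exp(-d2 / (2.0 * self.width**2))


@dataclass
class CellTuning:
    unit_id: int
    fields: dict  # journey tuple -> list[PlaceField]
    demand_gain: dict  # subtask -> rate multiplier
    prospective_gain: dict  # destination side -> pre-turn multiplier (VD laps)
    uniform_rate: float = 0.0  # spatially untuned background (untuned cells)
    spike_width_ms: float = 0.8
    cell_class: str = "pyramidal"

    def rate_at(self, journey, subtask, x, y, pre_turn=None):
        """Firing rate (Hz) at position(s) for a lap of the given trial type.

        ``pre_turn`` is an optional boolean mask marking samples before the
        turn onset; prospective gain applies only there and only in VD.
        """
        lam = np.full(np.broadcast(np.asarray(x), np.asarray(y)).shape,
                      float(self.uniform_rate))
        for f in self.fields.get(tuple(journey), ()):
            lam = lam + f.rate(x, y)
        lam = lam * self.demand_gain.get(subtask, 1.0)
        if pre_turn is not None and subtask == "VD":
            g = self.prospective_gain.get(journey[1], 1.0)
            if g != 1.0:
                lam = np.where(pre_turn, lam * g, lam)
        return lam

    @property
    def peak_rate(self):
        peaks = [f.peak for fs in self.fields.values() for f in fs]
        return max(peaks) if peaks else self.uniform_rate


@dataclass
class TuningParams:
    n_cells: int = 50  # tuned place cells
    n_untuned: int = 0  # spatially uniform low-rate pyramidal cells
    n_interneurons: int = 0  # narrow-spike, high-rate units
    fields_per_journey: int = 1
    field_width: float = 8.0  # cm
    peak_range: tuple = (5.0, 25.0)  # Hz, uniform per field
    journey_mode: str = "global"  # 'global' | 'none'
    journey_key: str = "pair"  # 'pair' | 'origin'
    demand_mode: str = "rate"  # 'rate' | 'none'
    demand_scale: float = 0.5
    prospective_gain: float = 1.0  # >1 turns on pre-turn destination modulation
    untuned_rate: float = 4.0  # Hz (high enough that the information
    # estimator's small-sample upward bias stays well below 1 bit/spike)
    interneuron_rate: float = 15.0  # Hz


@dataclass
class TuningModel:
    cells: list = field(default_factory=list)
    params: Optional[TuningParams] = None

    def __len__(self):
        return len(self.cells)

    def __iter__(self):
        return iter(self.cells)

    def pyramidal(self):
        return [c for c in self.cells if c.cell_class == "pyramidal"]


def _draw_fields(rng, geometry: MazeGeometry, journey, params: TuningParams,
                 arc_max=None):
    path = geometry.ideal_path(*journey)
    hi = path.length if arc_max is None else min(arc_max, path.length)
    fields = []
    for _ in range(params.fields_per_journey):
        s = rng.uniform(0.0, hi)
        cx, cy = path.point_at(s)
        peak = rng.uniform(*params.peak_range)
        fields.append(PlaceField((float(cx), float(cy)), params.field_width, peak))
    return fields


def generate_tuning(geometry: MazeGeometry, params: TuningParams = None,
                    seed=0) -> TuningModel:
    """Draw a cell roster with the configured remapping structure."""
    params = params or TuningParams()
    if params.journey_mode not in ("global", "none"):
        raise ValueError("journey_mode must be 'global' or 'none'")
    if params.demand_mode not in ("rate", "none"):
        raise ValueError("demand_mode must be 'rate' or 'none'")
    rng = np.random.default_rng(seed)
    cells = []
    uid = 0
    for _ in range(params.n_cells):
        if params.journey_key == "origin":
            # destination-blind: fields on the origin arm + stem, shared by
            # both destinations from that origin
            _, stem_end = geometry.stem_arc_interval()
            per_origin = {
                o: _draw_fields(rng, geometry, (o, LEFT if o == RIGHT else RIGHT),
                                params, arc_max=stem_end)
                for o in (LEFT, RIGHT)
            }
            fields = {j: per_origin[j[0]] for j in JOURNEYS}
        elif params.journey_mode == "global":
            fields = {j: _draw_fields(rng, geometry, j, params) for j in JOURNEYS}
        else:
            shared = _draw_fields(rng, geometry, JOURNEYS[0], params)
            # shared fields must live on ground common to every journey: resample
            # centers onto the stem interval, present in all four paths
            s0, s1 = geometry.stem_arc_interval()
            path = geometry.ideal_path(*JOURNEYS[0])
            for f in shared:
                cx, cy = path.point_at(rng.uniform(s0, s1))
                f.center = (float(cx), float(cy))
            fields = {j: shared for j in JOURNEYS}
        gain = {"VD": 1.0}
        for st in ("SA", "DA"):
            if params.demand_mode == "rate":
                s = params.demand_scale
                gain[st] = s if rng.random() < 0.5 else 1.0 / s
            else:
                gain[st] = 1.0
        g = params.prospective_gain
        if g != 1.0:
            up = rng.random() < 0.5  # which destination this cell prefers
            pgain = {LEFT: g if up else 1.0 / g, RIGHT: 1.0 / g if up else g}
        else:
            pgain = {}
        cells.append(CellTuning(uid, fields, gain, pgain,
                                spike_width_ms=float(rng.uniform(0.5, 1.1))))
        uid += 1
    for _ in range(params.n_untuned):
        cells.append(CellTuning(uid, {}, {}, {}, uniform_rate=params.untuned_rate,
                                spike_width_ms=float(rng.uniform(0.5, 1.1))))
        uid += 1
    for _ in range(params.n_interneurons):
        cells.append(CellTuning(uid, {}, {}, {}, uniform_rate=params.interneuron_rate,
                                spike_width_ms=float(rng.uniform(0.15, 0.3)),
                                cell_class="interneuron"))
        uid += 1
    return TuningModel(cells, params)
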
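"""Figure-8 maze geometry and idealized journey paths.

The maze is a figure-8 track: a central stem running bottom-to-top flanked by
left and right return rails. A lap starts at a reward zone at the bottom
corner of one rail (the *origin* side), runs along the bottom arm onto the
central stem, climbs the stem to the decision point at the top, turns onto
the left or right rail (the *destination* side), and descends back to that
rail's reward zone. Coordinates: origin at the lower-left outer corner,
x rightward, y upward, units cm.

Idealized paths are piecewise linear polylines densified to ~1 cm vertex
spacing. Corners are quarter-circle arcs (radius = half the path width) so
that heading changes smoothly at realistic angular velocities. The central
stem segment array is shared (byte-identical) across all journeys, which
makes central-stem region-of-interest comparisons exact across journeys.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

LEFT = "L"
RIGHT = "R"


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle (xmin, ymin, xmax, ymax) in maze coordinates."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def contains(self, x, y):
        """Vectorized point-in-rectangle test (edges inclusive)."""
        x = np.asarray(x)
        y = np.asarray(y)
        return (x >= self.xmin) & (x <= self.xmax) & (y >= self.ymin) & (y <= self.ymax)


class Polyline:
    """A densified polyline with cached cumulative arc length."""

    def __init__(self, vertices: np.ndarray):
        vertices = np.asarray(vertices, dtype=float)
        if vertices.ndim != 2 or vertices.shape[1] != 2 or len(vertices) < 2:
            raise ValueError("polyline needs >= 2 (x, y) vertices")
        self.vertices = vertices
        seg = np.diff(vertices, axis=0)
        seglen = np.hypot(seg[:, 0], seg[:, 1])
        if np.any(seglen <= 0):
            raise ValueError("polyline has zero-length segments")
        self.seg_lengths = seglen
        self.arc = np.concatenate([[0.0], np.cumsum(seglen)])
        self.length = float(self.arc[-1])
        # unit tangents per segment
        self.tangents = seg / seglen[:, None]

    def point_at(self, s):
        """Interpolate (x, y) at arc length(s) ``s`` (clipped to [0, length])."""
        s = np.clip(np.asarray(s, dtype=float), 0.0, self.length)
        x = np.interp(s, self.arc, self.vertices[:, 0])
        y = np.interp(s, self.arc, self.vertices[:, 1])
        return np.stack([x, y], axis=-1)

    def tangent_at(self, s):
        """Unit tangent of the segment containing each arc length."""
        s = np.clip(np.asarray(s, dtype=float), 0.0, self.length)
        idx = np.clip(np.searchsorted(self.arc, s, side="right") - 1, 0, len(self.tangents) - 1)
        return self.tangents[idx]

    def project(self, points):
        """Project points onto the polyline.

        Returns ``(arc, lateral, dist)`` where ``arc`` is the arc length of the
        nearest point on the line, ``lateral`` the signed offset (positive to
        the right of the direction of travel) and ``dist = |lateral|``.
        Nearest candidate vertices come from a KD-tree; the exact foot is then
        found on the segments adjacent to the nearest vertex.
        """
        from scipy.spatial import cKDTree

        points = np.atleast_2d(np.asarray(points, dtype=float))
        tree = self._tree()
        _, k = tree.query(points)
        best_d2 = np.full(len(points), np.inf)
        best_arc = np.zeros(len(points))
        best_lat = np.zeros(len(points))
        for off in (-1, 0):
            i = k + off
            ok = (i >= 0) & (i < len(self.seg_lengths))
            if not np.any(ok):
                continue
            i = np.clip(i, 0, len(self.seg_lengths) - 1)
            a = self.vertices[i]
            t = self.tangents[i]
            rel = points - a
            proj = np.clip(np.einsum("ij,ij->i", rel, t), 0.0, self.seg_lengths[i])
            foot = a + proj[:, None] * t
            dvec = points - foot
            d2 = np.einsum("ij,ij->i", dvec, dvec)
            upd = ok & (d2 < best_d2)
            best_d2[upd] = d2[upd]
            best_arc[upd] = self.arc[i[upd]] + proj[upd]
            # right-hand normal of travel direction: (ty, -tx)
            best_lat[upd] = dvec[upd, 0] * t[upd, 1] - dvec[upd, 1] * t[upd, 0]
        return best_arc, best_lat, np.sqrt(best_d2)

    def _tree(self):
        if not hasattr(self, "_ckdtree"):
            from scipy.spatial import cKDTree

            self._ckdtree = cKDTree(self.vertices)
        return self._ckdtree


def _densify_straight(p0, p1, spacing=1.0):
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    n = max(1, int(round(np.hypot(*(p1 - p0)) / spacing)))
    t = np.linspace(0.0, 1.0, n + 1)[:, None]
    return p0 + t * (p1 - p0)


def _densify_arc(center, radius, a0_deg, a1_deg, spacing=1.0):
    center = np.asarray(center, float)
    sweep = math.radians(abs(a1_deg - a0_deg)) * radius
    n = max(2, int(round(sweep / spacing)))
    ang = np.radians(np.linspace(a0_deg, a1_deg, n + 1))
    return center + radius * np.stack([np.cos(ang), np.sin(ang)], axis=1)


@dataclass(eq=False)
class MazeGeometry:
    """Figure-8 maze: outer 100 cm x 140 cm box, 20 cm wide path."""

    outer_width: float = 100.0
    outer_height: float = 140.0
    path_width: float = 20.0
    corner_radius: float = 10.0
    zones: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.path_width <= 0:
            raise ValueError("path width must be > 0")
        w, h = self.outer_width, self.outer_height
        hp = self.path_width / 2.0  # centerline inset from the outer walls
        if not self.zones:
            self.zones = {
                "reward_zone_L": Rect(0, 0, 25, 2 * hp),
                "reward_zone_R": Rect(w - 25, 0, w, 2 * hp),
                "delay_zone": Rect(25, 0, w - 25, 2 * hp),
                "central_stem": Rect(w / 2 - hp, 2 * hp, w / 2 + hp, h - 2 * hp),
                "upper_junction": Rect(w / 2 - hp, h - 2 * hp, w / 2 + hp, h),
                "decision_point": Rect(w / 2 - hp / 2, h - 1.5 * hp - 2.5, w / 2 + hp / 2, h - 2.5),
            }
        outer = Rect(0, 0, w, h)
        for name, z in self.zones.items():
            if not (z.xmin >= outer.xmin and z.ymin >= outer.ymin
                    and z.xmax <= outer.xmax and z.ymax <= outer.ymax):
                raise ValueError(f"zone {name} outside the outer rectangle")

    # --- centerline landmarks -------------------------------------------------
    @property
    def _cx(self):
        return self.outer_width / 2.0

    @property
    def _inset(self):
        return self.path_width / 2.0

    def _stem_vertices(self):
        """Shared central-stem segment: one array instance reused by every path."""
        if not hasattr(self, "_stem_cache"):
            lo = 2 * self._inset  # stem begins after the bottom corner arc
            hi = self.outer_height - 2 * self._inset
            self._stem_cache = _densify_straight((self._cx, lo), (self._cx, hi))
        return self._stem_cache

    @lru_cache(maxsize=None)
    def ideal_path(self, origin: str, destination: str) -> Polyline:
        """Idealized centerline polyline for one journey, ~1 cm vertex spacing."""
        w, h, r, cx = self.outer_width, self.outer_height, self.corner_radius, self._cx
        ins = self._inset
        # laps start/end exactly at the bottom corner-arc junctions, so the
        # outbound and return legs never overlap (the path is a closed loop
        # for same-side journeys)
        rz_L = np.array([ins + r, ins])
        rz_R = np.array([w - ins - r, ins])
        parts = []
        # bottom arm: reward zone -> corner arc onto the stem
        if origin == LEFT:
            parts.append(_densify_straight(rz_L, (cx - r, ins)))
            parts.append(_densify_arc((cx - r, ins + r), r, -90, 0))
        else:
            parts.append(_densify_straight(rz_R, (cx + r, ins)))
            parts.append(_densify_arc((cx + r, ins + r), r, 270, 180))
        # shared central stem
        parts.append(self._stem_vertices())
        top = h - 2 * ins
        if destination == LEFT:
            parts.append(_densify_arc((cx - r, top), r, 0, 90))
            parts.append(_densify_straight((cx - r, top + r), (ins + r, top + r)))
            parts.append(_densify_arc((ins + r, top), r, 90, 180))
            parts.append(_densify_straight((ins, top), (ins, ins + r)))
            parts.append(_densify_arc((ins + r, ins + r), r, 180, 270))
        else:
            parts.append(_densify_arc((cx + r, top), r, 180, 90))
            parts.append(_densify_straight((cx + r, top + r), (w - ins - r, top + r)))
            parts.append(_densify_arc((w - ins - r, top), r, 90, 0))
            parts.append(_densify_straight((w - ins, top), (w - ins, ins + r)))
            parts.append(_densify_arc((w - ins - r, ins + r), r, 0, -90))
        verts = [parts[0]]
        for p in parts[1:]:
            verts.append(p[1:] if np.allclose(p[0], verts[-1][-1]) else p)
        return Polyline(np.concatenate(verts))

    def stem_arc_interval(self, origin: str = LEFT, destination: str = RIGHT):
        """(start, end) arc length of the central stem; identical across journeys."""
        path = self.ideal_path(origin, destination)
        stem = self._stem_vertices()
        # stem starts after bottom arm + entry arc; locate by matching vertices
        s0, _, _ = path.project(stem[0])
        return float(s0[0]), float(s0[0]) + float(
            np.sum(np.hypot(*np.diff(stem, axis=0).T))
        )

    def delay_arc(self, origin: str):
        """Arc length of the DA waiting point: 20 cm before the stem entrance."""
        s0, _ = self.stem_arc_interval(origin, LEFT if origin == RIGHT else RIGHT)
        return s0 - 20.0

    def in_zone(self, name, x, y):
        return self.zones[name].contains(x, y)
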
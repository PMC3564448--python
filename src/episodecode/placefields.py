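"""Place-field analysis: occupancy-normalized kernel rate maps, spatial
information, unit classification, spatial/rate similarity and the ANCOVA
differential-firing screen.

The rate at a point x is the kernel ratio

    f(x) = sum_i w((s_i - x) / h) / integral_0^T w((y(t) - x) / h) dt

with s_i the position of the i-th spike, y(t) the tracked position, and w a
Gaussian kernel of width h = 5 cm; f is evaluated at the centers of
5 cm x 5 cm bins. Bins farther than 5 cm from the tracked path are
unvisited. Spatial information is the Skaggs bits-per-spike measure
sum_i P_i (R_i / R) log2(R_i / R).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial import cKDTree

from .taskmodel.geometry import MazeGeometry, Rect
from .taskmodel.spikes import SpikeTrain
from .taskmodel.tracking import TrackingSeries

UNVISITED_CM = 5.0


class UndefinedStatisticError(ValueError):
    """A similarity or information score has no defined value for this input."""


@dataclass
class RateMap:
    """Occupancy-normalized, kernel-smoothed firing-rate grid."""

    rates: np.ndarray  # (ny, nx) Hz; nan where unvisited
    occupancy: np.ndarray  # (ny, nx) s
    visited: np.ndarray  # (ny, nx) bool
    bin_size: float = 5.0
    h: float = 5.0
    extent: tuple = (0.0, 100.0, 0.0, 140.0)  # xmin, xmax, ymin, ymax

    @property
    def occupancy_prob(self):
        """P_i: occupancy probability over visited bins (sums to 1)."""
        p = np.zeros_like(self.occupancy)
        tot = self.occupancy[self.visited].sum()
        if tot > 0:
            p[self.visited] = self.occupancy[self.visited] / tot
        return p

    @property
    def mean_rate(self):
        """R = sum_i P_i R_i over visited bins."""
        p = self.occupancy_prob[self.visited]
        return float(np.nansum(p * self.rates[self.visited]))

    @property
    def peak_rate(self):
        return float(np.nanmax(self.rates[self.visited])) if self.visited.any() else 0.0

    def bin_centers(self):
        xmin, xmax, ymin, ymax = self.extent
        cx = xmin + (np.arange(self.rates.shape[1]) + 0.5) * self.bin_size
        cy = ymin + (np.arange(self.rates.shape[0]) + 0.5) * self.bin_size
        return cx, cy

    def roi_mask(self, roi: Optional[Rect]):
        if roi is None:
            return np.ones_like(self.visited, dtype=bool)
        cx, cy = self.bin_centers()
        gx, gy = np.meshgrid(cx, cy)
        return np.asarray(roi.contains(gx, gy))

    def roi_mean_rate(self, roi: Optional[Rect] = None):
        """Occupancy-weighted mean rate over visited bins of a region."""
        m = self.roi_mask(roi) & self.visited
        occ = self.occupancy[m]
        if occ.sum() <= 0:
            return 0.0
        return float(np.sum(self.rates[m] * occ) / occ.sum())


class RateMapper:
    """Precomputes the occupancy kernel of a tracking segment so that many
    cells' maps over the same behavior are cheap to evaluate."""

    def __init__(self, tracking: TrackingSeries, sample_mask=None,
                 bin_size: float = 5.0, h: float = 5.0,
                 extent=(0.0, 100.0, 0.0, 140.0)):
        self.bin_size = float(bin_size)
        self.h = float(h)
        self.extent = extent
        mask = np.ones(len(tracking), bool) if sample_mask is None else sample_mask
        if not mask.any():
            raise ValueError("no tracking samples selected")
        self.tracking = tracking
        self._mask = mask
        self._t = tracking.t[mask]
        px, py = tracking.x[mask], tracking.y[mask]
        xmin, xmax, ymin, ymax = extent
        nx = int(np.ceil((xmax - xmin) / bin_size))
        ny = int(np.ceil((ymax - ymin) / bin_size))
        cx = xmin + (np.arange(nx) + 0.5) * bin_size
        cy = ymin + (np.arange(ny) + 0.5) * bin_size
        self._cx, self._cy = cx, cy
        dt = 1.0 / tracking.fs
        # denominator: integral of the kernel along the trajectory
        kx = np.exp(-0.5 * ((px[:, None] - cx[None, :]) / h) ** 2)
        ky = np.exp(-0.5 * ((py[:, None] - cy[None, :]) / h) ** 2)
        self._denom = np.einsum("ti,tj->ji", kx, ky) * dt  # (ny, nx)
        gx, gy = np.meshgrid(cx, cy)
        d, _ = cKDTree(np.stack([px, py], axis=1)).query(
            np.stack([gx.ravel(), gy.ravel()], axis=1))
        self.visited = (d.reshape(ny, nx) <= UNVISITED_CM)
        self.occupancy = np.histogram2d(
            py, px, bins=[ny, nx], range=[[ymin, ymax], [xmin, xmax]])[0] * dt

    def spike_positions(self, spikes: SpikeTrain):
        """Positions of this segment's spikes, interpolated from tracking."""
        t = spikes.spike_times
        # keep spikes whose nearest selected sample is within one frame
        idx = np.searchsorted(self._t, t)
        idx = np.clip(idx, 0, len(self._t) - 1)
        near = np.minimum(np.abs(self._t[idx] - t),
                          np.abs(self._t[np.maximum(idx - 1, 0)] - t))
        t = t[near <= 1.0 / self.tracking.fs]
        return self.tracking.position_at(t)

    def map(self, spikes: SpikeTrain) -> RateMap:
        sx, sy = self.spike_positions(spikes)
        if len(sx):
            kx = np.exp(-0.5 * ((np.asarray(sx)[:, None] - self._cx[None, :]) / self.h) ** 2)
            ky = np.exp(-0.5 * ((np.asarray(sy)[:, None] - self._cy[None, :]) / self.h) ** 2)
            num = np.einsum("ti,tj->ji", kx, ky)
        else:
            num = np.zeros_like(self._denom)
        rates = np.full_like(self._denom, np.nan)
        ok = self.visited & (self._denom > 0)
        rates[ok] = num[ok] / self._denom[ok]
        return RateMap(rates, self.occupancy, ok, self.bin_size, self.h, self.extent)


def compute_rate_map(spikes: SpikeTrain, tracking: TrackingSeries,
                     bin_size: float = 5.0, h: float = 5.0,
                     extent=(0.0, 100.0, 0.0, 140.0),
                     sample_mask=None) -> RateMap:
    """One-shot kernel rate map (see :class:`RateMapper` for batch use)."""
    if len(tracking) == 0:
        raise ValueError("empty tracking")
    return RateMapper(tracking, sample_mask, bin_size, h, extent).map(spikes)


def spatial_information(rate_map: RateMap) -> float:
    """Skaggs spatial information in bits/spike; requires mean rate > 0."""
    R = rate_map.mean_rate
    if not R > 0:
        raise UndefinedStatisticError("mean rate is zero; information undefined")
    p = rate_map.occupancy_prob[rate_map.visited]
    r = rate_map.rates[rate_map.visited]
    pos = (r > 0) & (p > 0)
    ratio = r[pos] / R
    return float(np.sum(p[pos] * ratio * np.log2(ratio)))


def classify_units(spike_width_ms: float, mean_rate_hz: float,
                   width_threshold: float = 0.4, rate_threshold: float = 5.0,
                   min_rate: float = 0.1) -> str:
    """Pyramidal / interneuron / excluded call from spike width and rate."""
    if spike_width_ms is None or mean_rate_hz is None:
        raise ValueError("spike width and mean rate are required")
    if mean_rate_hz < min_rate:
        return "excluded"
    if spike_width_ms >= width_threshold and mean_rate_hz <= rate_threshold:
        return "pyramidal"
    return "interneuron"


def spatial_similarity(map_a: RateMap, map_b: RateMap, roi: Optional[Rect] = None,
                       method: str = "spearman") -> float:
    """Spatial correlation r_s between two maps over jointly visited ROI bins.

    Rank (Spearman) correlation by default, so the score is independent of
    any rank-preserving rescaling of the rates (and hence of rate
    similarity); Pearson is available via ``method``.
    """
    m = map_a.roi_mask(roi) & map_a.visited & map_b.visited
    if m.sum() < 3:
        raise UndefinedStatisticError("fewer than 3 jointly visited ROI bins")
    a, b = map_a.rates[m], map_b.rates[m]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedStatisticError("zero variance in an ROI map")
    if method == "spearman":
        r = sps.spearmanr(a, b).statistic
    elif method == "pearson":
        r = sps.pearsonr(a, b).statistic
    else:
        raise ValueError(f"unknown method {method!r}")
    if np.isnan(r):
        raise UndefinedStatisticError("correlation undefined (constant ranks)")
    return float(r)


def rate_similarity(rate_a: float, rate_b: float) -> float:
    """r_r = 1 - |a - b| / (a + b); in [0, 1], symmetric, scale-invariant."""
    if rate_a < 0 or rate_b < 0:
        raise ValueError("rates must be non-negative")
    s = rate_a + rate_b
    if s <= 0:
        raise UndefinedStatisticError("both rates are zero")
    return 1.0 - abs(rate_a - rate_b) / s


def select_place_cells(si_table: pd.DataFrame, threshold: float = 1.0):
    """Cells whose spatial information exceeds threshold in >= 1 trial type.

    ``si_table`` has columns unit_id, trial_type, spatial_information.
    """
    best = si_table.groupby("unit_id")["spatial_information"].max()
    return sorted(best.index[best > threshold].tolist())


@dataclass
class AncovaResult:
    unit_id: int
    comparison: str
    p_value: float
    covariates: tuple = ("speed", "head_direction", "lateral")
    alpha: float = 0.05

    @property
    def significant(self):
        return bool(self.p_value < self.alpha)


def ancova_screen(observations: pd.DataFrame, unit_id: int = -1,
                  comparison: str = "", alpha: float = 0.05) -> AncovaResult:
    """One-way ANCOVA of firing rate on condition with behavioral covariates.

    ``observations`` columns: rate, condition, speed, head_direction,
    lateral. The model is rate ~ condition (factor) + speed +
    head_direction + lateral; the returned p-value is the type-II F test of
    the condition factor after covariate adjustment.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = observations.dropna(subset=["rate", "speed", "head_direction", "lateral"])
    levels = df["condition"].unique()
    if len(levels) < 2:
        raise ValueError("need >= 2 conditions")
    if (df.groupby("condition").size() < 2).any():
        raise ValueError("need >= 2 observations per condition")
    model = smf.ols(
        "rate ~ C(condition) + speed + head_direction + lateral", data=df).fit()
    if np.isnan(model.params).any() or model.df_resid <= 0:
        raise ValueError("rank-deficient ANCOVA design")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = sm.stats.anova_lm(model, typ=2)
    p = float(table.loc["C(condition)", "PR(>F)"])
    return AncovaResult(unit_id, comparison, p, alpha=alpha)
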
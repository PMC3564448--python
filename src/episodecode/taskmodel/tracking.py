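"""Virtual-rat tracking: 60 Hz head position/direction along idealized paths.

Each lap is a constant-nominal-speed traversal of its journey's idealized
polyline with Ornstein-Uhlenbeck speed and lateral-offset noise and smooth
head-direction noise. DA laps pause for the delay period at the waiting
point 20 cm before the stem entrance. A short stationary dwell at the reward
zone precedes every lap (and ends the session), which is what downstream lap
segmentation keys on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import lfilter

from .geometry import MazeGeometry
from .schedule import LapSchedule


@dataclass
class TrackingParams:
    fs: float = 60.0  # Hz
    mean_speed: float = 30.0  # cm/s along the path
    speed_sd: float = 4.0  # OU sd of speed fluctuations, cm/s
    speed_tau: float = 1.0  # OU time constant, s
    lateral_sd: float = 1.5  # OU sd of lateral offset, cm
    lateral_tau: float = 0.5  # s
    lateral_smooth_s: float = 0.4  # extra smoothing of the sway, s
    hd_noise_sd: float = 3.0  # deg, smoothed white noise added to heading
    hd_noise_tau: float = 0.25  # s, Gaussian smoothing scale of hd noise
    delay_s: float = 5.0  # DA waiting period
    inter_lap_s: float = 0.5  # stationary reward-zone dwell before each lap


@dataclass
class TrackingSeries:
    """Head tracking samples: t (s), x/y (cm), head_direction (deg, [0, 360))."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    head_direction: np.ndarray
    fs: float = 60.0
    # generator ground truth (absent for externally loaded data)
    lap_slices: Optional[list] = None  # [(i0, i1)] sample index ranges per lap
    delay_epochs: Optional[list] = None  # [(i0, i1)] per DA lap

    def __post_init__(self):
        if len(self.t) and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self):
        return len(self.t)

    @property
    def duration(self):
        return float(self.t[-1] - self.t[0] + 1.0 / self.fs) if len(self.t) else 0.0

    def speed(self, smooth_samples: int = 5):
        """Ground speed (cm/s) by central differences, boxcar smoothed."""
        if len(self.t) < 2:
            return np.zeros(len(self.t))
        vx = np.gradient(self.x, self.t)
        vy = np.gradient(self.y, self.t)
        sp = np.hypot(vx, vy)
        if smooth_samples > 1:
            k = np.ones(smooth_samples) / smooth_samples
            sp = np.convolve(sp, k, mode="same")
        return sp

    def position_at(self, times):
        """Linear interpolation of (x, y) at arbitrary times."""
        return (np.interp(times, self.t, self.x), np.interp(times, self.t, self.y))


def _ou_series(rng, n, sd, tau, dt):
    """Discrete Ornstein-Uhlenbeck path with stationary sd and time constant."""
    if sd <= 0 or n == 0:
        return np.zeros(n)
    a = np.exp(-dt / tau)
    eps = rng.standard_normal(n) * sd * np.sqrt(1.0 - a * a)
    eps[0] = rng.standard_normal() * sd
    return lfilter([1.0], [1.0, -a], eps)


def _smooth_noise(rng, n, sd, tau, dt):
    """Gaussian-smoothed white noise rescaled to the target sd (deg)."""
    if sd <= 0 or n == 0:
        return np.zeros(n)
    from scipy.ndimage import gaussian_filter1d

    w = rng.standard_normal(n + 1)
    sm = gaussian_filter1d(w, sigma=max(tau / dt, 1e-9), mode="nearest")[:n]
    s = sm.std()
    return sm * (sd / s) if s > 0 else np.zeros(n)


def simulate_tracking(schedule: LapSchedule, geometry: MazeGeometry,
                      params: TrackingParams = None, seed=0) -> TrackingSeries:
    """Simulate the full-session 60 Hz tracking for a lap schedule."""
    params = params or TrackingParams()
    if params.mean_speed <= 0:
        raise ValueError("mean speed must be > 0")
    rng = np.random.default_rng(seed)
    dt = 1.0 / params.fs
    n_dwell = max(1, int(round(params.inter_lap_s * params.fs)))
    n_delay = int(np.ceil(params.delay_s * params.fs))

    xs, ys, hds = [], [], []
    lap_slices, delay_epochs = [], []
    i = 0
    for lap in schedule:
        path = geometry.ideal_path(*lap.journey)
        # pre-lap stationary dwell at the origin reward zone
        start = path.point_at(0.0)
        xs.append(np.full(n_dwell, start[0]))
        ys.append(np.full(n_dwell, start[1]))
        hds.append(np.full(n_dwell, np.degrees(np.arctan2(*path.tangent_at(0.0)[::-1]))))
        i += n_dwell
        # traverse: arc positions from an OU-perturbed speed
        n_max = int(np.ceil(path.length / params.mean_speed * params.fs * 3)) + 60
        sp = params.mean_speed + _ou_series(rng, n_max, params.speed_sd,
                                            params.speed_tau, dt)
        sp = np.clip(sp, 0.1 * params.mean_speed, None)
        arc = np.cumsum(sp * dt)
        n = int(np.searchsorted(arc, path.length)) + 1
        arc = arc[:n]
        arc[-1] = min(arc[-1], path.length)
        if lap.delay:
            d_arc = geometry.delay_arc(lap.journey[0])
            k = int(np.searchsorted(arc, d_arc))
            arc = np.concatenate([arc[:k], np.full(n_delay, d_arc), arc[k:]])
            delay_epochs.append((i + k, i + k + n_delay))
            n += n_delay
        base = path.point_at(arc)
        tang = path.tangent_at(arc)
        # OU sway, low-passed so the implied lateral velocity stays small
        # compared to running speed (keeps measured ground speed unbiased)
        lat = _ou_series(rng, n, params.lateral_sd, params.lateral_tau, dt)
        if params.lateral_sd > 0 and params.lateral_smooth_s > 0 and n > 1:
            from scipy.ndimage import gaussian_filter1d

            lat = gaussian_filter1d(lat, params.lateral_smooth_s / dt,
                                    mode="nearest")
            s = lat.std()
            if s > 0:
                lat *= params.lateral_sd / s
        if lap.delay:
            k0, k1 = delay_epochs[-1][0] - i, delay_epochs[-1][1] - i
            lat[k0:k1] = lat[k0] if k0 < n else 0.0  # hold still behind the barrier
        normal = np.stack([tang[:, 1], -tang[:, 0]], axis=1)  # rat's right
        pos = base + lat[:, None] * normal
        hd = np.degrees(np.arctan2(tang[:, 1], tang[:, 0]))
        hd = np.unwrap(hd, period=360.0) + _smooth_noise(
            rng, n, params.hd_noise_sd, params.hd_noise_tau, dt)
        xs.append(pos[:, 0])
        ys.append(pos[:, 1])
        hds.append(hd)
        lap_slices.append((i, i + n))
        i += n
    # closing dwell at the final reward zone so the last lap has a terminator
    end = geometry.ideal_path(*schedule[-1].journey).point_at(
        geometry.ideal_path(*schedule[-1].journey).length)
    xs.append(np.full(n_dwell, end[0]))
    ys.append(np.full(n_dwell, end[1]))
    hds.append(np.full(n_dwell, hds[-1][-1]))
    i += n_dwell

    x = np.concatenate(xs)
    y = np.concatenate(ys)
    hd = np.mod(np.concatenate(hds), 360.0)
    t = np.arange(len(x)) * dt
    return TrackingSeries(t, x, y, hd, fs=params.fs,
                          lap_slices=lap_slices, delay_epochs=delay_epochs)
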
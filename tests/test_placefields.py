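"""Rate maps, spatial information, similarity scores, unit selection, ANCOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from episodecode.placefields import (RateMap, UndefinedStatisticError,
                                     ancova_screen, classify_units,
                                     compute_rate_map, rate_similarity,
                                     select_place_cells, spatial_information,
                                     spatial_similarity)
from episodecode.taskmodel import SpikeTrain, TrackingSeries


def _tracking_on_line(xs, y=70.0, fs=60.0):
    t = np.arange(len(xs)) / fs
    return TrackingSeries(t, np.asarray(xs, float), np.full(len(xs), y),
                          np.zeros(len(xs)), fs=fs)


# ---------------------------------------------------------------------------
# kernel rate maps


def test_stationary_rat_rate_is_n_over_T():
    """With the rat parked at one point, numerator and denominator kernels
    cancel and the rate equals spikes / time at every visited bin."""
    n, T = 30, 10.0
    tr = _tracking_on_line(np.full(int(T * 60), 52.5), y=72.5)
    spikes = SpikeTrain(0, np.linspace(0.2, T - 0.2, n))
    m = compute_rate_map(spikes, tr)
    assert m.visited.sum() >= 1
    assert np.allclose(m.rates[m.visited], n / T, rtol=1e-3)


def test_zero_spikes_zero_rates():
    tr = _tracking_on_line(np.linspace(20, 80, 600))
    m = compute_rate_map(SpikeTrain(0, np.empty(0)), tr)
    assert np.allclose(m.rates[m.visited], 0.0)
    assert m.occupancy_prob[m.visited].sum() == pytest.approx(1.0)


def test_rate_map_matches_direct_quadrature():
    """Oracle equivalence: the binned kernel-ratio map agrees with direct
    numerical quadrature of the formula on a dense time grid."""
    rng = np.random.default_rng(0)
    xs = np.linspace(15.0, 85.0, 900) + rng.normal(0, 0.05, 900)
    tr = _tracking_on_line(xs)
    spike_t = np.sort(rng.uniform(2.0, 13.0, 25))
    spikes = SpikeTrain(0, spike_t)
    m = compute_rate_map(spikes, tr, h=5.0)
    # --- independent quadrature at each visited bin center -----------------
    tt = np.linspace(tr.t[0], tr.t[-1], 200001)
    yx = np.interp(tt, tr.t, tr.x)
    yy = np.interp(tt, tr.t, tr.y)
    sx = np.interp(spike_t, tr.t, tr.x)
    sy = np.interp(spike_t, tr.t, tr.y)
    cx, cy = m.bin_centers()
    h = 5.0
    for iy, ix in zip(*np.nonzero(m.visited)):
        bx, by = cx[ix], cy[iy]
        num = np.exp(-((sx - bx) ** 2 + (sy - by) ** 2) / (2 * h * h)).sum()
        ker = np.exp(-((yx - bx) ** 2 + (yy - by) ** 2) / (2 * h * h))
        den = np.trapezoid(ker, tt)
        if den > 1e-3:
            assert m.rates[iy, ix] == pytest.approx(num / den, rel=0.01)


def test_kernel_conservation_of_spike_count(small_session, small_prep):
    """Sum over visited bins of rate x occupancy recovers the spike count
    within ~5% on smooth trajectories."""
    tr = small_session.tracking
    mask = small_prep.trial_type_mask({"SA1"})
    from episodecode.placefields import RateMapper

    mapper = RateMapper(tr, mask)
    checked = 0
    for st in small_prep.spike_trains_for(small_prep.place_cells[:5]):
        m = mapper.map(st)
        sx, _ = mapper.spike_positions(st)
        n_spk = len(sx)
        if n_spk < 50:
            continue
        est = np.nansum(m.rates[m.visited] * m.occupancy[m.visited])
        assert est == pytest.approx(n_spk, rel=0.05)
        checked += 1
    assert checked >= 1


def test_empty_tracking_rejected():
    tr = _tracking_on_line(np.empty(0))
    with pytest.raises(ValueError):
        compute_rate_map(SpikeTrain(0, np.empty(0)), tr)


# ---------------------------------------------------------------------------
# spatial information


def _map_from(rates, occupancy):
    rates = np.asarray(rates, float)[None, :]
    occ = np.asarray(occupancy, float)[None, :]
    return RateMap(rates, occ, np.ones_like(rates, bool),
                   extent=(0, rates.size * 5.0, 0, 5.0))


def test_spatial_information_analytic_cases():
    assert spatial_information(_map_from([3, 3, 3, 3], [1, 1, 1, 1])) == \
        pytest.approx(0.0)
    # half the time in a bin firing at twice the mean, half silent: 1 bit
    assert spatial_information(_map_from([2.0, 0.0], [5.0, 5.0])) == \
        pytest.approx(1.0)
    with pytest.raises(UndefinedStatisticError):
        spatial_information(_map_from([0.0, 0.0], [1.0, 1.0]))


def test_spatial_information_scale_invariant():
    base = _map_from([0.5, 4.0, 1.0, 0.0], [2, 1, 3, 2])
    scaled = _map_from([5.0, 40.0, 10.0, 0.0], [2, 1, 3, 2])
    assert spatial_information(base) == pytest.approx(spatial_information(scaled))


def test_place_cell_selection():
    si = pd.DataFrame({
        "unit_id": [1, 1, 2, 2, 3, 3],
        "trial_type": ["VD1", "SA1"] * 3,
        "spatial_information": [0.2, 1.3, 0.4, 0.9, 1.2, 0.1],
    })
    assert select_place_cells(si) == [1, 3]
    si["spatial_information"] = 0.5
    assert select_place_cells(si) == []


def test_generator_ground_truth_place_cells(small_session, small_prep):
    """Tuned cells pass the 1 bit/spike screen; untuned uniform cells fail;
    interneurons never enter."""
    tuned = {c.unit_id for c in small_session.tuning
             if c.fields and c.cell_class == "pyramidal"}
    untuned = {c.unit_id for c in small_session.tuning
               if not c.fields and c.cell_class == "pyramidal"}
    inter = {c.unit_id for c in small_session.tuning
             if c.cell_class == "interneuron"}
    selected = set(small_prep.place_cells)
    assert tuned <= selected
    assert not (selected & inter)
    # at most one untuned cell slips past the screen at this session length
    # (the information estimator is upward-biased at small spike counts)
    assert len(selected & untuned) <= 1


# ---------------------------------------------------------------------------
# unit classification


@pytest.mark.parametrize("width,rate,expected", [
    (0.6, 1.5, "pyramidal"),
    (0.5, 0.05, "excluded"),
    (0.2, 12.0, "interneuron"),
    (0.6, 12.0, "interneuron"),
    (0.4, 5.0, "pyramidal"),
])
def test_classify_units(width, rate, expected):
    assert classify_units(width, rate) == expected


def test_classify_units_requires_metadata():
    with pytest.raises(ValueError):
        classify_units(None, 2.0)


# ---------------------------------------------------------------------------
# similarity scores


def _grid_map(values):
    v = np.asarray(values, float)
    return RateMap(v, np.ones_like(v), np.ones_like(v, bool),
                   extent=(0, v.shape[1] * 5.0, 0, v.shape[0] * 5.0))


def test_spatial_similarity_identity_and_reversal(rng):
    a = _grid_map(rng.uniform(0, 10, (4, 5)))
    assert spatial_similarity(a, a) == pytest.approx(1.0)
    flipped = _grid_map(10.0 - a.rates)  # monotone decreasing transform
    assert spatial_similarity(a, flipped) == pytest.approx(-1.0)


def test_spatial_similarity_independent_of_rate_scaling(rng):
    a = _grid_map(rng.uniform(0, 10, (4, 5)))
    doubled = _grid_map(2.0 * a.rates)
    assert spatial_similarity(a, doubled) == pytest.approx(1.0)
    r1 = a.roi_mean_rate()
    r2 = doubled.roi_mean_rate()
    assert rate_similarity(r1, r2) < 1.0  # rate similarity sees the change


def test_spatial_similarity_symmetry_and_errors(rng):
    a = _grid_map(rng.uniform(0, 5, (3, 4)))
    b = _grid_map(rng.uniform(0, 5, (3, 4)))
    assert spatial_similarity(a, b) == pytest.approx(spatial_similarity(b, a))
    tiny = _grid_map(np.array([[1.0, 2.0]]))
    with pytest.raises(UndefinedStatisticError):
        spatial_similarity(tiny, tiny)  # < 3 joint bins
    flat = _grid_map(np.full((3, 4), 2.0))
    with pytest.raises(UndefinedStatisticError):
        spatial_similarity(flat, a)


@pytest.mark.parametrize("a,b,expected", [
    (2.0, 2.0, 1.0),
    (3.0, 1.0, 0.5),
    (7.3, 0.0, 0.0),
])
def test_rate_similarity_values(a, b, expected):
    assert rate_similarity(a, b) == pytest.approx(expected)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(a=st.floats(0.0, 100.0), b=st.floats(0.0, 100.0),
       c=st.floats(0.01, 50.0))
def test_rate_similarity_properties(a, b, c):
    if a + b == 0:
        with pytest.raises(UndefinedStatisticError):
            rate_similarity(a, b)
        return
    r = rate_similarity(a, b)
    assert 0.0 <= r <= 1.0
    assert r == pytest.approx(rate_similarity(b, a))
    assert r == pytest.approx(rate_similarity(c * a, c * b))  # scale-invariant


# ---------------------------------------------------------------------------
# ANCOVA screen


def _cell_obs(rng, n=40, effect=0.0, speed_confound=False):
    rows = []
    for ci, cond in enumerate(("A", "B")):
        speed = rng.normal(30, 3, n) + (2.0 * (2 * ci - 1) if speed_confound else 0)
        rate = 3.0 * (1.0 + effect * ci) + rng.normal(0, 0.8, n)
        if speed_confound:
            rate = rate + 0.3 * (speed - 30.0)
        rows.append(pd.DataFrame({
            "rate": rate, "condition": cond, "speed": speed,
            "head_direction": rng.normal(90, 4, n),
            "lateral": rng.normal(0, 1, n)}))
    return pd.concat(rows, ignore_index=True)


def test_ancova_detects_rate_offset(rng):
    hits = sum(ancova_screen(_cell_obs(rng, effect=0.5)).significant
               for _ in range(60))
    assert hits >= 57  # >95% power at a 50% rate offset, 40 laps/condition


def test_ancova_removes_speed_confound(rng):
    """Rate differences fully mediated by a speed difference are not flagged
    after covariate adjustment in >= 90% of simulations."""
    flags = sum(ancova_screen(_cell_obs(rng, speed_confound=True)).significant
                for _ in range(100))
    assert flags <= 10


def test_ancova_input_validation(rng):
    obs = _cell_obs(rng)
    with pytest.raises(ValueError):
        ancova_screen(obs[obs["condition"] == "A"])
    res = ancova_screen(obs, unit_id=5, comparison="demo")
    assert 0.0 <= res.p_value <= 1.0
    assert res.significant == (res.p_value < 0.05)
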
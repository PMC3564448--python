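"""State-space trajectory construction and the nearest-mean classifiers."""

import numpy as np
import pandas as pd
import pytest

from episodecode import ensemble
from episodecode.ensemble import (TrajectorySet, _majority, _predict_bins,
                                  build_trajectories, binary_suite,
                                  cell_count_curve, classify_laps,
                                  generalize_journey, generalization_shuffle,
                                  pca_project, shuffle_control)


def _toy_ts(X, labels, subtask=None, origin=None, dest=None, pitch=1.0):
    X = np.asarray(X, dtype=np.float32)
    n = X.shape[0]
    laps = pd.DataFrame({
        "lap_index": np.arange(n),
        "trial_type": labels,
        "subtask": subtask if subtask is not None else ["VD"] * n,
        "origin": origin if origin is not None else ["R"] * n,
        "destination": dest if dest is not None else ["L"] * n,
        "correct": True,
    })
    return TrajectorySet(X, laps, pitch, np.arange(X.shape[2]))


def _cluster_X(rng, n_per, centers, m=30, n_cells=6, noise=0.3):
    X, labels = [], []
    for li, c in enumerate(centers):
        for _ in range(n_per):
            X.append(c + rng.normal(0, noise, (m, n_cells)))
            labels.append(f"T{li}")
    return np.asarray(X), labels


# ---------------------------------------------------------------------------
# trajectory construction


def test_single_spike_smoothing_profile(small_session, small_prep):
    """A single spike produces a discrete Gaussian column (SD = 5 cm) that
    integrates to ~1 spike."""
    from episodecode.taskmodel import SpikeTrain

    lin = small_prep.linearized[0]
    mid = 0.5 * (lin.sample_t[0] + lin.sample_t[-1])
    st = SpikeTrain(0, np.array([mid]))
    ts = build_trajectories([st], [lin], small_prep.laps.iloc[:1])
    col = ts.X[0, :, 0]
    assert col.sum() == pytest.approx(1.0, rel=1e-3)
    peak_bin = int(np.argmax(col))
    expect_bin = int(lin.arc_at(np.array([mid]))[0] / lin.pitch)
    assert abs(peak_bin - expect_bin) <= 1
    # profile matches a normalized Gaussian of SD 5 cm on the arc grid
    arcs = (np.arange(ts.n_bins) + 0.5) * ts.pitch
    mu = arcs[peak_bin]
    ref = np.exp(-0.5 * ((arcs - mu) / 5.0) ** 2)
    ref = ref / ref.sum()
    assert np.corrcoef(col, ref)[0, 1] > 0.999


def test_trajectory_linearity_and_zero(small_prep):
    from episodecode.taskmodel import SpikeTrain

    lin = small_prep.linearized[0]
    t0, t1 = lin.sample_t[0], lin.sample_t[-1]
    times = np.linspace(t0 + 0.1, t1 - 0.1, 7)
    one = build_trajectories([SpikeTrain(0, times)], [lin],
                             small_prep.laps.iloc[:1])
    two = build_trajectories([SpikeTrain(0, np.sort(np.r_[times, times]))],
                             [lin], small_prep.laps.iloc[:1])
    assert np.allclose(two.X, 2.0 * one.X, atol=1e-5)
    empty = build_trajectories([SpikeTrain(0, np.empty(0))], [lin],
                               small_prep.laps.iloc[:1])
    assert np.all(empty.X == 0)


def test_mismatched_bin_counts_rejected(small_prep):
    from episodecode.taskmodel import SpikeTrain

    bad = small_prep.linearized[0]
    import copy

    other = copy.copy(small_prep.linearized[1])
    other.occupancy = other.occupancy[:-10]
    with pytest.raises(ValueError):
        build_trajectories([SpikeTrain(0, np.empty(0))], [bad, other],
                           small_prep.laps.iloc[:2])


# ---------------------------------------------------------------------------
# LOOCV nearest-mean engine


def test_loocv_matches_explicit_exclusion(rng):
    """The rescaling shortcut equals recomputing each mean without the test
    lap (LOOCV integrity, verified by recomputation)."""
    X = rng.normal(0, 1, (12, 7, 4))
    y = np.array([0, 0, 0, 0, 1, 1, 1, 2, 2, 2, 2, 2])
    pred = _predict_bins(X, y, 3, loocv=True)
    for l in range(len(y)):
        d = np.empty((3, 7))
        for k in range(3):
            sel = (y == k) & (np.arange(len(y)) != l)
            mu = X[sel].mean(axis=0)
            d[k] = np.sqrt(((X[l] - mu) ** 2).sum(axis=1))
        assert np.array_equal(pred[l], np.argmin(d, axis=0))


def test_separable_clusters_classified_perfectly(rng):
    X, labels = _cluster_X(rng, 6, [np.zeros((30, 6)), np.full((30, 6), 3.0)])
    res = classify_laps(_toy_ts(X, labels), roi=None)
    assert res.accuracy == 1.0
    assert res.chance == 0.5
    assert (res.per_bin_accuracy == 1.0).all()


def test_relabeling_equivariance(rng):
    """Swapping candidate label names permutes predictions identically."""
    X, labels = _cluster_X(rng, 5, [np.zeros((20, 5)), np.full((20, 5), 2.0)],
                           m=20, n_cells=5)
    res1 = classify_laps(_toy_ts(X, labels), roi=None, profile=False)
    swapped = ["B" if l == "T0" else "A" for l in labels]
    res2 = classify_laps(_toy_ts(X, swapped), roi=None, profile=False)
    mapping = {"T0": "B", "T1": "A"}
    assert [mapping[p] for p in res1.predicted] == list(res2.predicted)
    assert res1.accuracy == res2.accuracy


def test_distance_tie_breaks_to_first_label():
    X = np.zeros((4, 3, 2), dtype=np.float32)  # all laps identical => all ties
    pred = _predict_bins(X, np.array([0, 0, 1, 1]), 2, loocv=False)
    assert (pred == 0).all()
    winners, tie = _majority(np.array([[0, 1]]), 2)
    assert winners[0] == -1 and tie[0]  # split vote is flagged ambiguous


def test_shuffle_null_at_chance_and_reproducible(rng):
    X = rng.normal(0, 1, (24, 10, 5)).astype(np.float32)  # no signal at all
    ts = _toy_ts(X, ["A"] * 12 + ["B"] * 12)
    null1 = shuffle_control(ts, roi=None, n_shuffles=60, seed=5)
    null2 = shuffle_control(ts, roi=None, n_shuffles=60, seed=5)
    assert np.array_equal(null1.accuracies, null2.accuracies)
    assert abs(null1.mean - 0.5) < 3.0 * np.sqrt(0.25 / 24)
    assert null1.chance == 0.5


def test_shuffle_null_sd_shrinks_with_lap_count(rng):
    """Binomial-variance oracle: the null SD scales ~1/sqrt(n_laps)."""
    sds = {}
    for n in (12, 48):
        X = rng.normal(0, 1, (2 * n, 8, 4)).astype(np.float32)
        ts = _toy_ts(X, ["A"] * n + ["B"] * n)
        sds[n] = shuffle_control(ts, roi=None, n_shuffles=150, seed=2).sd
    ratio = sds[12] / sds[48]
    assert ratio == pytest.approx(2.0, rel=0.5)


def test_no_remapping_session_is_at_chance():
    """With identical tuning across all trial types, stem classification
    falls to chance (within 3 null SD)."""
    from conftest import SMALL_BLOCKS
    from episodecode.session import (simulate_session, prepare_session,
                                     build_trajectory_set)
    from episodecode.taskmodel import TuningParams

    s = simulate_session(
        blocks=SMALL_BLOCKS,
        tuning_params=TuningParams(n_cells=12, journey_mode="none",
                                   demand_mode="none"),
        seed=77)
    prep = prepare_session(s)
    ts = build_trajectory_set(prep, units=prep.place_cells or
                              list(range(12)))
    lab = np.where(np.isin(prep.laps["trial_type"], ["SA1", "SA2"]),
                   prep.laps["trial_type"], None)
    res = classify_laps(ts, labels=lab, profile=False)
    null = shuffle_control(ts, labels=lab, n_shuffles=100, seed=1)
    assert abs(res.accuracy - 0.5) <= 3.0 * max(null.sd, 1e-6) + 1e-9


# ---------------------------------------------------------------------------
# generalization and the cell-count curve


@pytest.fixture(scope="module")
def gen_ts(rng=None):
    """Toy session: journey patterns shared across subtasks, rates scaled by
    demand (rate-only remapping)."""
    rng = np.random.default_rng(8)
    m, n = 25, 10
    pat = {"RL": rng.uniform(0, 3, (m, n)), "LR": rng.uniform(0, 3, (m, n))}
    scale = {"VD": 1.0, "SA": 0.6, "DA": 1.5}
    X, tt, sub, orig, dest = [], [], [], [], []
    for st_name in ("VD", "SA", "DA"):
        for j, (o, d) in (("RL", ("R", "L")), ("LR", ("L", "R"))):
            for _ in range(8):
                X.append(scale[st_name] * pat[j] + rng.normal(0, 0.3, (m, n)))
                tt.append(f"{st_name}{j}")
                sub.append(st_name)
                orig.append(o)
                dest.append(d)
    return _toy_ts(np.asarray(X), tt, sub, orig, dest)


def test_generalization_across_demands(gen_ts):
    g = generalize_journey(gen_ts, "VD", roi=None)
    assert set(g.targets) == {"SA", "DA"}
    assert g.n_laps == 32
    assert g.accuracy > 0.95
    null = generalization_shuffle(gen_ts, "VD", roi=None, n_shuffles=40, seed=3)
    assert abs(null.mean - 0.5) < 3.0 * np.sqrt(0.25 / 32)


def test_generalization_degenerate_equals_loocv(gen_ts):
    """With a single subtask present, generalization reduces to the LOOCV
    journey classifier on that subtask."""
    only_vd = gen_ts.laps["subtask"] == "VD"
    sub = TrajectorySet(gen_ts.X[only_vd.values], gen_ts.laps[only_vd]
                        .reset_index(drop=True), gen_ts.pitch, gen_ts.cell_ids)
    g = generalize_journey(sub, "VD", roi=None)
    jl = np.where(sub.laps["origin"] == "R", "RL", "LR")
    ref = classify_laps(sub, labels=jl, roi=None, profile=False)
    assert g.accuracy == ref.accuracy


def test_cell_count_curve_monotone(gen_ts):
    df = cell_count_curve(gen_ts, "VD", sizes=[1, 4, 10], n_draws=25, seed=0,
                          roi=None)
    assert df.loc[df["n_cells"] == 10, "sd"].item() == 0.0  # full roster
    assert df.loc[df["n_cells"] == 10, "n_draws"].item() == 1
    accs = df.sort_values("n_cells")["mean_accuracy"].values
    assert accs[-1] >= accs[0] - 0.05
    with pytest.raises(ValueError):
        cell_count_curve(gen_ts, "VD", sizes=[999], n_draws=2, seed=0)


def test_missing_reference_journey_rejected(gen_ts):
    bad = gen_ts.laps.copy()
    bad.loc[bad["subtask"] == "VD", "destination"] = "L"
    bad.loc[bad["subtask"] == "VD", "origin"] = "R"
    ts = TrajectorySet(gen_ts.X, bad, gen_ts.pitch, gen_ts.cell_ids)
    with pytest.raises(ValueError):  # reference has the R-L journey only
        generalize_journey(ts, "VD", roi=None)


# ---------------------------------------------------------------------------
# binary suite and PCA


def test_binary_suite_on_separable_session(small_ts):
    out = binary_suite(small_ts)
    assert set(out) <= {"journeys", "task_demands", "trial_types"}
    assert "journeys" in out
    assert out["journeys"]["mean"] > 0.9  # strong remapping separates journeys
    for cat in out.values():
        assert len(cat["pairs"]) == len(cat["accuracies"])
        assert all(0.0 <= a <= 1.0 for a in cat["accuracies"])


def test_pca_projection_properties(rng):
    m, n = 40, 8
    basis = rng.normal(0, 1, (3, n))
    coords = rng.normal(0, 2, (6, m, 3))
    X = coords @ basis  # data confined to a 3-dim subspace
    ts = _toy_ts(X, ["A"] * 3 + ["B"] * 3)
    proj, evr = pca_project(ts, n_components=3)
    assert proj.shape == (6, m, 3)
    assert evr.sum() == pytest.approx(1.0, abs=1e-9)
    # projection is contractive: pairwise distances never grow
    d_full = np.linalg.norm(ts.X[0].astype(np.float64) - ts.X[1], axis=1)
    d_proj = np.linalg.norm(proj[0] - proj[1], axis=1)
    assert np.all(d_proj <= d_full * (1.0 + 1e-4) + 1e-4)
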
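"""State-space neuronal-trajectory analysis.

Each lap is represented as an m-location x n-cell matrix of Gaussian-smoothed
spike counts (SD = 5 cm on an ~0.35 cm arc-length grid): a trajectory
through the n-dimensional ensemble state space. Laps are classified by the
Euclidean distance, at matched location bins, to the mean trajectory of each
candidate condition; the mean is always recomputed excluding the test lap
(leave-one-out cross-validation). A lap's label over a region of interest
(the central stem) is the most frequent per-bin label. Shuffle controls
permute the sequence of lap labels and repeat the whole procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.ndimage import gaussian_filter1d

AMBIGUOUS = "__ambiguous__"


@dataclass
class TrajectorySet:
    """Stacked ensemble trajectories: laps x location bins x cells."""

    X: np.ndarray  # (n_laps, m, n_cells) smoothed counts
    laps: pd.DataFrame  # lap_index, trial_type, subtask, origin, destination, correct
    pitch: float  # cm per location bin
    cell_ids: np.ndarray
    sd_cm: float = 5.0
    stem_interval: Optional[tuple] = None  # (arc_start, arc_end) of the ROI

    @property
    def n_laps(self):
        return self.X.shape[0]

    @property
    def n_bins(self):
        return self.X.shape[1]

    @property
    def n_cells(self):
        return self.X.shape[2]

    @property
    def arc_centers(self):
        return (np.arange(self.n_bins) + 0.5) * self.pitch

    def roi_bins(self, roi: Optional[tuple] = None):
        """Bin indices whose centers fall inside an arc interval (default:
        the central stem)."""
        roi = roi if roi is not None else self.stem_interval
        if roi is None:
            return np.arange(self.n_bins)
        c = self.arc_centers
        return np.flatnonzero((c >= roi[0]) & (c <= roi[1]))

    def subset_cells(self, cells) -> "TrajectorySet":
        return TrajectorySet(self.X[:, :, cells], self.laps, self.pitch,
                             np.asarray(self.cell_ids)[cells], self.sd_cm,
                             self.stem_interval)


def build_trajectories(spike_trains, linearized_laps, lap_table: pd.DataFrame,
                       sd_cm: float = 5.0) -> TrajectorySet:
    """Bin each cell's spikes on the arc-length grid and smooth (SD = 5 cm).

    ``linearized_laps`` provide the per-lap time-to-arc mapping; all laps
    must share the same bin count (journeys of equal path length).
    """
    m_set = {lin.n_bins for lin in linearized_laps}
    if len(m_set) != 1:
        raise ValueError(f"laps disagree on bin count: {sorted(m_set)}")
    m = m_set.pop()
    pitch = linearized_laps[0].pitch
    n = len(spike_trains)
    sigma = sd_cm / pitch
    X = np.zeros((len(linearized_laps), m, n), dtype=np.float32)
    for li, lin in enumerate(linearized_laps):
        t0, t1 = lin.sample_t[0], lin.sample_t[-1]
        counts = np.zeros((m, n))
        for ci, st in enumerate(spike_trains):
            ts = st.between(t0, t1 + 1e-9)
            if len(ts) == 0:
                continue
            idx = np.minimum((lin.arc_at(ts) / pitch).astype(int), m - 1)
            counts[:, ci] = np.bincount(idx, minlength=m)
        X[li] = gaussian_filter1d(counts, sigma=sigma, axis=0, mode="constant")
    cells = np.asarray([st.unit_id for st in spike_trains])
    return TrajectorySet(X, lap_table.reset_index(drop=True), pitch, cells, sd_cm)


# ---------------------------------------------------------------------------
# nearest-mean-trajectory engine


def _predict_bins(X, y_idx, n_classes, loocv=True):
    """Per-bin nearest-LOOCV-mean class for every lap.

    X: (L, B, N); y_idx: int class per lap. Returns (L, B) argmin labels.
    Ties in distance resolve to the lowest class index (lexicographic when
    the caller passes sorted class labels).
    """
    L, B, N = X.shape
    X64 = X.astype(np.float64, copy=False)
    Y = np.zeros((n_classes, L))
    Y[y_idx, np.arange(L)] = 1.0
    counts = Y.sum(axis=1)
    S = (Y @ X64.reshape(L, B * N)).reshape(n_classes, B, N)
    M = S / counts[:, None, None]
    Xb = np.ascontiguousarray(X64.transpose(1, 0, 2))  # (B, L, N)
    Mb = np.ascontiguousarray(M.transpose(1, 2, 0))  # (B, N, K)
    cross = Xb @ Mb  # (B, L, K)
    Xn = np.einsum("bln,bln->bl", Xb, Xb)
    Mn = np.einsum("bnk,bnk->bk", Mb, Mb)
    d2 = Xn[:, :, None] + Mn[:, None, :] - 2.0 * cross
    np.maximum(d2, 0.0, out=d2)
    if loocv:
        nk = counts[y_idx]
        if np.any(nk < 2):
            raise ValueError("LOOCV needs >= 2 laps per class")
        # excluding the test lap rescales its own-class distance by n/(n-1)
        d2[:, np.arange(L), y_idx] *= (nk / (nk - 1.0)) ** 2
    return np.argmin(d2, axis=2).T  # (L, B)


def _majority(pred_bins, n_classes):
    """Most frequent per-bin class per lap; ties are flagged ambiguous (-1)."""
    votes = (pred_bins[:, :, None] == np.arange(n_classes)).sum(axis=1)
    top = votes.max(axis=1)
    winners = np.argmax(votes, axis=1)
    tie = (votes == top[:, None]).sum(axis=1) > 1
    winners = winners.astype(int)
    winners[tie] = -1
    return winners, tie


@dataclass
class ClassificationResult:
    """Outcome of LOOCV nearest-mean-trajectory classification."""

    class_labels: list
    lap_index: np.ndarray
    true_labels: np.ndarray
    predicted: np.ndarray  # ROI majority label per lap ('-' = ambiguous tie)
    correct: np.ndarray
    accuracy: float  # lap-level ROI accuracy
    chance: float
    per_bin_accuracy: np.ndarray = field(repr=False, default=None)
    per_bin_p: np.ndarray = field(repr=False, default=None)
    arc_centers: np.ndarray = field(repr=False, default=None)
    n_ties: int = 0

    def to_frame(self):
        return pd.DataFrame({
            "lap_index": self.lap_index,
            "true": self.true_labels,
            "predicted": self.predicted,
            "correct": self.correct,
        })


def _select_laps(ts, labels, include, min_laps):
    """Resolve the lap subset and integer class labels for classification."""
    lab = np.asarray(labels if labels is not None else ts.laps["trial_type"].values,
                     dtype=object)
    keep = np.asarray(include if include is not None
                      else ts.laps["correct"].values & pd.notna(lab), dtype=bool)
    keep = keep & pd.notna(lab)
    lab_s = np.where(keep, lab, None)
    uniq, counts = np.unique(lab_s[keep].astype(str), return_counts=True)
    small = uniq[counts < min_laps]
    if len(small):
        warnings.warn(f"excluding labels with < {min_laps} laps: {list(small)}")
        keep[keep] = ~np.isin(lab_s[keep].astype(str), small)
    classes = sorted(np.unique(lab_s[keep].astype(str)).tolist())
    if len(classes) < 2:
        raise ValueError("need >= 2 candidate labels")
    y = np.array([classes.index(v) for v in lab_s[keep].astype(str)])
    return np.flatnonzero(keep), y, classes


def classify_laps(ts: TrajectorySet, labels: Optional[Sequence] = None,
                  roi: Optional[tuple] = None, include: Optional[np.ndarray] = None,
                  min_laps: int = 2, profile: bool = True) -> ClassificationResult:
    """Classify every lap among its candidate labels by nearest LOOCV mean.

    ``labels`` defaults to the lap table's trial types (correct laps only
    when ``include`` is not given). Labels with fewer than ``min_laps`` laps
    are excluded with a warning. ``roi`` is an arc interval; default the
    central stem.
    """
    idx, y, classes = _select_laps(ts, labels, include, min_laps)
    lab_k = np.asarray(classes, dtype=object)[y]
    roi_bins = ts.roi_bins(roi)
    pred_roi = _predict_bins(ts.X[idx][:, roi_bins, :], y, len(classes))
    winners, tie = _majority(pred_roi, len(classes))
    predicted = np.array([classes[w] if w >= 0 else AMBIGUOUS for w in winners],
                         dtype=object)
    correct = (winners == y) & ~tie
    acc = float(correct.mean())
    per_bin_acc = per_bin_p = centers = None
    if profile:
        pred_all = _predict_bins(ts.X[idx], y, len(classes))
        hits = pred_all == y[:, None]
        per_bin_acc = hits.mean(axis=0)
        k = hits.sum(axis=0)
        per_bin_p = sps.binom.sf(k - 1, len(y), 1.0 / len(classes))
        centers = ts.arc_centers
    return ClassificationResult(
        classes, ts.laps["lap_index"].values[idx], lab_k.astype(str), predicted,
        correct, acc, 1.0 / len(classes), per_bin_acc, per_bin_p, centers,
        n_ties=int(tie.sum()))


@dataclass
class ShuffleNull:
    accuracies: np.ndarray
    chance: float

    @property
    def mean(self):
        return float(self.accuracies.mean())

    @property
    def sd(self):
        return float(self.accuracies.std(ddof=1))

    def quantile(self, q):
        return float(np.quantile(self.accuracies, q))


def shuffle_control(ts: TrajectorySet, labels: Optional[Sequence] = None,
                    roi: Optional[tuple] = None, include: Optional[np.ndarray] = None,
                    n_shuffles: int = 1000, seed=0) -> ShuffleNull:
    """Null accuracy distribution from randomizing the sequence of lap labels.

    Each shuffle permutes the lap labels, recomputes the LOOCV mean
    trajectories under the permuted labels, and scores the stem majority
    vote against the permuted labels.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    idx, y, classes = _select_laps(ts, labels, include, min_laps=2)
    Xroi = ts.X[idx][:, ts.roi_bins(roi), :]
    rng = np.random.default_rng(seed)
    accs = np.empty(n_shuffles)
    for s in range(n_shuffles):
        yp = rng.permutation(y)
        winners, tie = _majority(_predict_bins(Xroi, yp, len(classes)), len(classes))
        accs[s] = float(((winners == yp) & ~tie).mean())
    return ShuffleNull(accs, 1.0 / len(classes))


# ---------------------------------------------------------------------------
# generalization across task demands


def _journey_class(laps: pd.DataFrame):
    """'RL'/'LR' label per lap; None for non-crossing journeys."""
    out = np.full(len(laps), None, dtype=object)
    rl = (laps["origin"] == "R") & (laps["destination"] == "L")
    lr = (laps["origin"] == "L") & (laps["destination"] == "R")
    out[rl.values] = "RL"
    out[lr.values] = "LR"
    return out


@dataclass
class GeneralizationResult:
    reference: str
    targets: tuple
    accuracy: float
    n_laps: int
    predicted: np.ndarray = field(repr=False, default=None)
    true_labels: np.ndarray = field(repr=False, default=None)
    chance: float = 0.5


def generalize_journey(ts: TrajectorySet, reference_subtask: str,
                       roi: Optional[tuple] = None, cells=None,
                       permuted_labels: Optional[np.ndarray] = None
                       ) -> GeneralizationResult:
    """Classify other subtasks' journeys by the reference subtask's templates.

    Mean R-L and L-R trajectories are computed from the reference subtask's
    correct crossing laps; each correct crossing lap of the remaining
    subtasks is labeled by the nearest template per stem bin and a majority
    vote. When reference and target coincide (degenerate case) the LOOCV
    classifier on that subtask is used instead.
    """
    if cells is not None:
        ts = ts.subset_cells(cells)
    laps = ts.laps
    jlab = _journey_class(laps)
    valid = laps["correct"].values & pd.notna(jlab)
    is_ref = (laps["subtask"] == reference_subtask).values & valid
    targets = tuple(sorted(set(laps["subtask"][valid & ~is_ref])))
    if not targets:  # degenerate: reference == target set
        res = classify_laps(ts, labels=jlab, roi=roi, include=is_ref, profile=False)
        return GeneralizationResult(reference_subtask, (reference_subtask,),
                                    res.accuracy, len(res.correct),
                                    res.predicted, res.true_labels)
    classes = ["LR", "RL"]
    lab = np.where(pd.notna(jlab), jlab, "")
    if permuted_labels is not None:
        lab = permuted_labels
    for j, need in ((is_ref, "reference"), (valid & ~is_ref, "target")):
        present = set(lab[j]) & set(classes)
        if len(present) < 2:
            raise ValueError(f"{need} subtask lacks one of the journeys")
    roi_bins = ts.roi_bins(roi)
    ref_idx = np.flatnonzero(is_ref)
    tgt_idx = np.flatnonzero(valid & ~is_ref)
    Xr = ts.X[ref_idx][:, roi_bins, :].astype(np.float64)
    Xt = ts.X[tgt_idx][:, roi_bins, :].astype(np.float64)
    y_ref = np.array([classes.index(v) for v in lab[ref_idx]])
    y_tgt = np.array([classes.index(v) for v in lab[tgt_idx]])
    M = np.stack([Xr[y_ref == k].mean(axis=0) for k in range(len(classes))])
    # d2[l, k, b]: distance to each journey template at each ROI bin
    d2 = ((Xt[:, None, :, :] - M[None, :, :, :]) ** 2).sum(axis=3)
    pred_bins = np.argmin(d2, axis=1)  # (L, B)
    winners, tie = _majority(pred_bins, len(classes))
    correct = (winners == y_tgt) & ~tie
    return GeneralizationResult(
        reference_subtask, targets, float(correct.mean()), len(y_tgt),
        np.array([classes[w] if w >= 0 else AMBIGUOUS for w in winners], dtype=object),
        np.asarray(lab[tgt_idx]))


def generalization_shuffle(ts: TrajectorySet, reference_subtask: str,
                           roi: Optional[tuple] = None, cells=None,
                           n_shuffles: int = 1000, seed=0) -> ShuffleNull:
    """Shuffle control for journey generalization: the R-L/L-R labels of all
    involved laps are permuted before templates and scoring."""
    laps = ts.laps
    jlab = _journey_class(laps)
    valid = laps["correct"].values & pd.notna(jlab)
    rng = np.random.default_rng(seed)
    accs = np.empty(n_shuffles)
    for s in range(n_shuffles):
        for _ in range(50):  # skip degenerate permutations (one-class ref)
            perm = np.array(jlab, dtype=object)
            perm[valid] = rng.permutation(perm[valid])
            try:
                res = generalize_journey(ts, reference_subtask, roi=roi,
                                         cells=cells, permuted_labels=perm)
                break
            except ValueError:
                continue
        else:
            raise ValueError("could not draw a valid label permutation")
        accs[s] = res.accuracy
    return ShuffleNull(accs, 0.5)


def cell_count_curve(ts: TrajectorySet, reference_subtask: str, sizes,
                     n_draws: int = 1000, seed=0, roi: Optional[tuple] = None
                     ) -> pd.DataFrame:
    """Generalization accuracy vs roster size over random cell subsets."""
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        if size > ts.n_cells:
            raise ValueError(f"roster size {size} exceeds {ts.n_cells} cells")
        if size == ts.n_cells:
            acc = np.array([generalize_journey(ts, reference_subtask, roi).accuracy])
        else:
            acc = np.array([
                generalize_journey(
                    ts, reference_subtask, roi,
                    cells=rng.choice(ts.n_cells, size, replace=False)).accuracy
                for _ in range(n_draws)])
        rows.append({"n_cells": int(size), "mean_accuracy": float(acc.mean()),
                     "sd": float(acc.std(ddof=1)) if len(acc) > 1 else 0.0,
                     "n_draws": len(acc)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# binary classification suite

JOURNEY_PAIR = (("VD1", "SA1", "DA1"), ("VD3", "SA2", "DA2"))
DEMAND_PAIRS = (("VD", "SA"), ("VD", "DA"), ("SA", "DA"))


def binary_suite(ts: TrajectorySet, roi: Optional[tuple] = None) -> dict:
    """Binary stem classification between journeys, task demands and trial
    types.

    * journeys: the R-L trial types (VD1, SA1, DA1) against the L-R trial
      types (VD3, SA2, DA2), irrespective of subtask;
    * task demands: each pair of subtasks, irrespective of journey;
    * trial types: every pair of the eight trial types.

    Returns, per category, the per-pair lap-majority accuracies and their
    mean.
    """
    laps = ts.laps
    tt = laps["trial_type"].values
    out = {}
    # journeys irrespective of subtask
    grp = np.full(len(laps), None, dtype=object)
    grp[np.isin(tt, JOURNEY_PAIR[0])] = "RL"
    grp[np.isin(tt, JOURNEY_PAIR[1])] = "LR"
    try:
        res = classify_laps(ts, labels=grp, roi=roi, profile=False)
        out["journeys"] = {"pairs": ["RL-vs-LR"], "accuracies": [res.accuracy],
                           "mean": res.accuracy}
    except ValueError as e:
        warnings.warn(f"journey pair skipped: {e}")
    # task demands irrespective of journey
    accs, pairs = [], []
    for a, b in DEMAND_PAIRS:
        sub = laps["subtask"].values
        labels = np.where(np.isin(sub, [a, b]), sub, None)
        try:
            res = classify_laps(ts, labels=labels, roi=roi, profile=False)
            accs.append(res.accuracy)
            pairs.append(f"{a}-vs-{b}")
        except ValueError as e:
            warnings.warn(f"demand pair {a}/{b} skipped: {e}")
    if accs:
        out["task_demands"] = {"pairs": pairs, "accuracies": accs,
                               "mean": float(np.mean(accs))}
    # all trial-type pairs
    types = sorted(v for v in pd.unique(tt) if v is not None)
    accs, pairs = [], []
    for i in range(len(types)):
        for j in range(i + 1, len(types)):
            labels = np.where(np.isin(tt, [types[i], types[j]]), tt, None)
            try:
                res = classify_laps(ts, labels=labels, roi=roi, profile=False)
                accs.append(res.accuracy)
                pairs.append(f"{types[i]}-vs-{types[j]}")
            except ValueError as e:
                warnings.warn(f"pair {types[i]}/{types[j]} skipped: {e}")
    if accs:
        out["trial_types"] = {"pairs": pairs, "accuracies": accs,
                              "mean": float(np.mean(accs))}
    return out


def pca_project(ts: TrajectorySet, n_components: int = 3,
                include: Optional[np.ndarray] = None):
    """Project trajectories onto leading principal components (visualization
    only; classification always runs in the full state space)."""
    from sklearn.decomposition import PCA

    keep = np.asarray(include if include is not None else np.ones(ts.n_laps, bool))
    X = ts.X[keep].astype(np.float64)
    L, B, N = X.shape
    k = min(n_components, N, L * B)
    if k < n_components:
        warnings.warn(f"only {k} components available")
    pca = PCA(n_components=k)
    flat = pca.fit_transform(X.reshape(L * B, N))
    return flat.reshape(L, B, k), pca.explained_variance_ratio_
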
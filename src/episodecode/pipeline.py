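"""End-to-end analysis of a session bundle: behavior -> place fields ->
similarity -> ANCOVA screen -> ensemble trajectory classification -> tests.

Produces a results dictionary of data frames plus a JSON-serializable
summary; :func:`write_results` lays them out on disk for the report stage.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, ensemble, placefields, stats
from .config import AnalysisParams
from .session import (PreparedSession, Session, ancova_table,
                      build_trajectory_set, differential_cells,
                      prepare_session, similarity_table, stem_observations)
from .taskmodel import TRIAL_TYPES


def analyze_session(session: Session, params: AnalysisParams = None,
                    seed: int = 0) -> dict:
    params = params or AnalysisParams()
    prep = prepare_session(session, params.immobility_cms, params.si_threshold)
    results = {"prep": prep}
    log = results["log"] = {}
    units = prep.units
    log["n_units"] = int(len(units))
    log["n_pyramidal"] = int((units["call"] == "pyramidal").sum())
    log["n_excluded_low_rate"] = int((units["call"] == "excluded").sum())
    log["n_place_cells"] = len(prep.place_cells)
    log["n_error_laps_excluded"] = int((~prep.laps["correct"]).sum())

    obs = stem_observations(prep)
    ancova = ancova_table(prep, alpha=params.alpha, observations=obs)
    diff = differential_cells(ancova)
    results["ancova"] = ancova
    log["n_differential_cells"] = len(diff)

    sim = similarity_table(prep, units=diff or prep.place_cells,
                           method=params.similarity_method)
    results["similarity"] = sim

    # turn onsets
    onsets = []
    for lap, sl in zip(session.schedule, prep.slices):
        path = session.geometry.ideal_path(*lap.journey)
        o = behavior.detect_turn_onset(session.tracking, sl, session.geometry, path)
        onsets.append({"lap_index": o.lap_index, "arclength_cm": o.arclength,
                       "x": o.x, "y": o.y, "found": o.found})
    results["turn_onsets"] = pd.DataFrame(onsets)

    ts = build_trajectory_set(prep)
    results["trajectories"] = ts
    eight = ensemble.classify_laps(ts)
    results["classification"] = eight
    null8 = ensemble.shuffle_control(ts, n_shuffles=params.n_shuffles, seed=seed)
    suite = ensemble.binary_suite(ts)
    results["binary_suite"] = suite

    gen_rows, gen_nulls = [], {}
    subtasks = sorted(set(prep.laps["subtask"]))
    if len(subtasks) == 3:
        for ref in subtasks:
            try:
                g = ensemble.generalize_journey(ts, ref)
            except ValueError as e:  # e.g. a journey missing at this scale
                import warnings

                warnings.warn(f"generalization from {ref} skipped: {e}")
                continue
            gen_rows.append({"reference": ref, "targets": "+".join(g.targets),
                             "n_cells": ts.n_cells, "accuracy": g.accuracy,
                             "n_laps": g.n_laps})
            gen_nulls[ref] = ensemble.generalization_shuffle(
                ts, ref, n_shuffles=min(params.n_shuffles, 200), seed=seed)
    results["generalization"] = pd.DataFrame(gen_rows)

    tests = [_binom_row("eightway_vs_chance", eight)]
    for cat, d in suite.items():
        k = int(round(np.mean(d["accuracies"]) * len(eight.correct)))
        tests.append(stats.binomial_test(
            min(k, len(eight.correct)), len(eight.correct), 0.5))
        tests[-1].extra["label"] = f"binary_{cat}"
    med = {}
    for klass, grp in sim.groupby("comparison_class"):
        med[klass] = {"r_s": float(grp["r_s"].median()),
                      "r_r": float(grp["r_r"].median()), "n": int(len(grp))}
    w = sim[sim["comparison_class"] == "within"]
    for other, col in (("cross_journey", "r_s"), ("cross_demand", "r_r")):
        o = sim[sim["comparison_class"] == other]
        if len(w) and len(o):
            t = stats.wilcoxon_rank_sum(o[col], w[col])
            t.extra["label"] = f"{other}_{col}_vs_within"
            tests.append(t)
    if len(suite) == 3:
        kw = stats.kruskal_wallis([d["accuracies"] for d in suite.values()],
                                  posthoc=len(suite["trial_types"]["accuracies"]) > 1)
        kw.extra["label"] = "suite_categories"
        tests.append(kw)
    results["tests"] = pd.DataFrame([
        {"test": t.test, "label": t.extra.get("label", t.test),
         "statistic": t.statistic, "p": t.p_value, "n": str(t.n), "side": t.side}
        for t in tests])

    results["summary"] = {
        "log": log,
        "similarity_medians": med,
        "eightway": {"accuracy": eight.accuracy, "chance": eight.chance,
                     "shuffle_mean": null8.mean, "shuffle_sd": null8.sd},
        "binary_suite": {k: d["mean"] for k, d in suite.items()},
        "generalization": {r["reference"]: {
            "accuracy": r["accuracy"],
            "shuffle_mean": gen_nulls[r["reference"]].mean,
            "shuffle_sd": gen_nulls[r["reference"]].sd,
        } for r in gen_rows},
        "n_shuffles": params.n_shuffles,
        "seed": seed,
    }
    return results


def _binom_row(label, res):
    t = stats.binomial_test(int(res.correct.sum()), len(res.correct), res.chance)
    t.extra["label"] = label
    return t


def write_results(results: dict, outdir, n_ratemap_cells: int = 3):
    """Write the analysis products under ``outdir``."""
    from .io import write_ratemap_csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prep: PreparedSession = results["prep"]
    results["similarity"].to_csv(outdir / "similarity.csv", index=False)
    results["ancova"].to_csv(outdir / "ancova.csv", index=False)
    results["turn_onsets"].to_csv(outdir / "turn_onsets.csv", index=False)
    results["tests"].to_csv(outdir / "tests.csv", index=False)
    results["generalization"].to_csv(outdir / "generalization.csv", index=False)
    prep.si_table.to_csv(outdir / "spatial_information.csv", index=False)
    eight = results["classification"]
    eight.to_frame().to_csv(outdir / "classification.csv", index=False)
    pd.DataFrame({"arclength_cm": eight.arc_centers,
                  "accuracy": eight.per_bin_accuracy,
                  "p": eight.per_bin_p}).to_csv(
        outdir / "accuracy_profile.csv", index=False)
    # example rate maps for the best place cells
    rmdir = outdir / "ratemaps"
    rmdir.mkdir(exist_ok=True)
    best = (prep.si_table.groupby("unit_id")["spatial_information"].max()
            .sort_values(ascending=False).index[:n_ratemap_cells])
    for u in best:
        st = prep.spike_trains_for([u])[0]
        for tt in TRIAL_TYPES:
            mask = prep.trial_type_mask({tt})
            if not mask.any():
                continue
            m = placefields.RateMapper(prep.session.tracking, mask).map(st)
            write_ratemap_csv(m, rmdir / f"{u}_{tt}.csv")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(results["summary"], fh, indent=1)
    return outdir
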
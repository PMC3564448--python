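"""Figure rendering from a results directory (matplotlib, headless)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .io import read_ratemap_csv  # noqa: E402


def render_report(results_dir, outdir=None):
    """Render the four standard figures; returns the written paths."""
    results_dir = Path(results_dir)
    if not (results_dir / "summary.json").exists():
        raise FileNotFoundError(f"no summary.json under {results_dir}")
    outdir = Path(outdir) if outdir else results_dir / "figures"
    outdir.mkdir(parents=True, exist_ok=True)
    paths = [
        _fig_ratemaps(results_dir, outdir / "ratemaps.png"),
        _fig_similarity(results_dir, outdir / "similarity.png"),
        _fig_accuracy_profile(results_dir, outdir / "accuracy_profile.png"),
        _fig_generalization(results_dir, outdir / "generalization.png"),
    ]
    return [p for p in paths if p is not None]


def _fig_ratemaps(results_dir, out):
    files = sorted((results_dir / "ratemaps").glob("*.csv"))
    if not files:
        return None
    by_cell = {}
    for f in files:
        cell, tt = f.stem.split("_", 1)
        by_cell.setdefault(cell, {})[tt] = f
    tts = sorted({tt for d in by_cell.values() for tt in d})
    fig, axes = plt.subplots(len(by_cell), len(tts),
                             figsize=(2.0 * len(tts), 2.6 * len(by_cell)),
                             squeeze=False)
    cmap = plt.get_cmap("jet").copy()
    cmap.set_bad("white")  # unvisited bins are white, distinct from rate 0
    for i, (cell, d) in enumerate(sorted(by_cell.items())):
        grids = {tt: read_ratemap_csv(f) for tt, f in d.items()}
        peak = max(np.nanmax(g) for g in grids.values()) or 1.0
        for j, tt in enumerate(tts):
            ax = axes[i][j]
            if tt in grids:
                ax.imshow(np.ma.masked_invalid(grids[tt]), origin="lower",
                          cmap=cmap, vmin=0, vmax=peak)  # scale spans the peak
            ax.set_xticks([])
            ax.set_yticks([])
            if i == 0:
                ax.set_title(tt, fontsize=9)
            if j == 0:
                ax.set_ylabel(f"cell {cell}\npeak {peak:.1f} Hz", fontsize=8)
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out


def _fig_similarity(results_dir, out):
    sim = pd.read_csv(results_dir / "similarity.csv")
    if sim.empty:
        return None
    order = [c for c in ("within", "cross_journey", "cross_demand")
             if c in set(sim["comparison_class"])]
    fig, axes = plt.subplots(1, 2, figsize=(8, 4))
    for ax, col, name in zip(axes, ("r_s", "r_r"),
                             ("spatial similarity $r_s$", "rate similarity $r_r$")):
        ax.boxplot([sim.loc[sim["comparison_class"] == c, col] for c in order],
                   tick_labels=order)
        ax.set_ylabel(name)
        ax.tick_params(axis="x", rotation=20)
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out


def _fig_accuracy_profile(results_dir, out):
    prof = pd.read_csv(results_dir / "accuracy_profile.csv")
    onsets = pd.read_csv(results_dir / "turn_onsets.csv")
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(prof["arclength_cm"], prof["accuracy"], "k-", lw=1)
    ax.axhline(0.125, ls="--", c="gray", label="chance (1/8)")
    if onsets["found"].any():
        ax.axvline(onsets.loc[onsets["found"], "arclength_cm"].mean(),
                   c="r", lw=1, label="mean turn onset")
    ax.set_xlabel("arc length (cm)")
    ax.set_ylabel("8-way classification accuracy")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out


def _fig_generalization(results_dir, out):
    gen = pd.read_csv(results_dir / "generalization.csv")
    if gen.empty:
        return None
    fig, ax = plt.subplots(figsize=(6, 4))
    for ref, grp in gen.groupby("reference"):
        ax.plot(grp["n_cells"], grp["accuracy"], "o-", label=f"reference {ref}")
    ax.axhline(0.5, ls="--", c="gray", label="chance")
    ax.set_xlabel("number of cells")
    ax.set_ylabel("journey generalization accuracy")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out
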
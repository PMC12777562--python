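"""Report bundles and figures for DOOR analyses.

A report bundle is one directory per run containing a manifest (config
hash, package version, seeds), CSV/JSON tables and PNG+SVG figures.  Every
figure has a CSV twin holding exactly the plotted numbers, so runs are
byte-reproducible and figures are auditable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .datamodel import DoorTable, GradingKey
from .grades import GradeGridResult, grade_grid, grid_long_frame, partial_credit_diff, tipping_boundary
from .rank import convert_metrics, count_pairs, forest_table
from .summaries import component_gain_loss, distribution_table, gain_loss, render_markdown

__all__ = ["analysis_bundle", "grid_bundle", "forest_plot", "contour_plot"]


def _write_manifest(outdir: Path, config: dict) -> None:
    payload = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "package": "doorstat",
        "version": __version__,
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "config": config,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def forest_plot(frame: pd.DataFrame, path_base: Path, level: float = 0.95) -> None:
    """Forest plot of DOOR probability estimates (percent scale), PNG + SVG."""
    fig, ax = plt.subplots(figsize=(7, 0.5 * len(frame) + 1.5))
    y = np.arange(len(frame))[::-1]
    est = 100 * frame["estimate"].to_numpy()
    lo = 100 * frame["ci_low"].to_numpy()
    hi = 100 * frame["ci_high"].to_numpy()
    ax.errorbar(est, y, xerr=[est - lo, hi - est], fmt="o", color="black",
                ecolor="black", capsize=3)
    ax.axvline(50.0, color="grey", linestyle="--", linewidth=1)
    ax.set_yticks(y)
    ax.set_yticklabels(frame["label"])
    ax.set_xlabel(f"DOOR probability, % ({100 * level:.0f}% CI)")
    fig.tight_layout()
    for ext in ("png", "svg"):
        fig.savefig(f"{path_base}.{ext}")
    plt.close(fig)


def contour_plot(grid: GradeGridResult, path_base: Path) -> None:
    """Contour of the mean-grade difference with the significant region shaded.

    Shading marks grading-key combinations with p below the grid's alpha
    (green favoring the experimental arm, orange favoring control); the
    tipping boundary between favored regions is overlaid.
    """
    fig, ax = plt.subplots(figsize=(6.5, 5.5))
    X, Y = np.meshgrid(grid.grid1, grid.grid2, indexing="ij")
    ax.contourf(
        X, Y, np.where(grid.favored == 1, 1.0, np.nan), levels=[0.5, 1.5],
        colors=["#2ca02c"], alpha=0.35,
    )
    ax.contourf(
        X, Y, np.where(grid.favored == -1, 1.0, np.nan), levels=[0.5, 1.5],
        colors=["#ff7f0e"], alpha=0.35,
    )
    cs = ax.contour(X, Y, grid.diff, colors="black", linewidths=0.7)
    ax.clabel(cs, inline=True, fontsize=7, fmt="%.1f")
    for (x0, y0), (x1, y1) in tipping_boundary(grid):
        ax.plot([x0, x1], [y0, y1], color="crimson", linewidth=1.2)
    ax.set_xlabel(f"partial credit for level {grid.free_levels[0]}")
    ax.set_ylabel(f"partial credit for level {grid.free_levels[1]}")
    ax.set_title(f"Difference in mean grades (shaded: p < {grid.alpha:g})")
    fig.tight_layout()
    for ext in ("png", "svg"):
        fig.savefig(f"{path_base}.{ext}")
    plt.close(fig)


def analysis_bundle(
    table: DoorTable,
    outdir: Path | str,
    components: dict[str, DoorTable] | None = None,
    grading_keys: list[GradingKey] | None = None,
    level: float = 0.95,
    standard_n: int = 1000,
    config: dict | None = None,
) -> dict:
    """Run the full unweighted analysis and write the report bundle.

    Emits the distribution table, gain/loss summary, forest-ready estimate
    table (overall + cumulative + components) with figure, pairwise metric
    conversions, and partial-credit results for each grading key.  Returns
    the bundle as a dict as well.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_manifest(outdir, config or {})

    dist = distribution_table(table)
    dist.to_csv(outdir / "distribution.csv", index=False)

    gl = gain_loss(table, standard_n)
    gl_rec = {
        "standard_n": gl.standard_n,
        "per_category": list(gl.per_category),
        "cumulative": list(gl.cumulative),
    }
    if components:
        gl_rec["per_component"] = component_gain_loss(components, standard_n)
    (outdir / "gain_loss.json").write_text(json.dumps(gl_rec, indent=2))
    (outdir / "summary_table.md").write_text(render_markdown(table, gl))

    forest = forest_table(table, components, level)
    forest.to_csv(outdir / "forest.csv", index=False)
    forest_plot(forest, outdir / "forest", level)

    metrics = convert_metrics(count_pairs(table))
    (outdir / "pairwise_metrics.json").write_text(json.dumps(metrics, indent=2))

    pc_records = []
    for key in grading_keys or []:
        est = partial_credit_diff(table, key, level)
        rec = {"grades": list(key.grades), **est.as_dict()}
        pc_records.append(rec)
    if pc_records:
        (outdir / "partial_credit.json").write_text(json.dumps(pc_records, indent=2))

    overall = forest.iloc[0]
    estimates = {
        "overall": {
            "estimate": float(overall["estimate"]),
            "ci_low": float(overall["ci_low"]),
            "ci_high": float(overall["ci_high"]),
            "p_value": float(overall["p_value"]),
            "level": level,
        },
        "metrics": metrics,
    }
    (outdir / "estimates.json").write_text(json.dumps(estimates, indent=2))
    return {
        "distribution": dist,
        "gain_loss": gl_rec,
        "forest": forest,
        "metrics": metrics,
        "partial_credit": pc_records,
    }


def grid_bundle(
    table: DoorTable,
    outdir: Path | str,
    free_levels: tuple[int, int],
    fixed_grades: dict[int, float],
    step: float = 1.0,
    alpha: float = 0.05,
    config: dict | None = None,
) -> GradeGridResult:
    """Compute the partial-credit grid, write its CSV twin and contour figure."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_manifest(outdir, config or {})
    grid = grade_grid(table, free_levels, fixed_grades, step, alpha)
    grid_long_frame(grid).to_csv(outdir / "grade_grid.csv", index=False)
    boundary = tipping_boundary(grid)
    pd.DataFrame(
        [(x0, y0, x1, y1) for (x0, y0), (x1, y1) in boundary],
        columns=["x0", "y0", "x1", "y1"],
    ).to_csv(outdir / "tipping_boundary.csv", index=False)
    contour_plot(grid, outdir / "contour")
    return grid
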
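"""Forest, funnel and leave-one-out influence plots.

All plots are drawn with matplotlib's non-interactive Agg backend and
written straight to file; they visualise numbers computed elsewhere and
never recompute statistics.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .bias import FunnelData
from .meta import EffectEstimate, PooledResult
from .stratify import LeaveOneOutReport

__all__ = ["render_forest", "render_funnel", "render_influence"]


def render_forest(effects: Sequence[EffectEstimate], labels: Sequence[str],
                  pooled: PooledResult, path: str | Path,
                  title: str = "") -> Path:
    """Forest plot: per-study squares sized by inverse-variance weight, 95%
    CI whiskers, a pooled diamond, and the OR = 1 reference line on a log
    axis.  Returns the written path."""
    k = len(effects)
    if k != len(labels):
        raise ValueError("one label per effect required")
    w = np.array([1.0 / e.var_log_or for e in effects])
    sizes = 40 + 160 * w / w.max()
    fig, ax = plt.subplots(figsize=(7, 0.45 * (k + 3)))
    ys = np.arange(k, 0, -1)
    for y, e, s in zip(ys, effects, sizes):
        ax.plot([e.ci_low, e.ci_high], [y, y], color="black", lw=1)
        ax.scatter([e.or_], [y], s=s, marker="s", color="#2c5f8a", zorder=3)
    # pooled diamond at y = 0
    dy = 0.25
    ax.fill(
        [pooled.ci_low, pooled.pooled_or, pooled.ci_high, pooled.pooled_or],
        [0, dy, 0, -dy],
        color="#8a2c2c",
    )
    ax.axvline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_xscale("log")
    ax.set_yticks(list(ys) + [0])
    ax.set_yticklabels(list(labels) + [f"Pooled ({pooled.method})"])
    ax.set_xlabel("Odds ratio (log scale)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path)
    plt.close(fig)
    return path


def render_funnel(data: FunnelData, path: str | Path, title: str = "") -> Path:
    """Begg-style funnel plot: log-OR against SE (inverted axis) with
    pseudo-95% confidence bounds around the fixed pooled estimate."""
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(data.log_or, data.se, color="#2c5f8a", zorder=3)
    ax.plot(data.lower, data.se_grid, "--", color="grey", lw=1)
    ax.plot(data.upper, data.se_grid, "--", color="grey", lw=1)
    ax.axvline(data.center, color="grey", lw=0.8)
    ax.invert_yaxis()
    ax.set_xlabel("log odds ratio")
    ax.set_ylabel("standard error")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path)
    plt.close(fig)
    return path


def render_influence(report: LeaveOneOutReport, path: str | Path,
                     title: str = "") -> Path:
    """Influence plot: the pooled OR and 95% CI after omitting each study,
    with the all-studies estimate and CI as reference lines."""
    entries = report.entries
    k = len(entries)
    fig, ax = plt.subplots(figsize=(7, 0.45 * (k + 2)))
    ys = np.arange(k, 0, -1)
    for y, e in zip(ys, entries):
        ax.plot([e.result.ci_low, e.result.ci_high], [y, y], color="black", lw=1)
        ax.scatter([e.result.pooled_or], [y], marker="o", color="#2c5f8a", zorder=3)
    ax.axvline(report.overall.pooled_or, color="#8a2c2c", lw=1)
    ax.axvline(report.overall.ci_low, color="#8a2c2c", lw=0.8, ls="--")
    ax.axvline(report.overall.ci_high, color="#8a2c2c", lw=0.8, ls="--")
    ax.set_xscale("log")
    ax.set_yticks(ys)
    ax.set_yticklabels([f"omit {e.omitted}" for e in entries])
    ax.set_xlabel("Pooled odds ratio with study omitted (log scale)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path)
    plt.close(fig)
    return path
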
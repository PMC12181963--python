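"""Diagnostic figures: map-vs-diagonal plots and density overlays."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .density import DensitySeries
from .dynamics import find_fixed_points
from .transfer import PiecewiseLinearMap

__all__ = ["plot_map", "plot_density_overlays"]


def plot_map(pw_map: PiecewiseLinearMap, path, title: str = "one-step map") -> None:
    """Draw the map's branches, the diagonal, and its fixed points."""
    fig, ax = plt.subplots(figsize=(5, 5))
    lo, hi = pw_map.partition.lo, pw_map.partition.hi
    for br in pw_map.branches:
        xs = np.array([br.x_lo, br.x_hi])
        ax.plot(xs, br.slope * xs + br.intercept, color="C0", lw=1.5)
    ax.plot([lo, hi], [lo, hi], color="red", lw=1, label="y = x")
    fps = find_fixed_points(pw_map)
    for fp in fps:
        ax.plot(
            fp.x_star,
            fp.x_star,
            "o",
            color="green" if fp.stable else "orange",
            ms=6,
        )
    ax.set_xlim(lo, hi)
    ax.set_ylim(lo, hi)
    ax.set_xlabel("log10 intensity, day n")
    ax.set_ylabel("log10 intensity, day n+1")
    ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=150)
    plt.close(fig)


def plot_density_overlays(
    observed: DensitySeries,
    predicted: DensitySeries,
    out_dir,
    prefix: str = "density",
) -> list[Path]:
    """One figure per shared day, observed (red) vs predicted (blue)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    part = observed.partition
    xs = np.repeat(part.edges, 2)[1:-1]
    paths: list[Path] = []
    shared = sorted(set(observed.times) & set(predicted.times))
    for day in shared:
        f_obs = observed.densities[observed.times.index(day)]
        f_pred = predicted.densities[predicted.times.index(day)]
        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.plot(xs, np.repeat(f_obs.values, 2), color="red", label="observed")
        ax.plot(
            xs, np.repeat(f_pred.values, 2), color="blue", ls="--", label="predicted"
        )
        ax.set_xlabel("log10 intensity")
        ax.set_ylabel("density")
        ax.set_title(f"{observed.fraction_label}, day {day}")
        ax.legend(fontsize=8)
        fig.tight_layout()
        path = out_dir / f"{prefix}_{observed.fraction_label}_day{day}.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        paths.append(path)
    return paths
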
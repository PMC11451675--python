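"""RAF-versus-OR bubble plots sized by attributable risk.

Each panel scatters risk allele frequency (x) against odds ratio (y) with
marker area linear in PAR, either one panel per ancestry colored by locus
(the per-ancestry comparison view) or one panel per variant colored by
ancestry (the per-variant cross-population view).  Output is
deterministic: identical inputs produce identical vector files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .records import ConfigError, PAREstimate

_MODES = ("by_locus_panels", "by_variant_panels")
_MIN_AREA = 12.0  # pt^2 floor so PAR = 0 is still visible


@dataclass
class PlotSpec:
    mode: str = "by_locus_panels"
    size_scale: float = 2000.0
    fmt: str = "svg"
    panel_order: list[str] = field(default_factory=list)
    log_or_axis: bool = False

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ConfigError(f"unknown plot mode {self.mode!r}; choose from {_MODES}")
        if self.size_scale <= 0:
            raise ConfigError("size_scale must be positive")
        if self.fmt not in ("svg", "png"):
            raise ConfigError(f"unsupported format {self.fmt!r}")


def marker_area(par: float, size_scale: float) -> float:
    """Marker area in pt^2: linear in PAR with a visibility floor."""
    return _MIN_AREA + size_scale * par


def plot_par(estimates: Sequence[PAREstimate], spec: PlotSpec, path) -> None:
    """Write the panel figure for a collection of PAR estimates."""
    estimates = list(estimates)
    if not estimates:
        raise ValueError("no estimates to plot")

    if spec.mode == "by_locus_panels":
        panel_key, color_key = lambda e: e.ancestry, lambda e: e.locus
    else:
        panel_key, color_key = lambda e: e.variant_id, lambda e: e.ancestry

    panels = spec.panel_order or sorted({panel_key(e) for e in estimates})
    color_values = sorted({color_key(e) for e in estimates})
    cmap = plt.get_cmap("tab20")
    colors = {v: cmap(i % 20) for i, v in enumerate(color_values)}

    ncols = min(len(panels), 2)
    nrows = (len(panels) + ncols - 1) // ncols
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(5.5 * ncols, 4.2 * nrows), squeeze=False
    )
    # fixed hash salt + no date metadata => reproducible SVG bytes
    plt.rcParams["svg.hashsalt"] = "gwaspar"

    for ax in axes.flat[len(panels):]:
        ax.set_visible(False)
    for ax, panel in zip(axes.flat, panels):
        sub = [e for e in estimates if panel_key(e) == panel]
        for e in sorted(sub, key=lambda e: (color_key(e), e.variant_id)):
            ax.scatter(
                e.raf,
                e.odds_ratio,
                s=marker_area(e.par, spec.size_scale),
                color=colors[color_key(e)],
                alpha=0.75,
                edgecolors="none",
                label=color_key(e),
            )
        ax.set_title(panel)
        ax.set_xlabel("Risk allele frequency")
        ax.set_ylabel("Odds ratio")
        ax.set_xlim(0, 1)
        if spec.log_or_axis:
            ax.set_yscale("log")
        handles, labels = ax.get_legend_handles_labels()
        uniq = dict(zip(labels, handles))
        ax.legend(uniq.values(), uniq.keys(), fontsize=7, loc="best")

    fig.tight_layout()
    fig.savefig(path, format=spec.fmt, metadata={"Date": None} if spec.fmt == "svg" else None)
    plt.close(fig)
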
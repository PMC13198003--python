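"""Static visual outputs: coreness maps, heterogeneity map, persistence diagram."""

from __future__ import annotations

import math

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .domains import MultiscaleDomain
from .io import SpotSet

__all__ = [
    "plot_coreness_map",
    "plot_heterogeneity_map",
    "plot_persistence_diagram",
]


def _spatial_scatter(values, spots: SpotSet, title, vmin=None, vmax=None, path=None):
    fig, ax = plt.subplots(figsize=(5, 5))
    sc = ax.scatter(
        spots.coords[:, 0],
        spots.coords[:, 1],
        c=values,
        s=9,
        cmap="viridis",
        vmin=vmin,
        vmax=vmax,
    )
    ax.set_aspect("equal")
    ax.set_title(title)
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    fig.colorbar(sc, ax=ax, shrink=0.8)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig


def plot_coreness_map(domain: MultiscaleDomain, spots: SpotSet, path=None):
    """Normalized coreness as a scalar field on the tissue (fixed [0, 1] scale)."""
    return _spatial_scatter(
        domain.normalized_coreness,
        spots,
        f"domain {domain.id} (lifetime {domain.lifetime:.3f})",
        vmin=0.0,
        vmax=1.0,
        path=path,
    )


def plot_heterogeneity_map(h: np.ndarray, spots: SpotSet, path=None):
    """Heterogeneity score as a scalar field on the tissue."""
    return _spatial_scatter(h, spots, "heterogeneity", path=path)


def plot_persistence_diagram(diagram, path=None):
    """Death vs birth; immortal components are drawn at the top margin."""
    finite = [p for p in diagram if math.isfinite(p.death)]
    immortal = [p for p in diagram if math.isinf(p.death)]
    top = 1.05
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    if finite:
        ax.scatter(
            [p.birth for p in finite], [p.death for p in finite],
            s=18, label="finite",
        )
    if immortal:
        ax.scatter(
            [p.birth for p in immortal], [top] * len(immortal),
            s=28, marker="^", color="firebrick", label="immortal",
        )
    ax.plot([0, top], [0, top], lw=0.8, color="grey")
    ax.axhline(top, lw=0.6, ls="--", color="firebrick")
    ax.set_xlim(-0.02, top + 0.02)
    ax.set_ylim(-0.02, top + 0.05)
    ax.set_xlabel("birth")
    ax.set_ylabel("death")
    ax.set_title("persistence diagram")
    ax.legend(loc="lower right", fontsize=8)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig
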
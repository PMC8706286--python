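"""Optional figure rendering (cosmetic; nothing downstream depends on it)."""

from __future__ import annotations

import os
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from scipy.cluster import hierarchy

from .core import CONDITIONS, SpeciesFingerprint
from .fusion import DensityMap, FusedPointSet, Heatmap
from .phylo import Dendrogram


def plot_fingerprints(fingerprints: Sequence[SpeciesFingerprint], path: str | os.PathLike) -> None:
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, cond in zip(axes, CONDITIONS):
        for fp in fingerprints:
            ax.plot(fp.grid.potentials, fp.traces[cond], lw=0.6, alpha=0.7)
        ax.set_title(cond)
        ax.set_xlabel("potential (V)")
    axes[0].set_ylabel("normalized current")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_fused(points: FusedPointSet, path: str | os.PathLike) -> None:
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(points.points[:, 0], points.points[:, 1], s=4, alpha=0.6)
    ax.set_xlim(0, 1); ax.set_ylim(0, 1)
    ax.set_xlabel("water/PBS"); ax.set_ylabel("ethanol/ABS")
    ax.set_title(points.species_id)
    fig.tight_layout(); fig.savefig(path, dpi=120); plt.close(fig)


def plot_map(source: DensityMap | Heatmap, path: str | os.PathLike) -> None:
    values = source.values if isinstance(source, DensityMap) else source.counts
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(values.T, origin="lower", extent=(0, 1, 0, 1), cmap="inferno")
    ax.set_title(source.species_id)
    fig.tight_layout(); fig.savefig(path, dpi=120); plt.close(fig)


def plot_dendrogram(dendrogram: Dendrogram, path: str | os.PathLike) -> None:
    fig, ax = plt.subplots(figsize=(6, 0.22 * dendrogram.n_leaves + 1))
    hierarchy.dendrogram(
        dendrogram.to_linkage(), labels=dendrogram.labels, orientation="left", ax=ax
    )
    ax.set_xlabel("distance")
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)
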
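"""On-disk formats: long-format CSV panels, fingerprint tables, Newick trees.

The panel schema — ``species_id, condition, replicate, potential_V,
current`` — is deliberately instrument-agnostic: exports from real
potentiostats can be massaged into it with one melt.  Potentials are
written with 4 decimals (the canonical 0.004 V step is exact at that
precision); currents keep full double precision so round-trips are
lossless.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .core import CONDITIONS, PotentialGrid, SpeciesFingerprint, Voltammogram
from .errors import FormatError

PANEL_COLUMNS = ["species_id", "condition", "replicate", "potential_V", "current"]


def panel_to_frame(panel: Iterable[Voltammogram]) -> pd.DataFrame:
    """Flatten voltammograms into the long-format panel table."""
    frames = []
    for v in panel:
        frames.append(
            pd.DataFrame(
                {
                    "species_id": v.species_id,
                    "condition": v.condition,
                    "replicate": v.replicate,
                    "potential_V": np.round(v.grid.potentials, 4),
                    "current": v.current,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_panel(panel: Iterable[Voltammogram], path: str | os.PathLike) -> None:
    panel_to_frame(panel).to_csv(path, index=False)


def _grid_from_potentials(potentials: np.ndarray, where: str) -> PotentialGrid:
    steps = np.diff(potentials)
    if len(steps) == 0 or np.any(steps <= 0):
        raise FormatError(f"non-monotone potentials in {where}")
    step = float(steps.mean())
    if np.any(np.abs(steps - step) > 1e-6):
        raise FormatError(f"non-uniform potential spacing in {where}")
    return PotentialGrid(float(potentials[0]), float(potentials[-1]), step)


def read_panel(path: str | os.PathLike) -> list[Voltammogram]:
    """Read a long-format panel CSV back into voltammograms.

    Validates the closed condition vocabulary, per-trace monotone
    potentials, and that all traces share one grid.
    """
    df = pd.read_csv(path)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"panel file missing column(s) {missing}")
    bad = df.loc[~df["condition"].isin(CONDITIONS)]
    if not bad.empty:
        row = int(bad.index[0]) + 2  # 1-based, after header
        raise FormatError(
            f"unknown condition {bad['condition'].iloc[0]!r} at line {row}; "
            f"expected one of {CONDITIONS}"
        )
    panel: list[Voltammogram] = []
    grid: PotentialGrid | None = None
    for (species, cond, rep), sub in df.groupby(
        ["species_id", "condition", "replicate"], sort=False
    ):
        where = f"trace ({species}, {cond}, replicate {rep})"
        potentials = sub["potential_V"].to_numpy(dtype=float)
        this_grid = _grid_from_potentials(potentials, where)
        if grid is None:
            grid = this_grid
        elif this_grid != grid and not np.allclose(
            this_grid.potentials, grid.potentials, atol=1e-9
        ):
            raise FormatError(f"{where} is not on the shared potential grid")
        panel.append(
            Voltammogram(str(species), str(cond), int(rep), grid, sub["current"].to_numpy(dtype=float))
        )
    if not panel:
        raise FormatError("panel file contains no traces")
    return panel


def write_fingerprints(
    fingerprints: Sequence[SpeciesFingerprint], path: str | os.PathLike
) -> None:
    frames = []
    for fp in fingerprints:
        for cond in CONDITIONS:
            frames.append(
                pd.DataFrame(
                    {
                        "species_id": fp.species_id,
                        "condition": cond,
                        "potential_V": np.round(fp.grid.potentials, 4),
                        "normalized_current": np.asarray(fp.traces[cond]),
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_tree(tree: dendropy.Tree, path: str | os.PathLike) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_tree(path: str | os.PathLike) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_matrix(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path)


def write_labels(labels: dict[str, int], path: str | os.PathLike) -> None:
    pd.Series(labels, name="cluster").rename_axis("species_id").to_csv(path)
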
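"""Trace preprocessing: resampling, normalization, replicate averaging.

The fixed pipeline order is: resample each replicate onto the canonical
grid → normalize each replicate → average replicates pointwise →
re-normalize the mean.  Averaging normalized replicates (rather than
normalizing a raw average) keeps a single replicate's amplitude jitter
from dominating the fused representation downstream.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np

from .core import CANONICAL_GRID, CONDITIONS, PotentialGrid, SpeciesFingerprint, Voltammogram
from .errors import CoverageError, DegenerateInputError, InvalidArgumentError


def resample_to_grid(trace: Voltammogram, grid: PotentialGrid = CANONICAL_GRID) -> Voltammogram:
    """Linearly interpolate a trace onto ``grid``.

    The source trace must cover the full target window; values are never
    extrapolated.
    """
    src = trace.grid
    if src.start > grid.start + 1e-12 or src.stop < grid.stop - 1e-12:
        raise CoverageError(
            f"trace spans [{src.start}, {src.stop}] V but grid requires "
            f"[{grid.start}, {grid.stop}] V"
        )
    if src == grid:
        return Voltammogram(
            trace.species_id, trace.condition, trace.replicate, grid, trace.current.copy()
        )
    current = np.interp(grid.potentials, src.potentials, trace.current)
    return Voltammogram(trace.species_id, trace.condition, trace.replicate, grid, current)


def minmax_normalize(trace: Voltammogram) -> Voltammogram:
    """Map the current affinely onto [0, 1] (min → 0, max → 1)."""
    return Voltammogram(
        trace.species_id,
        trace.condition,
        trace.replicate,
        trace.grid,
        _minmax(trace.current),
    )


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        raise DegenerateInputError("constant trace cannot be min-max normalized")
    return (x - lo) / (hi - lo)


def area_normalize(trace: Voltammogram) -> Voltammogram:
    """Alternative normalization: unit area under the curve (trapezoid)."""
    area = float(np.trapezoid(trace.current, trace.grid.potentials))
    if area == 0.0:
        raise DegenerateInputError("zero-area trace cannot be area normalized")
    return Voltammogram(
        trace.species_id, trace.condition, trace.replicate, trace.grid, trace.current / area
    )


_NORMALIZERS = {"minmax": minmax_normalize, "area": area_normalize}


def normalize(trace: Voltammogram, mode: str = "minmax") -> Voltammogram:
    try:
        return _NORMALIZERS[mode](trace)
    except KeyError:
        raise InvalidArgumentError(
            f"unknown normalization {mode!r}; expected one of {sorted(_NORMALIZERS)}"
        ) from None


def average_replicates(traces: Sequence[Voltammogram]) -> tuple[np.ndarray, float]:
    """Average already-normalized replicates and re-normalize.

    Returns ``(mean_trace, consistency)`` where consistency is the maximum
    pointwise sample standard deviation across replicates before
    re-normalization.
    """
    if len(traces) == 0:
        raise InvalidArgumentError("need at least one replicate")
    first = traces[0]
    for t in traces[1:]:
        if (
            t.species_id != first.species_id
            or t.condition != first.condition
            or t.grid != first.grid
        ):
            raise InvalidArgumentError(
                "replicates must share species, condition and potential grid"
            )
    stack = np.stack([t.current for t in traces])
    mean = stack.mean(axis=0)
    if len(traces) > 1:
        # center on the first replicate so identical replicates give an
        # exact zero rather than rounding noise
        consistency = float((stack - stack[0]).std(axis=0, ddof=1).max())
    else:
        consistency = 0.0
    return _minmax(mean), consistency


def fingerprint_from_replicates(
    traces: Iterable[Voltammogram],
    grid: PotentialGrid = CANONICAL_GRID,
    normalization: str = "minmax",
) -> SpeciesFingerprint:
    """Run the full per-species pipeline over replicates of both conditions."""
    traces = list(traces)
    if not traces:
        raise InvalidArgumentError("no traces supplied")
    species = traces[0].species_id
    by_condition: dict[str, list[Voltammogram]] = defaultdict(list)
    for t in traces:
        if t.species_id != species:
            raise InvalidArgumentError("all traces must belong to one species")
        by_condition[t.condition].append(t)
    missing = [c for c in CONDITIONS if c not in by_condition]
    if missing:
        raise InvalidArgumentError(f"species {species!r} missing condition(s): {missing}")
    mean_traces: dict[str, np.ndarray] = {}
    consistency: dict[str, float] = {}
    for cond, reps in by_condition.items():
        prepared = [normalize(resample_to_grid(t, grid), normalization) for t in reps]
        mean_traces[cond], consistency[cond] = average_replicates(prepared)
    return SpeciesFingerprint(species, grid, mean_traces, consistency)


def build_fingerprints(
    panel: Iterable[Voltammogram],
    grid: PotentialGrid = CANONICAL_GRID,
    normalization: str = "minmax",
) -> list[SpeciesFingerprint]:
    """Group a panel of traces by species and build one fingerprint each.

    Species order follows first appearance in the panel.
    """
    by_species: dict[str, list[Voltammogram]] = defaultdict(list)
    for t in panel:
        by_species[t.species_id].append(t)
    return [
        fingerprint_from_replicates(traces, grid, normalization)
        for traces in by_species.values()
    ]
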
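"""Shared containers for voltammetric fingerprint data.

A differential-pulse voltammogram (DPV) is a current-versus-potential
trace recorded over a fixed potential window.  Fingerprints here are
*multidimensional*: every specimen is measured under two extraction /
electrolyte conditions — an aqueous extract in phosphate buffer at
pH 7.0 and an ethanolic extract in acetate buffer at pH 4.5 — which
capture partly disjoint sets of electroactive compounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import InvalidArgumentError

#: The closed vocabulary of measurement conditions: solvent_electrolyte.
CONDITIONS: tuple[str, str] = ("water_PBS", "ethanol_ABS")


@dataclass(frozen=True)
class PotentialGrid:
    """Uniform potential grid in volts.

    The canonical grid spans the DPV window 0–1.3 V at a 0.004 V step
    (326 points).
    """

    start: float = 0.0
    stop: float = 1.3
    step: float = 0.004

    def __post_init__(self) -> None:
        if not (np.isfinite(self.start) and np.isfinite(self.stop) and np.isfinite(self.step)):
            raise InvalidArgumentError("grid parameters must be finite")
        if self.step <= 0 or self.stop <= self.start:
            raise InvalidArgumentError("grid must be strictly increasing")

    @property
    def n_points(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    @property
    def potentials(self) -> np.ndarray:
        """Grid potentials in volts, endpoints included."""
        return np.linspace(self.start, self.stop, self.n_points)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_points


#: Default 0–1.3 V window, 0.004 V step.
CANONICAL_GRID = PotentialGrid()


@dataclass
class Voltammogram:
    """One current trace for a (species, condition, replicate) triple."""

    species_id: str
    condition: str
    replicate: int
    grid: PotentialGrid
    current: np.ndarray

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise InvalidArgumentError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        self.current = np.asarray(self.current, dtype=float)
        if self.current.ndim != 1 or len(self.current) != self.grid.n_points:
            raise InvalidArgumentError(
                f"current length {len(self.current)} does not match grid "
                f"({self.grid.n_points} points)"
            )
        if not np.all(np.isfinite(self.current)):
            raise InvalidArgumentError("current must be finite everywhere")


@dataclass
class SpeciesFingerprint:
    """Replicate-averaged, min–max-normalized trace per condition.

    ``replicate_consistency`` holds, per condition, the maximum pointwise
    standard deviation across replicates before re-normalization — a QC
    measure of how reproducible the recordings were.
    """

    species_id: str
    grid: PotentialGrid
    traces: Mapping[str, np.ndarray]
    replicate_consistency: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CONDITIONS if c not in self.traces]
        if missing:
            raise InvalidArgumentError(f"fingerprint missing condition(s): {missing}")
        for cond, trace in self.traces.items():
            arr = np.asarray(trace, dtype=float)
            if len(arr) != self.grid.n_points:
                raise InvalidArgumentError(
                    f"trace for {cond} has {len(arr)} points, grid has {self.grid.n_points}"
                )
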
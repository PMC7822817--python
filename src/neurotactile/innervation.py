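"""Random weighted receptive fields connecting taxels to afferents.

Mimicking the branching of first-order tactile neurons in the skin, each
digital afferent innervates a handful of spatially nearby taxels with random
weights, forming overlapping receptive fields.  An afferent's scalar drive
for one frame is the weighted sum of its taxels' ADC counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .stimuli import GridSpec, TaxelFrame

__all__ = [
    "ReceptiveField",
    "InnervationMap",
    "CoverageStats",
    "build_innervation",
    "afferent_drive",
    "coverage_stats",
]

#: Weights are uniform on (WEIGHT_LOW, 1]; the floor keeps every connection
#: non-negligible.  Weights are not normalized per field, so drive (and
#: firing rate) grows with receptive-field size.
WEIGHT_LOW = 0.25


@dataclass(frozen=True)
class ReceptiveField:
    """Per-afferent 5x5 weight matrix; positive entries are innervated taxels."""

    afferent_kind: str  # "SA1" | "RA1"
    weights: np.ndarray  # (rows, cols) non-negative
    center: tuple[int, int]

    @property
    def n_taxels(self) -> int:
        return int((self.weights > 0).sum())


@dataclass(frozen=True)
class InnervationMap:
    fields: tuple[ReceptiveField, ...]
    n_sa: int
    n_ra: int
    mean_taxels: float
    seed: int

    def weight_stack(self) -> np.ndarray:
        """(n_fields, rows, cols) array of weights, SA fields first."""
        return np.stack([f.weights for f in self.fields])

    @property
    def sa_fields(self) -> tuple[ReceptiveField, ...]:
        return self.fields[: self.n_sa]

    @property
    def ra_fields(self) -> tuple[ReceptiveField, ...]:
        return self.fields[self.n_sa :]


def _neighborhood(center: tuple[int, int], radius: int, grid: GridSpec) -> np.ndarray:
    """(k, 2) taxel indices within Chebyshev *radius* of *center*, on-grid."""
    r0, c0 = center
    rows = np.arange(max(0, r0 - radius), min(grid.rows, r0 + radius + 1))
    cols = np.arange(max(0, c0 - radius), min(grid.cols, c0 + radius + 1))
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()])


def build_innervation(
    n_sa: int = 6,
    n_ra: int = 12,
    mean_taxels: float = 3.0,
    grid: GridSpec | None = None,
    seed: int = 0,
    neighborhood_radius: int | None = None,
) -> InnervationMap:
    """Draw random overlapping receptive fields for ``n_sa + n_ra`` afferents.

    Each afferent places its center uniformly on the grid and innervates
    ``1 + Poisson(mean_taxels - 1)`` taxels (shifted Poisson: mean exactly
    ``mean_taxels``, never zero, capped at the neighborhood size) sampled
    without replacement from the center's spatial neighborhood (Chebyshev
    radius 1, widening to 2 for means above nine taxels, unless
    ``neighborhood_radius`` overrides).  Weights are i.i.d. uniform on
    (0.25, 1].  Deterministic under *seed*; fields of different afferents
    may overlap.
    """
    grid = grid or GridSpec()
    if mean_taxels < 1:
        raise ValueError("mean_taxels must be >= 1")
    if mean_taxels > grid.n_taxels:
        raise ValueError("mean_taxels cannot exceed the taxel count")
    if neighborhood_radius is not None:
        radius = neighborhood_radius
    else:
        radius = 1 if mean_taxels <= 9 else 2
    rng = np.random.default_rng(seed)
    kinds = ["SA1"] * n_sa + ["RA1"] * n_ra
    fields = []
    for kind in kinds:
        center = (int(rng.integers(grid.rows)), int(rng.integers(grid.cols)))
        nbhd = _neighborhood(center, radius, grid)
        n_t = min(1 + int(rng.poisson(mean_taxels - 1)), len(nbhd))
        chosen = rng.choice(len(nbhd), size=n_t, replace=False)
        weights = np.zeros((grid.rows, grid.cols))
        # uniform on (WEIGHT_LOW, 1]: 1 - U[0, 1-WEIGHT_LOW)
        w = 1.0 - rng.uniform(0.0, 1.0 - WEIGHT_LOW, size=n_t)
        for (r, c), wi in zip(nbhd[chosen], w):
            weights[r, c] = wi
        fields.append(ReceptiveField(afferent_kind=kind, weights=weights, center=center))
    return InnervationMap(
        fields=tuple(fields), n_sa=n_sa, n_ra=n_ra, mean_taxels=mean_taxels, seed=seed
    )


def afferent_drive(field: ReceptiveField, frame: TaxelFrame | np.ndarray) -> float:
    """Weighted sum of taxel counts: the afferent's input for one frame."""
    values = frame.values if isinstance(frame, TaxelFrame) else np.asarray(frame)
    if values.shape != field.weights.shape:
        raise ValueError(
            f"frame shape {values.shape} does not match field shape {field.weights.shape}"
        )
    return float(np.sum(field.weights * values))


@dataclass(frozen=True)
class CoverageStats:
    unused_taxel_count: int
    mean_overlap: float


def coverage_stats(imap: InnervationMap, grid: GridSpec | None = None) -> CoverageStats:
    """How well the receptive fields tile the array.

    ``unused_taxel_count`` counts taxels no field innervates; ``mean_overlap``
    is the mean number of fields per taxel.  Larger mean field sizes leave
    fewer taxels unused.
    """
    grid = grid or GridSpec()
    stack = imap.weight_stack() > 0
    per_taxel = stack.sum(axis=0)
    return CoverageStats(
        unused_taxel_count=int((per_taxel == 0).sum()),
        mean_overlap=float(per_taxel.mean()),
    )
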
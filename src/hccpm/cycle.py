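"""Cell-cycle expression profiles on a common 100-point grid.

Profiles are Cyclebase-style log2 ratios (synchronous over asynchronous
culture) sampled at arbitrary points of the division cycle, expressed in
percent with 100% corresponding to cytokinesis.  To compare genes measured
on different time scales, every profile is resampled by linear interpolation
onto the integer grid 0..99.  Because the cycle is periodic (100% = 0%),
interpolation wraps around between the last and first raw point by default.

Two genes are considered co-expressed when both log2 ratios exceed a
threshold (default 0, i.e. enrichment over the asynchronous baseline) at at
least one shared grid point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

GRID_SIZE = 100
GRID = np.arange(GRID_SIZE, dtype=float)


def normalize_profile(
    raw_points: Sequence[tuple[float, float]], cyclic: bool = True
) -> np.ndarray:
    """Resample raw (time_percent, log2_ratio) points onto the 0..99 grid.

    Linear interpolation between consecutive points; with ``cyclic`` (the
    default) the segment from the last point back to the first wraps through
    100% = 0%.  Without it, values are held flat beyond the raw extremes.
    """
    if len(raw_points) < 2:
        raise ValueError("need at least 2 raw points to interpolate")
    pts = sorted(raw_points)
    times = np.array([t for t, _ in pts], dtype=float)
    values = np.array([v for _, v in pts], dtype=float)
    if np.any(times < 0) or np.any(times >= 100):
        raise ValueError("time points must lie in [0, 100)")
    if np.any(np.diff(times) == 0):
        raise ValueError("duplicate time points")
    if cyclic:
        xp = np.concatenate(([times[-1] - 100.0], times, [times[0] + 100.0]))
        fp = np.concatenate(([values[-1]], values, [values[0]]))
    else:
        xp, fp = times, values
    return np.interp(GRID, xp, fp)


@dataclass
class CycleProfile:
    """One gene's cycle profile: raw measurements plus the resampled grid."""

    accession: str
    raw_points: list[tuple[float, float]]
    grid: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    cyclic: bool = True

    def __post_init__(self) -> None:
        self.raw_points = sorted((float(t), float(v)) for t, v in self.raw_points)
        if self.grid is None:
            self.grid = normalize_profile(self.raw_points, cyclic=self.cyclic)

    @classmethod
    def from_points(
        cls, accession: str, points: Sequence[tuple[float, float]],
        cyclic: bool = True,
    ) -> "CycleProfile":
        return cls(accession=accession, raw_points=list(points), cyclic=cyclic)


def coexpressed(
    a: CycleProfile, b: CycleProfile, threshold: float = 0.0
) -> bool:
    """True iff both profiles exceed ``threshold`` at a shared grid point."""
    return bool(np.any((a.grid > threshold) & (b.grid > threshold)))
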
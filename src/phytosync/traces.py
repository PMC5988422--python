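"""Core container for a single cell's expression time series.

All times are hours since release into constant light (LL); positions are in
millimetres with ``y`` measured along the longitudinal axis from the root tip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CellTrace"]


@dataclass
class CellTrace:
    """One cell's sampled intensity series plus 3D position and section label.

    Parameters
    ----------
    cell_id
        Unique identifier within a trace set.
    position
        ``(x, y, z)`` in mm; ``y`` measured from the root tip.
    section
        Imaged-section label, e.g. ``"root_tip"`` or ``"upper_hypocotyl"``.
    times
        Strictly increasing sample times in hours of constant light.
    values
        Intensities (arbitrary units), same length as ``times``.
    """

    cell_id: str
    position: tuple[float, float, float]
    section: str
    times: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.shape != self.times.shape:
            raise ValueError(
                f"cell {self.cell_id}: times and values must be 1-D and equal length"
            )
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError(f"cell {self.cell_id}: times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"cell {self.cell_id}: non-finite intensity values")

    @property
    def n_samples(self) -> int:
        return self.times.size

    @property
    def span(self) -> float:
        """Recording span in hours."""
        return float(self.times[-1] - self.times[0])

    @property
    def sampling_interval(self) -> float:
        """Median sampling interval in hours."""
        return float(np.median(np.diff(self.times)))

    def with_values(self, values: np.ndarray, times: np.ndarray | None = None) -> "CellTrace":
        """Copy of this trace with new values (and optionally a new time grid)."""
        return CellTrace(
            cell_id=self.cell_id,
            position=self.position,
            section=self.section,
            times=self.times.copy() if times is None else np.asarray(times, float),
            values=np.asarray(values, float),
        )
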
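"""2-D seedling phase-oscillator model and space-time plots.

Each occupied grid cell (m horizontal, n vertical; n = 0 at the root tip)
carries a Kuramoto phase oscillator

    d(theta_mn)/dt = omega_mn + K * sum_<pq> sin(theta_pq - theta_mn)

with the sum over the Moore neighbourhood (the 8 surrounding cells) restricted
to occupied positions — no wraparound and no normalisation by neighbour
count.  Intrinsic periods are section-specific: by default 24 h in the shoot
(cotyledon/hypocotyl), 25.55 h in the root and 22.67 h in the root tip.
Simulated bioluminescence is ``B = cos(theta) + 1``; summing B across each
row and normalising each row to its own maximum yields the space-time plot,
in which the shoot-downward and tip-upward expression waves meet mid-root as
a "bow wave".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SeedlingTemplate",
    "PhaseField",
    "SpaceTimeMatrix",
    "DEFAULT_PERIODS",
    "build_template",
    "simulate_field",
    "bioluminescence",
    "spacetime_from_field",
    "peak_time_table",
    "peak_time_plot",
]

TWO_PI = 2.0 * math.pi
DEFAULT_PERIODS = {"shoot": 24.0, "root": 25.55, "root_tip": 22.67}


@dataclass
class SeedlingTemplate:
    """Occupancy mask plus per-row section identity and intrinsic periods.

    ``mask[n, m]`` is True for occupied cells; row n = 0 is the root tip.
    The mask is symmetric about the vertical midline.
    """

    mask: np.ndarray
    section_of_row: np.ndarray  # length n_rows array of section names
    periods: dict[str, float]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, bool)
        if self.mask.ndim != 2 or not self.mask.any():
            raise ValueError("mask must be a non-empty 2-D occupancy grid")
        if not np.array_equal(self.mask, self.mask[:, ::-1]):
            raise ValueError("template mask must be symmetric about the midline")
        if len(self.section_of_row) != self.mask.shape[0]:
            raise ValueError("one section label per row required")
        for n, name in enumerate(self.section_of_row):
            if self.mask[n].any() and name not in self.periods:
                raise ValueError(f"occupied row {n} has no assigned section period")
        for s, p in self.periods.items():
            if p <= 0:
                raise ValueError(f"section {s!r}: period must be > 0")

    @property
    def n_rows(self) -> int:
        return self.mask.shape[0]

    @property
    def width_of_row(self) -> np.ndarray:
        """Occupied-cell count per row (Nw)."""
        return self.mask.sum(axis=1)

    def omega_grid(self) -> np.ndarray:
        """Intrinsic angular frequency per grid cell (NaN off-template)."""
        omega = np.full(self.mask.shape, np.nan)
        for n in range(self.n_rows):
            if self.mask[n].any():
                omega[n, self.mask[n]] = TWO_PI / self.periods[self.section_of_row[n]]
        return omega


def build_template(
    n_rows: int = 60,
    root_width: int = 4,
    shoot_width: int = 10,
    root_tip_rows: int = 6,
    shoot_rows: int = 14,
    periods: dict[str, float] | None = None,
) -> SeedlingTemplate:
    """Default symmetric seedling: narrow root flaring into a wider shoot.

    Rows 0..root_tip_rows-1 are root tip, the top ``shoot_rows`` rows are
    shoot (hypocotyl/cotyledon), everything between is root.
    """
    if root_tip_rows + shoot_rows > n_rows:
        raise ValueError("section boundaries do not partition the rows")
    periods = dict(DEFAULT_PERIODS if periods is None else periods)
    width = max(root_width, shoot_width)
    mask = np.zeros((n_rows, width), dtype=bool)
    sections = []
    for n in range(n_rows):
        if n < root_tip_rows:
            sec, w = "root_tip", root_width
        elif n >= n_rows - shoot_rows:
            sec, w = "shoot", shoot_width
        else:
            sec, w = "root", root_width
        lo = (width - w) // 2
        if (width - w) % 2:
            raise ValueError("row widths must share the parity of the grid width")
        mask[n, lo : lo + w] = True
        sections.append(sec)
    return SeedlingTemplate(mask, np.array(sections), periods)


@dataclass
class PhaseField:
    """Simulated phases on the template grid.

    ``theta`` has shape (T, n_rows, n_cols) with NaN off-template.
    """

    template: SeedlingTemplate
    times: np.ndarray
    theta: np.ndarray = field(repr=False)
    K: float = 1.0
    dt: float = 0.05


def simulate_field(
    template: SeedlingTemplate,
    K: float = 1.0,
    dt: float = 0.05,
    t_end: float = 200.0,
    initial_phases: np.ndarray | None = None,
    rng_seed: int | None = None,
    store_every: int = 1,
) -> PhaseField:
    """Euler-integrate the template model.

    ``initial_phases`` is a full-grid array (values off-template ignored);
    default is all-zero (release from entrainment).  Pass ``rng_seed`` for
    uniform-random initial phases instead.  ``store_every`` thins the stored
    trajectory to every k-th Euler step.
    """
    mask = template.mask
    omega = np.nan_to_num(template.omega_grid())
    if initial_phases is None:
        if rng_seed is not None:
            theta = np.random.default_rng(rng_seed).uniform(0, TWO_PI, mask.shape)
        else:
            theta = np.zeros(mask.shape)
    else:
        theta = np.asarray(initial_phases, float).copy()
    theta = np.where(mask, theta, 0.0)

    n_steps = int(round(t_end / dt))
    kept = range(0, n_steps + 1, store_every)
    out = np.full((len(kept), *mask.shape), np.nan)
    times = np.empty(len(kept))
    k_out = 0
    for step in range(n_steps + 1):
        if step % store_every == 0:
            out[k_out][mask] = theta[mask]
            times[k_out] = step * dt
            k_out += 1
        if step == n_steps:
            break
        # Moore-neighbourhood coupling: sum of sin(theta_nbr - theta) over the
        # 8 occupied neighbours, off-template positions simply omitted.
        s, c = np.sin(theta) * mask, np.cos(theta) * mask
        ssum = _moore_sum(s)
        csum = _moore_sum(c)
        # sum sin(th_nbr - th) = cos(th)*sum sin(th_nbr) - sin(th)*sum cos(th_nbr)
        coupling = np.cos(theta) * ssum - np.sin(theta) * csum
        theta = theta + (omega + K * coupling) * dt
        theta = np.where(mask, theta, 0.0)
    return PhaseField(template, times, out, K=K, dt=dt)


def _moore_sum(a: np.ndarray) -> np.ndarray:
    """Sum of the 8 neighbours of each cell (zero padding at the border)."""
    p = np.pad(a, 1)
    return (
        p[:-2, :-2] + p[:-2, 1:-1] + p[:-2, 2:]
        + p[1:-1, :-2] + p[1:-1, 2:]
        + p[2:, :-2] + p[2:, 1:-1] + p[2:, 2:]
    )


def bioluminescence(field: PhaseField) -> np.ndarray:
    """Per-cell signal B = cos(theta) + 1, in [0, 2] (NaN off-template)."""
    return np.cos(field.theta) + 1.0


@dataclass
class SpaceTimeMatrix:
    """Per-row signal vs time, each row normalised to its own peak (max = 1)."""

    rows: np.ndarray  # row indices (longitudinal sections) retained
    times: np.ndarray
    values: np.ndarray  # (n_rows_kept, T)

    def peak_time_by_row(self) -> np.ndarray:
        """Time of the global maximum of each row."""
        return self.times[np.argmax(self.values, axis=1)]

    def first_peak_time_by_row(
        self, min_separation: float = 12.0, after: float = 0.0
    ) -> np.ndarray:
        """Time of each row's first local maximum at or after ``after``
        (NaN when none found).

        After amplitude de-trending all cycles have comparable height, so an
        early-cycle peak — not the global argmax — carries the wave timing.
        Pass ``after=period`` to skip the first cycle, whose peaks are
        distorted by zero-phase-filter edge transients.
        """
        from scipy.signal import find_peaks

        dt = float(np.median(np.diff(self.times))) if self.times.size > 1 else 1.0
        dist = max(1, int(round(min_separation / dt)))
        out = np.full(self.values.shape[0], np.nan)
        for i, row in enumerate(self.values):
            pk, _ = find_peaks(row, distance=dist)
            pk = pk[self.times[pk] >= after]
            if pk.size:
                out[i] = self.times[pk[0]]
        return out


def spacetime_from_field(field: PhaseField) -> SpaceTimeMatrix:
    """Total bioluminescence per row, peak-normalised row-wise.

    Rows with no occupied cells (all-zero signal) are excluded.
    """
    B = bioluminescence(field)
    total = np.nansum(B, axis=2)  # (T, n_rows)
    keep = field.template.mask.any(axis=1) & (np.nanmax(total, axis=0) > 0)
    vals = total[:, keep].T
    vals = vals / vals.max(axis=1, keepdims=True)
    return SpaceTimeMatrix(
        rows=np.flatnonzero(keep),
        times=field.times.copy(),
        values=vals,
    )


def peak_time_table(results, window: tuple[float, float] = (48.0, 72.0)):
    """Table of (cell, section, y position, earliest in-window peak time).

    ``results`` are rhythm results carrying positions and peak times; cells
    without an in-window peak are omitted.  Returns a pandas DataFrame.
    """
    import pandas as pd

    lo, hi = window
    rows = []
    for r in results:
        if not getattr(r, "rhythmic", True) or len(r.peak_times) == 0:
            continue
        in_win = np.asarray(r.peak_times)[
            (np.asarray(r.peak_times) >= lo) & (np.asarray(r.peak_times) <= hi)
        ]
        if in_win.size:
            rows.append(
                {
                    "cell_id": r.cell_id,
                    "section": r.section,
                    "y_mm": r.position[1],
                    "peak_time_h": float(in_win[0]),
                }
            )
    if not rows:
        raise ValueError("no rhythmic cells with in-window peaks")
    return pd.DataFrame(rows)


def peak_time_plot(results, window=(48.0, 72.0), ax=None):
    """Scatter of peak time vs longitudinal position with per-section means."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    table = peak_time_table(results, window)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for sec, grp in table.groupby("section"):
        ax.scatter(grp["peak_time_h"], grp["y_mm"], s=8, label=sec, alpha=0.6)
        ax.axvline(grp["peak_time_h"].mean(), lw=0.8, ls="--", color="grey")
    ax.set_xlabel("peak time (h in LL)")
    ax.set_ylabel("longitudinal position from root tip (mm)")
    ax.legend(fontsize=7)
    return table, ax
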
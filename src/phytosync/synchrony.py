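"""Synchrony analysis: phase extraction, Kuramoto order parameter,
synchronisation index, neighbourhood curves and coupling-strength estimation.

Phase convention: between consecutive detected peaks ``t_k`` and ``t_k+1`` a
cell's phase grows linearly,

    theta_j(t) = 2*pi*k + (t - t_k) / (t_{k+1} - t_k) * 2*pi,

so ``theta = 2*pi*k`` exactly at the k-th peak.  The arbitrary k-offset per
cell is immaterial downstream because the order parameter uses theta modulo
2*pi.

Coupling strength is estimated by simulating the all-to-all Kuramoto model

    d(theta_j)/dt = omega_j + (K/N) * sum_k sin(theta_k - theta_j)

(Euler, dt = 0.1 h) with frequencies ``omega_j = 2*pi/tau_j`` and initial
phases taken from the data, slowly increasing K from 0.002 on a geometric
schedule until the simulated order-parameter slope reaches the observed one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .traces import CellTrace

__all__ = [
    "PhaseSeries",
    "SyncCurve",
    "CouplingEstimate",
    "extract_phase",
    "order_parameter",
    "sync_index",
    "neighbourhood_curve",
    "simulate_kuramoto",
    "estimate_coupling",
]

TWO_PI = 2.0 * math.pi


@dataclass
class PhaseSeries:
    """Unwrapped phase of one cell, anchored at its detected peaks."""

    cell_id: str
    times: np.ndarray
    theta: np.ndarray
    period_tau: float
    fit_r2: float
    peak_times: np.ndarray

    def theta_at(self, t: np.ndarray) -> np.ndarray:
        return np.interp(t, self.times, self.theta)


@dataclass
class SyncCurve:
    """Order parameter (or sync index) vs time for one spherical neighbourhood."""

    centroid_cell_id: str
    radius_r: float
    n_neighbours: int
    density_rho: float  # cells / mm^3, N / ((4/3) pi r^3)
    times: np.ndarray
    R: np.ndarray
    slope: float  # 1/h, OLS slope of R on t
    measure: str  # "order_parameter" | "sync_index"


@dataclass
class CouplingEstimate:
    centroid_cell_id: str
    K_hat: float
    K_init: float
    slope_obs: float
    slope_sim_at_K_hat: float


# ---------------------------------------------------------------------------
# phase extraction
# ---------------------------------------------------------------------------


def _fit_cosine_window(t, y, tau):
    """LS fit of a*cos(w t)+b*sin(w t)+c on one window.

    Returns (r2, amplitude, peak_phase_time_offset) where the fitted signal
    peaks at times satisfying w*t = atan2(b, a) (mod 2*pi).
    """
    w = TWO_PI / tau
    X = np.stack([np.cos(w * t), np.sin(w * t), np.ones_like(t)], axis=1)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fit = X @ beta
    ss_res = float(np.sum((y - fit) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    phi = math.atan2(beta[1], beta[0])  # fit = A cos(w t - phi) + c
    return r2, math.hypot(beta[0], beta[1]), phi / w


def extract_phase(
    trace: CellTrace,
    tau: float,
    min_r2: float = 0.7,
) -> PhaseSeries | None:
    """Locate peaks by a sliding one-period cosine fit and build the phase.

    A window of length ``tau`` slides across the trace one sample at a time;
    in each window an offset cosine of fixed period ``tau`` is least-squares
    fitted and, when the fitted peak lies inside the window and the fit's
    coefficient of determination reaches ``min_r2``, the peak time is kept as
    a candidate.  Candidates closer than ``tau/2`` are averaged.  Returns
    ``None`` when no window fits well enough or fewer than 2 peaks are found.
    """
    t, y = trace.times, trace.values
    if trace.span < tau or trace.n_samples < 4:
        return None
    win = tau
    candidates: list[tuple[float, float]] = []  # (peak_time, r2)
    best_r2 = -np.inf
    i = 0
    while t[i] + win <= t[-1] + 1e-9:
        sel = (t >= t[i]) & (t <= t[i] + win + 1e-9)
        if sel.sum() >= 4:
            r2, amp, peak_offset = _fit_cosine_window(t[sel], y[sel], tau)
            best_r2 = max(best_r2, r2)
            if r2 >= min_r2 and amp > 0:
                # peaks of the fitted cosine at peak_offset + m*tau
                m = math.ceil((t[i] - peak_offset) / tau - 1e-9)
                pk = peak_offset + m * tau
                if t[i] - 1e-9 <= pk <= t[i] + win + 1e-9:
                    candidates.append((pk, r2))
        i += 1
        if i >= t.size:
            break
    if best_r2 < min_r2 or not candidates:
        return None

    candidates.sort()
    clusters: list[list[tuple[float, float]]] = [[candidates[0]]]
    for c in candidates[1:]:
        if c[0] - clusters[-1][-1][0] < tau / 2:
            clusters[-1].append(c)
        else:
            clusters.append([c])
    peaks = np.array([np.mean([c[0] for c in cl]) for cl in clusters])
    mean_r2 = float(np.mean([c[1] for cl in clusters for c in cl]))
    if peaks.size < 2:
        return None

    sel = (t >= peaks[0]) & (t <= peaks[-1])
    times = t[sel]
    theta = np.interp(times, peaks, TWO_PI * np.arange(peaks.size))
    return PhaseSeries(
        cell_id=trace.cell_id,
        times=times,
        theta=theta,
        period_tau=tau,
        fit_r2=mean_r2,
        peak_times=peaks,
    )


# ---------------------------------------------------------------------------
# synchrony measures
# ---------------------------------------------------------------------------


def order_parameter(theta: np.ndarray) -> float:
    """Kuramoto order parameter R = |mean_j exp(-i theta_j)| in [0, 1]."""
    theta = np.asarray(theta, float)
    if theta.size == 0:
        raise ValueError("order_parameter of an empty phase set")
    return float(np.abs(np.mean(np.exp(-1j * theta))))


def sync_index(
    traces: np.ndarray,
    times: np.ndarray,
    t: float,
    half_window: float = 12.0,
    return_ratio: bool = False,
) -> float:
    """Windowed synchronisation index at time ``t``.

    ``traces`` is an (N, T) array of cell signals on the common grid
    ``times``.  Over the window ``t - half_window < s < t + half_window`` the
    ensemble mean ``M(s)`` is formed and the variance ratio

        R^2 = Var(M) / mean_j Var(x_j)

    computed (time averages over the window).  The square root is returned
    (identical traces give 1, a balanced cosine ensemble 0); pass
    ``return_ratio=True`` for the raw ratio.
    """
    traces = np.atleast_2d(np.asarray(traces, float))
    sel = (times > t - half_window) & (times < t + half_window)
    if sel.sum() < 2:
        raise ValueError("window contains fewer than 2 samples")
    x = traces[:, sel]
    var_j = x.var(axis=1)
    if np.any(var_j <= 0):
        raise ValueError("a trace is constant over the window")
    M = x.mean(axis=0)
    ratio = float(M.var() / var_j.mean())
    return ratio if return_ratio else math.sqrt(ratio)


def _density(n: int, r: float) -> float:
    return n / ((4.0 / 3.0) * math.pi * r**3)


def neighbourhood_curve(
    cells: list[CellTrace],
    phases: dict[str, PhaseSeries],
    centroid_id: str,
    r: float,
    measure: str = "order_parameter",
    grid_spacing: float = 1.0,
    half_window: float = 12.0,
) -> SyncCurve:
    """Synchrony-vs-time curve for the sphere of radius ``r`` around one cell.

    Members are all cells (the centroid included) within the *closed* ball.
    For ``measure="order_parameter"`` members need an entry in ``phases``;
    phases are compared on the intersection of their time supports.  For
    ``measure="sync_index"`` the raw traces are used and the curve is defined
    where the 2*half_window window fits inside the common span.  The slope is
    the OLS slope of R on t.
    """
    by_id = {c.cell_id: c for c in cells}
    if centroid_id not in by_id:
        raise ValueError(f"centroid {centroid_id!r} not among cells")
    c0 = np.asarray(by_id[centroid_id].position)
    members = [
        c for c in cells if np.linalg.norm(np.asarray(c.position) - c0) <= r + 1e-12
    ]
    if measure == "order_parameter":
        members = [c for c in members if c.cell_id in phases]
    if not members:
        raise ValueError(f"no usable neighbours within r={r} of {centroid_id!r}")

    if measure == "order_parameter":
        ps = [phases[c.cell_id] for c in members]
        t0 = max(p.times[0] for p in ps)
        t1 = min(p.times[-1] for p in ps)
        if t1 <= t0:
            raise ValueError("phase series have no common time support")
        grid = np.arange(t0, t1 + 1e-9, grid_spacing)
        theta = np.stack([p.theta_at(grid) for p in ps])
        R = np.abs(np.mean(np.exp(-1j * theta), axis=0))
    elif measure == "sync_index":
        t0 = max(c.times[0] for c in members)
        t1 = min(c.times[-1] for c in members)
        grid_all = np.arange(t0, t1 + 1e-9, grid_spacing)
        x = np.stack([np.interp(grid_all, c.times, c.values) for c in members])
        grid = grid_all[
            (grid_all >= t0 + half_window) & (grid_all <= t1 - half_window)
        ]
        if grid.size < 2:
            raise ValueError("span too short for the sync-index window")
        R = np.array([sync_index(x, grid_all, t, half_window) for t in grid])
    else:
        raise ValueError(f"unknown measure {measure!r}")

    slope = float(stats.linregress(grid, R).slope) if grid.size >= 2 else 0.0
    return SyncCurve(
        centroid_cell_id=centroid_id,
        radius_r=r,
        n_neighbours=len(members),
        density_rho=_density(len(members), r),
        times=grid,
        R=np.asarray(R, float),
        slope=slope,
        measure=measure,
    )


# ---------------------------------------------------------------------------
# coupling estimation
# ---------------------------------------------------------------------------


def simulate_kuramoto(
    omega: np.ndarray,
    theta0: np.ndarray,
    t_end: float,
    K: float,
    dt: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Euler-integrate the all-to-all (1/N) Kuramoto model.

    Returns ``(times, R)`` where ``R[i]`` is the order parameter at step i.
    """
    omega = np.asarray(omega, float)
    theta = np.asarray(theta0, float).copy()
    n = theta.size
    n_steps = int(round(t_end / dt))
    times = np.arange(n_steps + 1) * dt
    R = np.empty(n_steps + 1)
    for i in range(n_steps + 1):
        z = np.mean(np.exp(1j * theta))
        R[i] = np.abs(z)
        if i == n_steps:
            break
        # (K/N) sum_k sin(theta_k - theta_j) = K * Im(z * exp(-i theta_j))
        coupling = K * np.imag(z * np.exp(-1j * theta))
        theta = theta + (omega + coupling) * dt
    return times, R


def estimate_coupling(
    phase_series: list[PhaseSeries],
    slope_obs: float,
    centroid_cell_id: str = "",
    K_init: float = 0.002,
    K_step: float = 1.25,
    K_max: float = 10.0,
    dt: float = 0.1,
    t_end: float | None = None,
) -> CouplingEstimate:
    """Incremental-K coupling estimate for one neighbourhood.

    Each member contributes its estimated period (``omega = 2*pi/tau``) and
    initial phase; the ensemble is simulated over the observed span at
    increasing K (geometric schedule, factor ``K_step``) until the simulated
    order-parameter slope reaches ``slope_obs``.  Raises ``RuntimeError``
    (carrying the last slope) if K exceeds ``K_max`` first.
    """
    if not phase_series:
        raise ValueError("empty ensemble")
    if not math.isfinite(slope_obs):
        raise ValueError("slope_obs must be finite")
    omega = np.array([TWO_PI / p.period_tau for p in phase_series])
    t0 = max(p.times[0] for p in phase_series)
    theta0 = np.array([p.theta_at(np.array([t0]))[0] for p in phase_series])
    if t_end is None:
        t_end = min(p.times[-1] for p in phase_series) - t0
    if t_end <= 0:
        raise ValueError("no common time support")

    K = K_init
    while True:
        times, R = simulate_kuramoto(omega, theta0, t_end, K, dt)
        slope_sim = float(stats.linregress(times, R).slope)
        if slope_sim >= slope_obs:
            return CouplingEstimate(
                centroid_cell_id=centroid_cell_id,
                K_hat=K,
                K_init=K_init,
                slope_obs=slope_obs,
                slope_sim_at_K_hat=slope_sim,
            )
        K *= K_step
        if K > K_max:
            raise RuntimeError(
                f"coupling search exceeded K_max={K_max}; last slope {slope_sim:.3g} "
                f"< observed {slope_obs:.3g}"
            )
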
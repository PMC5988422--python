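"""Per-cell rhythm analysis.

A cell is called rhythmic only when *every* configured period estimator finds
a circadian period with acceptable goodness of fit **and** all estimates agree
pairwise within a consensus tolerance (default 2.5 h).  The consensus period
reported is the first-listed estimator's value — by convention the
cosine-NLLS analogue, mirroring the usual practice of reporting FFT-NLLS
periods once the consensus filter has been applied.

Two concrete estimators are shipped behind a single contract:

``cosine_nlls``
    Nonlinear least-squares fit of the linearly detrended trace to
    ``offset + a*cos(2*pi*t/tau + phi)``; goodness of fit is the relative RMS
    residual (0 = perfect fit).  Default acceptance threshold 1.0.
``lomb_scargle``
    Normalised Lomb-Scargle periodogram peak in the circadian band; goodness
    of fit is the fraction of variance *not* captured by the peak frequency
    (1 - normalised peak power).  Default acceptance threshold 0.9.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from .traces import CellTrace

__all__ = [
    "PeriodEstimator",
    "RhythmResult",
    "VariabilityStats",
    "cosine_nlls_estimator",
    "lomb_scargle_estimator",
    "default_estimators",
    "interpolate_trace",
    "smooth_rloess",
    "detect_extrema",
    "assess_rhythmicity",
    "amplitude_stats",
    "period_variability",
    "dedupe_overlaps",
    "section_phase_stats",
]

TWO_PI = 2.0 * math.pi
DEFAULT_PERIOD_WINDOW = (15.0, 35.0)


# ---------------------------------------------------------------------------
# interpolation and smoothing
# ---------------------------------------------------------------------------


def interpolate_trace(trace: CellTrace, spacing: float = 1.0) -> CellTrace:
    """Linearly interpolate a trace onto a uniform grid (no extrapolation).

    The grid starts at the first sample and steps by ``spacing`` up to the
    last sample time.
    """
    if trace.n_samples < 2:
        raise ValueError(f"cell {trace.cell_id}: need >= 2 samples to interpolate")
    grid = np.arange(trace.times[0], trace.times[-1] + 1e-9, spacing)
    vals = np.interp(grid, trace.times, trace.values)
    return trace.with_values(vals, times=grid)


def smooth_rloess(values: np.ndarray, window: int, n_robust: int = 2) -> np.ndarray:
    """Robust local quadratic regression (MATLAB 'rloess'-style smoother).

    Fits a weighted second-degree polynomial in a sliding window with tricube
    weights, then re-fits ``n_robust`` times with bisquare robustness weights
    to resist outliers.  ``window`` is the window length in samples (forced
    odd, >= 5).
    """
    y = np.asarray(values, float)
    n = y.size
    window = max(5, window | 1)
    half = window // 2
    robust_w = np.ones(n)
    out = y.copy()
    for _ in range(n_robust + 1):
        out = np.empty(n)
        for i in range(n):
            lo, hi = max(0, i - half), min(n, i + half + 1)
            x = np.arange(lo, hi) - i
            d = np.abs(x) / max(half, 1)
            w = (1 - np.minimum(d, 1) ** 3) ** 3 * robust_w[lo:hi]
            if w.sum() <= 0:
                out[i] = y[i]
                continue
            X = np.stack([np.ones_like(x, float), x, x**2], axis=1)
            Xw = X * w[:, None]
            beta, *_ = np.linalg.lstsq(Xw.T @ X, Xw.T @ y[lo:hi], rcond=None)
            out[i] = beta[0]
        resid = y - out
        s = np.median(np.abs(resid)) or 1.0
        robust_w = np.clip(1 - (resid / (6 * s)) ** 2, 0, None) ** 2
    return out


def _linear_detrend(times: np.ndarray, values: np.ndarray) -> np.ndarray:
    slope, intercept = np.polyfit(times, values, 1)
    return values - (slope * times + intercept)


# ---------------------------------------------------------------------------
# period estimators
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PeriodEstimator:
    """A pluggable period estimator with its acceptance threshold.

    ``fn(times, detrended_values, period_window)`` returns ``(period, gof)``
    or ``None`` when no oscillation is found; the cell passes this estimator
    when a period is returned and ``gof <= gof_max``.
    """

    name: str
    fn: "callable"
    gof_max: float


def _periodogram_peak_period(times, values, period_window):
    """Dominant period from a dense normalised Lomb-Scargle periodogram."""
    lo, hi = period_window
    periods = np.linspace(lo, hi, 801)
    ang = TWO_PI / periods
    power = signal.lombscargle(times, values - values.mean(), ang, normalize=True)
    k = int(np.argmax(power))
    return float(periods[k]), float(power[k])


def cosine_nlls_estimator(times, values, period_window=DEFAULT_PERIOD_WINDOW):
    """Offset + cosine least-squares fit; gof = relative RMS residual."""
    rms = float(np.sqrt(np.mean(values**2)))
    if rms < 1e-12:
        return None
    tau0, _ = _periodogram_peak_period(times, values, period_window)

    def model(p):
        a, tau, phi, c = p
        return a * np.cos(TWO_PI * times / tau + phi) + c - values

    # analytic start: harmonic regression at the periodogram period
    w0 = TWO_PI / tau0
    X = np.stack([np.cos(w0 * times), np.sin(w0 * times), np.ones_like(times)], axis=1)
    alpha, beta_s, c0 = np.linalg.lstsq(X, values, rcond=None)[0]
    a0 = math.hypot(alpha, beta_s)
    phi0 = math.atan2(-beta_s, alpha)
    best = optimize.least_squares(
        model,
        x0=[a0, tau0, phi0, c0],
        bounds=([0.0, period_window[0], -TWO_PI, -np.inf],
                [np.inf, period_window[1], TWO_PI, np.inf]),
    )
    a, tau, _, _ = best.x
    if a < 1e-9 * rms:
        return None
    gof = float(np.sqrt(2 * best.cost / times.size)) / rms
    return float(tau), gof


def lomb_scargle_estimator(times, values, period_window=DEFAULT_PERIOD_WINDOW):
    """Lomb-Scargle band peak; gof = 1 - normalised peak power."""
    if np.std(values) < 1e-12:
        return None
    tau, power = _periodogram_peak_period(times, values, period_window)
    if power <= 0:
        return None
    return tau, float(1.0 - power)


def default_estimators() -> list[PeriodEstimator]:
    return [
        PeriodEstimator("cosine_nlls", cosine_nlls_estimator, gof_max=1.0),
        PeriodEstimator("lomb_scargle", lomb_scargle_estimator, gof_max=0.9),
    ]


# ---------------------------------------------------------------------------
# rhythmicity assessment
# ---------------------------------------------------------------------------


@dataclass
class RhythmResult:
    """Per-cell rhythm verdict and statistics."""

    cell_id: str
    section: str
    position: tuple[float, float, float]
    period_estimates: dict[str, float]
    gof: dict[str, float]
    rhythmic: bool
    consensus_period: float  # NaN when non-rhythmic
    peak_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    trough_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    peak_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    trough_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    amplitude: float | None = None


def detect_extrema(
    times: np.ndarray,
    values: np.ndarray,
    period: float,
    prominence_frac: float = 0.1,
):
    """Local maxima/minima with minimum separation of half a period.

    ``values`` should already be detrended (and smoothed for densely sampled
    data).  Prominence threshold is a fraction of the value range.
    """
    spacing = float(np.median(np.diff(times)))
    distance = max(1, int(round(0.5 * period / spacing)))
    prom = prominence_frac * float(np.ptp(values)) if np.ptp(values) > 0 else None
    peaks, _ = signal.find_peaks(values, distance=distance, prominence=prom)
    troughs, _ = signal.find_peaks(-values, distance=distance, prominence=prom)
    return times[peaks], values[peaks], times[troughs], values[troughs]


def assess_rhythmicity(
    trace: CellTrace,
    estimators: list[PeriodEstimator] | None = None,
    consensus_tol: float = 2.5,
    period_window: tuple[float, float] = DEFAULT_PERIOD_WINDOW,
    smooth_if_interval_leq: float = 1.5,
    prominence_frac: float = 0.1,
) -> RhythmResult:
    """Run all estimators and apply the consensus rhythmicity filter.

    Rhythmic iff every estimator returns a period with gof within its
    threshold and the maximum pairwise difference of the estimates is at most
    ``consensus_tol`` hours.  The trace must already be on a uniform grid
    (see :func:`interpolate_trace`).
    """
    if estimators is None:
        estimators = default_estimators()
    if len(estimators) < 2:
        raise ValueError("consensus filtering needs at least 2 estimators")

    detrended = _linear_detrend(trace.times, trace.values)
    periods: dict[str, float] = {}
    gofs: dict[str, float] = {}
    all_pass = True
    for est in estimators:
        out = est.fn(trace.times, detrended, period_window)
        if out is None:
            all_pass = False
            continue
        period, gof = out
        periods[est.name] = period
        gofs[est.name] = gof
        if gof > est.gof_max:
            all_pass = False

    rhythmic = (
        all_pass
        and len(periods) == len(estimators)
        and (max(periods.values()) - min(periods.values())) <= consensus_tol
    )
    consensus = periods.get(estimators[0].name, math.nan) if rhythmic else math.nan

    result = RhythmResult(
        cell_id=trace.cell_id,
        section=trace.section,
        position=trace.position,
        period_estimates=periods,
        gof=gofs,
        rhythmic=rhythmic,
        consensus_period=consensus,
    )
    if not rhythmic:
        return result

    working = detrended
    if trace.sampling_interval <= smooth_if_interval_leq:
        window = int(round(6.0 / trace.sampling_interval))  # ~6 h local window
        working = smooth_rloess(detrended, window)
    pt, pv, tt, tv = detect_extrema(trace.times, working, consensus, prominence_frac)
    result.peak_times, result.peak_values = pt, pv
    result.trough_times, result.trough_values = tt, tv
    result.amplitude = amplitude_stats(pt, pv, tt, tv)
    return result


def amplitude_stats(peak_times, peak_values, trough_times, trough_values) -> float | None:
    """Mean of all successive trough->peak and peak->trough excursions.

    Returns ``None`` (amplitude absent) when fewer than 3 peaks were found or
    the peak and trough counts differ by more than one.
    """
    if len(peak_times) < 3 or abs(len(peak_times) - len(trough_times)) > 1:
        return None
    events = sorted(
        [(t, v, "p") for t, v in zip(peak_times, peak_values)]
        + [(t, v, "t") for t, v in zip(trough_times, trough_values)]
    )
    excursions = [
        abs(b[1] - a[1]) for a, b in zip(events, events[1:]) if a[2] != b[2]
    ]
    return float(np.mean(excursions)) if excursions else None


# ---------------------------------------------------------------------------
# population statistics
# ---------------------------------------------------------------------------


@dataclass
class VariabilityStats:
    """Within- and between-cell period variability from peak-to-peak intervals."""

    between_cell_sd: float
    within_cell_sd: float
    n_cells: int


def period_variability(results: list[RhythmResult]) -> VariabilityStats:
    """Peak-interval period variability across a group of rhythmic cells.

    within-cell: mean over cells of the SD of successive peak-to-peak
    intervals; between-cell: SD over cells of the per-cell mean interval.
    Requires >= 2 cells, each with >= 3 detected peaks.
    """
    usable = [r for r in results if r.rhythmic and len(r.peak_times) >= 3]
    if len(usable) < 2:
        raise ValueError("period_variability needs >= 2 rhythmic cells with >= 3 peaks")
    means, sds = [], []
    for r in usable:
        intervals = np.diff(r.peak_times)
        means.append(float(np.mean(intervals)))
        sds.append(float(np.std(intervals, ddof=1)))
    return VariabilityStats(
        between_cell_sd=float(np.std(means, ddof=1)),
        within_cell_sd=float(np.mean(sds)),
        n_cells=len(usable),
    )


def dedupe_overlaps(
    cells: list,
    section_boxes: dict[str, tuple[float, float, float, float]],
) -> tuple[list, dict[str, int]]:
    """Remove double-counted cells where imaged-section bounding boxes overlap.

    ``section_boxes`` maps section name to ``(x0, y0, x1, y1)``.  Where two
    boxes overlap, only cells of the section with the lower origin are kept;
    cells assigned to the higher section that fall inside the overlap are
    dropped.  "Lower" compares ``(y0, x0)`` lexicographically.  Works on any
    objects with ``.section`` and ``.position`` (traces or rhythm results).

    Returns the kept cells and a per-section count of removals.
    """
    removed_ids = set()
    removed_by_section: dict[str, int] = {}
    names = list(section_boxes)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            ax0, ay0, ax1, ay1 = section_boxes[a]
            bx0, by0, bx1, by1 = section_boxes[b]
            ox0, oy0 = max(ax0, bx0), max(ay0, by0)
            ox1, oy1 = min(ax1, bx1), min(ay1, by1)
            if ox0 >= ox1 or oy0 >= oy1:
                continue
            higher = a if (ay0, ax0) > (by0, bx0) else b
            for c in cells:
                if c.section != higher or id(c) in removed_ids:
                    continue
                x, y = c.position[0], c.position[1]
                if ox0 <= x <= ox1 and oy0 <= y <= oy1:
                    removed_ids.add(id(c))
                    removed_by_section[higher] = removed_by_section.get(higher, 0) + 1
    kept = [c for c in cells if id(c) not in removed_ids]
    return kept, removed_by_section


def section_phase_stats(
    results: list[RhythmResult],
    window: tuple[float, float] = (48.0, 72.0),
) -> dict[str, dict[str, float]]:
    """Per-section mean and SD of the peak time inside a phase window.

    For each rhythmic cell the earliest detected peak inside ``window`` is its
    phase; sections with no in-window peaks are absent from the output.
    """
    lo, hi = window
    by_section: dict[str, list[float]] = {}
    for r in results:
        if not r.rhythmic or r.peak_times.size == 0:
            continue
        in_win = r.peak_times[(r.peak_times >= lo) & (r.peak_times <= hi)]
        if in_win.size:
            by_section.setdefault(r.section, []).append(float(in_win[0]))
    out = {}
    for sec, phases in by_section.items():
        arr = np.asarray(phases)
        out[sec] = {
            "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
            "n": int(arr.size),
        }
    return out
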
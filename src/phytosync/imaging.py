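"""Luciferase movie pipeline: segmentation, despiking, low-pass filtering,
amplitude de-trending and per-section space-time plots.

The stages mirror a standard weak-signal bioluminescence workflow:

1. per-frame foreground segmentation at the frame's mean grey level;
2. per-frame 3x3 median filter to remove sporadic cosmic-ray pixel spikes;
3. per-pixel zero-phase (forward-backward) 3rd-order Butterworth low-pass at
   15% of the Nyquist frequency;
4. per-pixel amplitude de-trending by dividing out a moving peak-to-trough
   envelope, so damped oscillations become comparable across time;
5. max-intensity per one-pixel-wide longitudinal section per frame, each
   section normalised to its own peak.

Row 0 of the space-time matrix is the root-tip end; pass ``row0_is_top=True``
if the stack stores the tip at the top of the frame.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .synthetic import ImageStack
from .wave_model import SpaceTimeMatrix

__all__ = [
    "segment_frame",
    "segment_stack",
    "despike",
    "lowpass",
    "amplitude_detrend",
    "build_spacetime",
    "process_stack",
]


def segment_frame(image: np.ndarray) -> np.ndarray:
    """Foreground mask: pixels strictly above the frame's mean grey level.

    A constant frame yields an empty mask (a warning is emitted): ties at
    exactly the mean are background.
    """
    image = np.asarray(image, float)
    if image.size == 0:
        raise ValueError("empty image")
    mask = image > image.mean()
    if not mask.any():
        warnings.warn("constant frame: empty segmentation mask", stacklevel=2)
    return mask


def segment_stack(stack: ImageStack) -> np.ndarray:
    """Apply mean-threshold segmentation to each frame individually."""
    return np.stack([segment_frame(f) for f in stack.frames])


def despike(stack: ImageStack) -> ImageStack:
    """Per-frame 3x3 median filter (reflective edges) to remove pixel spikes."""
    t, h, w = stack.frames.shape
    if h < 3 or w < 3:
        raise ValueError("frames must be at least 3x3")
    filtered = np.stack(
        [ndimage.median_filter(f, size=3, mode="reflect") for f in stack.frames]
    )
    return ImageStack(filtered, stack.frame_interval, stack.pixel_size)


def lowpass(series: np.ndarray, order: int = 3, cutoff_frac: float = 0.15) -> np.ndarray:
    """Zero-phase Butterworth low-pass along the last axis.

    Forward-backward filtering (``filtfilt``) avoids phase distortion; the
    squared magnitude response halves the amplitude of a sinusoid exactly at
    the cutoff (default 15% of Nyquist).  DC gain is 1.  Reflective padding
    of 3x the (order+1) filter length is used at the edges.
    """
    series = np.asarray(series, float)
    padlen = 3 * (order + 1)
    if series.shape[-1] <= padlen:
        raise ValueError(f"series too short for padlen={padlen}")
    b, a = signal.butter(order, cutoff_frac)
    return signal.filtfilt(b, a, series, axis=-1, padtype="even", padlen=padlen)


def _dominant_period_samples(series: np.ndarray) -> float | None:
    """Dominant oscillation period (in samples) from the FFT, or None."""
    x = series - series.mean()
    if np.std(x) < 1e-12:
        return None
    power = np.abs(np.fft.rfft(x)) ** 2
    if power.size < 3:
        return None
    k = int(np.argmax(power[1:])) + 1  # skip DC
    total = power[1:].sum()
    if total <= 0 or power[k] < 0.2 * total or k < 2:
        # no pronounced spectral peak, or fewer than 2 cycles in the series
        return None
    return series.size / k


def amplitude_detrend(series: np.ndarray, period_samples: float | None = None) -> np.ndarray:
    """Divide out the local oscillation envelope.

    The mean is removed, then the moving peak-to-trough range over a
    one-period window (rolling max minus rolling min) is divided out, so a
    damped cosine becomes (approximately) constant-amplitude.  Series without
    a pronounced spectral peak are returned unchanged (mean removed) with a
    warning.
    """
    series = np.asarray(series, float)
    if period_samples is None:
        period_samples = _dominant_period_samples(series)
    if period_samples is None or period_samples < 4:
        warnings.warn("non-oscillatory series: amplitude de-trend skipped", stacklevel=2)
        return series - series.mean()
    x = series - series.mean()
    w = max(3, int(round(period_samples)))
    env = ndimage.maximum_filter1d(x, w, mode="nearest") - ndimage.minimum_filter1d(
        x, w, mode="nearest"
    )
    # edge windows see less than a full cycle and underestimate the range;
    # hold the envelope constant over the first/last period instead
    if x.size > 2 * w:
        env[: w // 2] = env[w // 2]
        env[-(w // 2) :] = env[-(w // 2) - 1]
    floor = 1e-6 * max(float(env.max()), 1e-30)
    return x / np.maximum(env, floor)


@dataclass
class PixelSeriesField:
    """Per-pixel filtered time series inside an ROI, with per-frame masks."""

    series: np.ndarray  # (H, W, T)
    masks: np.ndarray  # (T, H, W) foreground masks
    frame_interval: float


def build_spacetime(
    stack_values: np.ndarray,
    masks: np.ndarray,
    frame_interval: float,
    hypocotyl_rows: int = 10,
    root_rows: int | None = None,
    row0_is_top: bool = False,
) -> SpaceTimeMatrix:
    """Max-per-longitudinal-section space-time matrix, row-peak-normalised.

    Entry (n, m) is the maximum over in-mask pixels of row n at frame m.
    Rows that never enter the mask are excluded.  ``root_rows`` limits the
    plot to that many rows from the root tip plus ``hypocotyl_rows`` beyond
    (default: all rows).  Rows of the output are indexed from the root tip.
    """
    vals = np.asarray(stack_values, float)
    if row0_is_top:
        vals = vals[:, ::-1, :]
        masks = masks[:, ::-1, :]
    t, h, w = vals.shape
    if root_rows is not None:
        limit = min(h, root_rows + hypocotyl_rows)
        vals, masks = vals[:, :limit, :], masks[:, :limit, :]
        h = limit

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        masked = np.where(masks, vals, np.nan)
        per_row = np.nanmax(masked, axis=2)  # (T, rows)
    keep = masks.any(axis=(0, 2))
    # rows absent from single frames: fill by linear interpolation in time
    out = per_row[:, keep].T.copy()
    times = np.arange(t) * frame_interval
    for i in range(out.shape[0]):
        bad = np.isnan(out[i])
        if bad.any():
            out[i, bad] = np.interp(times[bad], times[~bad], out[i, ~bad])
    peaks = out.max(axis=1, keepdims=True)
    out = out / np.where(peaks > 0, peaks, 1.0)
    return SpaceTimeMatrix(rows=np.flatnonzero(keep), times=times, values=out)


def process_stack(
    stack: ImageStack,
    hypocotyl_rows: int = 10,
    root_rows: int | None = None,
    row0_is_top: bool = False,
    detrend: bool = True,
    lowpass_cutoff: float = 0.15,
) -> tuple[SpaceTimeMatrix, PixelSeriesField]:
    """Full pipeline: despike -> segment -> per-pixel filter/de-trend -> plot.

    Filtering and de-trending are applied per pixel before the per-section
    max projection (the Methods-order default).
    """
    clean = despike(stack)
    masks = segment_stack(clean)
    series = np.moveaxis(clean.frames, 0, -1)  # (H, W, T)
    ever = masks.any(axis=0)
    flat = series[ever]  # (n_px, T)
    flat = lowpass(flat, cutoff_frac=lowpass_cutoff)
    if detrend:
        for i in range(flat.shape[0]):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                flat[i] = amplitude_detrend(flat[i])
    processed = np.zeros_like(series)
    processed[ever] = flat
    field = PixelSeriesField(
        series=processed, masks=masks, frame_interval=stack.frame_interval
    )
    stm = build_spacetime(
        np.moveaxis(processed, -1, 0),
        masks,
        stack.frame_interval,
        hypocotyl_rows=hypocotyl_rows,
        root_rows=root_rows,
        row0_is_top=row0_is_top,
    )
    return stm, field
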
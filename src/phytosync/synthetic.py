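"""Synthetic seedling generator.

Emulates the statistical structure of single-cell clock-reporter movies of
*Arabidopsis* seedlings in constant light: per-section cell counts, intrinsic
period distributions, section-specific peak-phase distributions, additive
measurement noise, optional phase diffusion / amplitude damping / cell-to-cell
coupling — plus a luciferase-macro-like image stack carrying a travelling
phase wave over a root-shaped mask, with hot-pixel spikes and background.

The signal model for cell *j* is

    B_j(t) = A_j * exp(-lambda * (t - t_start)) * (cos(theta_j(t)) + 1) + eps(t)

with ``d(theta_j)/dt = 2*pi/tau_j + coupling + phase-diffusion noise``.  In the
noise-free uncoupled limit the trace is an exactly sampled (damped) cosine
whose peaks fall at ``p_j + m * tau_j`` for an anchor peak time
``p_j ~ N(phase_mean, phase_sd^2)`` drawn per section.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .traces import CellTrace

__all__ = [
    "SectionProfile",
    "GeneratorConfig",
    "ImageStackConfig",
    "ImageStack",
    "StackGroundTruth",
    "default_sections",
    "generate_layout",
    "generate_traces",
    "generate_image_stack",
]

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class SectionProfile:
    """Statistical description of one imaged seedling section.

    ``phase_mean``/``phase_sd`` describe the per-cell anchor peak time (hours
    in LL) of the reference clock peak; ``y_range`` is the section's extent
    along the longitudinal axis, measured from the root tip.
    """

    section_name: str
    n_cells: int
    period_mean: float
    period_sd: float
    phase_mean: float
    phase_sd: float
    y_range: tuple[float, float]
    x_halfwidth: float = 0.15
    z_depth: float = 0.1

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError(f"{self.section_name}: n_cells must be >= 0")
        if self.period_mean <= 0:
            raise ValueError(f"{self.section_name}: period_mean must be > 0")
        if self.period_sd < 0 or self.phase_sd < 0:
            raise ValueError(f"{self.section_name}: SDs must be >= 0")
        if not self.y_range[1] > self.y_range[0]:
            raise ValueError(f"{self.section_name}: y_range must be non-degenerate")


def default_sections() -> list[SectionProfile]:
    """Default section panel: counts and 48-72 h peak-phase statistics of a
    wild-type seedling movie, shoot/root/root-tip intrinsic periods.

    Period SDs are free parameters (higher in the root, where period
    variability is larger)."""
    return [
        SectionProfile("root_tip", 242, 22.67, 1.5, 56.2, 5.0, (0.0, 0.18)),
        SectionProfile("lower_root", 84, 25.55, 1.5, 58.0, 4.4, (0.18, 2.0)),
        SectionProfile("upper_root", 46, 25.55, 1.5, 56.6, 4.5, (2.0, 3.5)),
        SectionProfile("lower_hypocotyl", 114, 24.0, 0.8, 52.1, 1.5, (3.5, 5.0)),
        SectionProfile("upper_hypocotyl", 53, 24.0, 0.8, 51.2, 1.1, (5.0, 6.5), 0.4),
        SectionProfile("cotyledon", 103, 24.0, 0.8, 55.6, 2.3, (6.5, 8.0), 0.6),
    ]


@dataclass
class GeneratorConfig:
    """Study conditions for the trace generator.

    Defaults emulate the wild-type movie: 29-168 h of constant light sampled
    every 1.1 h, low additive measurement noise, no phase diffusion, no
    damping, uncoupled cells.  ``phase_diffusion`` (rad^2 / h) is the explicit
    desynchronisation dial; the per-section phase SDs already carry the
    observed static phase dispersion.
    """

    sections: list[SectionProfile] = field(default_factory=default_sections)
    t_start: float = 29.0
    t_end: float = 168.0
    sampling_interval: float = 1.1
    noise_sd: float = 2.0
    phase_diffusion: float = 0.0
    amplitude_mean: float = 100.0
    amplitude_cv: float = 0.3
    damping_rate: float = 0.0
    coupling_K: float = 0.0
    neighbourhood_radius: float = 0.1
    euler_dt: float = 0.1
    rng_seed: int = 0

    def validate(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError("t_end must exceed t_start")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be > 0")
        if self.sampling_interval >= self.t_end - self.t_start:
            raise ValueError("sampling_interval must be smaller than the span")
        for name, v in [
            ("noise_sd", self.noise_sd),
            ("phase_diffusion", self.phase_diffusion),
            ("amplitude_cv", self.amplitude_cv),
            ("damping_rate", self.damping_rate),
            ("coupling_K", self.coupling_K),
        ]:
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        # distinct sections may not overlap along the longitudinal axis
        ordered = sorted(self.sections, key=lambda s: s.y_range[0])
        for a, b in zip(ordered, ordered[1:]):
            if b.y_range[0] < a.y_range[1] - 1e-12:
                raise ValueError(
                    f"sections {a.section_name!r} and {b.section_name!r} have "
                    "overlapping y_ranges"
                )


def generate_layout(config: GeneratorConfig) -> list[CellTrace]:
    """Place cells in their sections (positions + labels; no values yet).

    Returns trace stubs with empty time/value arrays.  Positions are uniform
    within each section's bounding volume and reproducible from ``rng_seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    stubs: list[CellTrace] = []
    idx = 0
    for sec in config.sections:
        y0, y1 = sec.y_range
        for _ in range(sec.n_cells):
            x = rng.uniform(-sec.x_halfwidth, sec.x_halfwidth)
            y = rng.uniform(y0, y1)
            z = rng.uniform(0.0, sec.z_depth)
            stubs.append(
                CellTrace(
                    cell_id=f"c{idx:04d}",
                    position=(float(x), float(y), float(z)),
                    section=sec.section_name,
                    times=np.empty(0),
                    values=np.empty(0),
                )
            )
            idx += 1
    return stubs


def _sample_amplitudes(rng, mean: float, cv: float, n: int) -> np.ndarray:
    # log-normal with the requested arithmetic mean and coefficient of variation
    if cv == 0:
        return np.full(n, mean)
    sigma2 = math.log1p(cv**2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), n)


@dataclass
class TraceGroundTruth:
    """Per-cell parameters the generator actually drew (recovery oracles)."""

    tau: dict[str, float]  # intrinsic period, hours
    anchor_peak: dict[str, float]  # noise-free reference peak time, hours
    amplitude: dict[str, float]


def generate_traces(
    layout: list[CellTrace],
    config: GeneratorConfig,
    return_truth: bool = False,
):
    """Fill a layout with sampled intensity series.

    Uncoupled phases follow the exact closed form; phase-diffusion increments
    between sample times are exact Gaussian Wiener increments.  With
    ``coupling_K > 0`` phases are Euler-integrated (step ``euler_dt``) with
    sinusoidal coupling to neighbours within ``neighbourhood_radius``,
    normalised by each cell's neighbour count.

    With ``return_truth=True`` also returns the drawn per-cell intrinsic
    periods, anchor peak times and amplitudes.
    """
    config.validate()
    if not layout:
        raise ValueError("layout is empty")
    rng = np.random.default_rng(config.rng_seed + 1)

    profiles = {s.section_name: s for s in config.sections}
    n = len(layout)
    tau = np.empty(n)
    anchor = np.empty(n)
    for j, cell in enumerate(layout):
        sec = profiles[cell.section]
        tau[j] = max(rng.normal(sec.period_mean, sec.period_sd), 4.0)
        anchor[j] = rng.normal(sec.phase_mean, sec.phase_sd)
    amps = _sample_amplitudes(rng, config.amplitude_mean, config.amplitude_cv, n)

    t = np.arange(config.t_start, config.t_end + 1e-9, config.sampling_interval)
    omega = TWO_PI / tau
    theta0 = omega * (config.t_start - anchor)  # theta=0 (a peak) at the anchor time

    if config.coupling_K == 0.0:
        theta = theta0[None, :] + omega[None, :] * (t[:, None] - config.t_start)
        if config.phase_diffusion > 0:
            dt = np.diff(t)
            incr = rng.normal(
                0.0,
                np.sqrt(config.phase_diffusion * dt)[:, None],
                (dt.size, n),
            )
            theta[1:, :] += np.cumsum(incr, axis=0)
    else:
        theta = _integrate_coupled(layout, theta0, omega, t, config, rng)

    envelope = amps[None, :] * np.exp(-config.damping_rate * (t[:, None] - config.t_start))
    clean = envelope * (np.cos(theta) + 1.0)
    noisy = clean + (
        rng.normal(0.0, config.noise_sd, clean.shape) if config.noise_sd > 0 else 0.0
    )

    traces = [cell.with_values(noisy[:, j], times=t) for j, cell in enumerate(layout)]
    if not return_truth:
        return traces
    truth = TraceGroundTruth(
        tau={c.cell_id: float(tau[j]) for j, c in enumerate(layout)},
        anchor_peak={c.cell_id: float(anchor[j]) for j, c in enumerate(layout)},
        amplitude={c.cell_id: float(amps[j]) for j, c in enumerate(layout)},
    )
    return traces, truth


def _integrate_coupled(layout, theta0, omega, t_out, config, rng) -> np.ndarray:
    """Euler integration of neighbour-coupled phases, sampled at ``t_out``."""
    pos = np.array([c.position for c in layout])
    d2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=-1)
    nbr = d2 <= config.neighbourhood_radius**2
    np.fill_diagonal(nbr, False)
    n_nbr = np.maximum(nbr.sum(axis=1), 1)

    dt = config.euler_dt
    n_steps = int(math.ceil((t_out[-1] - t_out[0]) / dt))
    theta = theta0.copy()
    grid_t = t_out[0]
    out = np.empty((t_out.size, theta0.size))
    k_out = 0
    sqrt_d_dt = math.sqrt(config.phase_diffusion * dt)
    for _ in range(n_steps + 1):
        while k_out < t_out.size and t_out[k_out] <= grid_t + 1e-9:
            out[k_out] = theta
            k_out += 1
        if k_out >= t_out.size:
            break
        sin_diff = np.sin(theta[None, :] - theta[:, None])  # [j, k] = sin(th_k - th_j)
        coupling = config.coupling_K * np.sum(np.where(nbr, sin_diff, 0.0), axis=1) / n_nbr
        theta = theta + (omega + coupling) * dt
        if config.phase_diffusion > 0:
            theta = theta + rng.normal(0.0, sqrt_d_dt, theta.shape)
        grid_t += dt
    if k_out < t_out.size:
        out[k_out:] = theta
    return out


# ---------------------------------------------------------------------------
# luciferase-like image stack fixture
# ---------------------------------------------------------------------------


@dataclass
class ImageStackConfig:
    """Parameters of the synthetic luciferase movie.

    The foreground is a root-shaped mask (narrow rectangular root with a
    flared hypocotyl at the top rows) whose pixels oscillate with a phase
    varying linearly along the longitudinal (row) axis: a travelling wave of
    known speed ``wave_speed_mm_h`` moving up from the root tip (row 0).
    """

    height: int = 80
    width: int = 40
    n_frames: int = 96
    frame_interval: float = 1.5
    pixel_size: float = 0.05
    period: float = 24.0
    wave_speed_mm_h: float = 0.2
    root_width_px: int = 8
    hypocotyl_rows: int = 20
    hypocotyl_width_px: int = 16
    amplitude: float = 100.0
    background: float = 10.0
    noise_sd: float = 2.0
    n_spikes: int = 30
    spike_value: float = 2000.0
    rng_seed: int = 0

    def validate(self) -> None:
        if min(self.height, self.width, self.n_frames) < 1:
            raise ValueError("stack dimensions must be >= 1")
        if self.frame_interval <= 0 or self.pixel_size <= 0 or self.period <= 0:
            raise ValueError("frame_interval, pixel_size and period must be > 0")
        if self.noise_sd < 0 or self.n_spikes < 0:
            raise ValueError("noise_sd and n_spikes must be >= 0")
        if self.root_width_px > self.width or self.hypocotyl_width_px > self.width:
            raise ValueError("foreground wider than the frame")
        if self.hypocotyl_rows > self.height:
            raise ValueError("hypocotyl_rows exceeds frame height")


@dataclass
class ImageStack:
    """A T x H x W stack of non-negative intensities."""

    frames: np.ndarray
    frame_interval: float
    pixel_size: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be T x H x W")
        if not np.all(np.isfinite(self.frames)) or np.any(self.frames < 0):
            raise ValueError("intensities must be finite and >= 0")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.frames.shape[0]) * self.frame_interval


@dataclass
class StackGroundTruth:
    """What the stack generator actually injected (for validation)."""

    mask: np.ndarray  # H x W foreground mask (row 0 = root tip)
    peak_time_by_row: np.ndarray  # hours; NaN for background-only rows
    wave_speed_mm_h: float
    spike_positions: np.ndarray  # (s, 3) array of (frame, row, col)


def _seedling_mask(cfg: ImageStackConfig) -> np.ndarray:
    # the flare tapers by at most one pixel per side per row so that every
    # foreground pixel keeps a majority-foreground 3x3 neighbourhood
    mask = np.zeros((cfg.height, cfg.width), dtype=bool)
    c = cfg.width // 2
    rw, hw = cfg.root_width_px, cfg.hypocotyl_width_px
    root_rows = cfg.height - cfg.hypocotyl_rows
    mask[:root_rows, c - rw // 2 : c + (rw + 1) // 2] = True
    for i, n in enumerate(range(root_rows, cfg.height)):
        w = min(hw, rw + 2 * (i + 1))
        mask[n, c - w // 2 : c + (w + 1) // 2] = True
    return mask


def generate_image_stack(cfg: ImageStackConfig) -> tuple[ImageStack, StackGroundTruth]:
    """Build the synthetic movie and its ground truth.

    Rows are indexed from the root tip (row 0).  A foreground pixel in row *n*
    carries ``background + amplitude * (cos(2*pi*(t - y_n / v)/period) + 1)``
    with ``y_n = n * pixel_size`` and ``v = wave_speed_mm_h``, so the peak
    time increases along the root with slope ``1/v`` (hours per mm).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)
    mask = _seedling_mask(cfg)
    t = np.arange(cfg.n_frames) * cfg.frame_interval
    y = np.arange(cfg.height) * cfg.pixel_size

    if math.isinf(cfg.wave_speed_mm_h):
        delay = np.zeros_like(y)
    else:
        delay = y / cfg.wave_speed_mm_h
    phase = TWO_PI * (t[:, None] - delay[None, :]) / cfg.period  # (T, H)
    rowsig = cfg.amplitude * (np.cos(phase) + 1.0)  # (T, H)

    frames = np.full((cfg.n_frames, cfg.height, cfg.width), cfg.background)
    frames += rowsig[:, :, None] * mask[None, :, :]
    if cfg.noise_sd > 0:
        frames += rng.normal(0.0, cfg.noise_sd, frames.shape)

    spikes = np.empty((cfg.n_spikes, 3), dtype=int)
    for s in range(cfg.n_spikes):
        spikes[s] = (
            rng.integers(cfg.n_frames),
            rng.integers(cfg.height),
            rng.integers(cfg.width),
        )
        frames[tuple(spikes[s])] = cfg.spike_value
    frames = np.clip(frames, 0.0, None)

    # first peak time of each foreground row: smallest t >= 0 with phase = 0 mod 2pi
    peak_time = np.where(mask.any(axis=1), delay % cfg.period, np.nan)
    truth = StackGroundTruth(
        mask=mask,
        peak_time_by_row=peak_time,
        wave_speed_mm_h=cfg.wave_speed_mm_h,
        spike_positions=spikes,
    )
    return ImageStack(frames, cfg.frame_interval, cfg.pixel_size), truth
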
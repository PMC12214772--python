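"""Pong-scan and raster-scan trajectory generation.

The Pong scan drives the x and y galvanometers with triangle waves whose
frequencies sit in the golden ratio, so the in-plane pattern fills the field
of view without repeating, while a TAG lens sweeps the focus axially at
~190 kHz.  Unlike a sinusoidal Lissajous scan, the triangle waves spend equal
time in every band of the field, and unlike a raster scan there is no slow
axis: every region of the image is revisited on a fast timescale, which is
what makes post-hoc rotation correction possible.

On the instrument the triangle waves are produced by an FPGA that increments
the galvo target by one pixel every time a 16-bit counter rolls over; the
counter periods are rounded to the nearest prime so that the joint (x, y)
state sequence repeats as slowly as the discrete logic permits.  The
generators here reproduce that quantisation exactly.

Coordinates are µm relative to the tracked reference neuron; time is seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sympy import nextprime, prevprime

__all__ = [
    "ScanConfig",
    "GalvoWaveform",
    "ScanTrajectory",
    "CoverageReport",
    "GOLDEN_FREQ_RATIO",
    "nominal_frequencies",
    "nearest_prime",
    "quantize_counters",
    "pong_trajectory",
    "raster_trajectory",
    "raster_characteristic_time",
    "tag_axial_position",
    "triangle_wave",
    "coverage_stats",
    "time_to_full_coverage",
]

#: y-frequency / x-frequency for the Pong scan: 2 / (1 + sqrt 5) = 1/phi.
GOLDEN_FREQ_RATIO = 2.0 / (1.0 + math.sqrt(5.0))


class InvalidScanConfig(ValueError):
    """Raised when scan parameters are inconsistent or non-physical."""


@dataclass(frozen=True)
class ScanConfig:
    """User-facing scan parameters.

    Parameters
    ----------
    a_x:
        Full peak-to-peak x scan range (µm).  The waveform is
        ``x(t) = (a_x / 2) * tri(2 pi f_x t)``.
    r_xy:
        Aspect ratio; the y range is ``a_x / r_xy``.
    tau_min:
        Minimum pixel dwell time (s).
    dx:
        Target pixel size (µm); also the galvo step per counter rollover.
    f_max:
        Maximum allowed galvo frequency (Hz).
    f_fpga:
        FPGA clock of the scan-generation loop (Hz).
    f_tag:
        TAG-lens resonance frequency (Hz); one axial line per half period.
    a_tag:
        Axial scan half-amplitude A (µm); z spans ±A.
    phi_exclude_deg:
        Half-angle (degrees) of the TAG-phase band around the turnaround
        points (phase 0 and pi) excluded from rate estimates.
    norm_const:
        Normalisation constant of the axial dwell correction
        ``n_adj = n |sin phi| / norm_const``.
    """

    a_x: float = 200.0
    r_xy: float = 1.0
    tau_min: float = 2.63e-6
    dx: float = 0.8
    f_max: float = 667.0
    f_fpga: float = 8.0e7
    f_tag: float = 1.9e5
    a_tag: float = 25.0
    phi_exclude_deg: float = 20.0
    norm_const: float = 0.7846

    def __post_init__(self) -> None:
        if not (self.a_x > 0 and self.dx > 0 and self.tau_min > 0):
            raise InvalidScanConfig("a_x, dx and tau_min must be positive")
        if self.dx >= self.a_x:
            raise InvalidScanConfig("pixel size dx must be smaller than the scan range")
        if self.r_xy < 1:
            raise InvalidScanConfig("aspect ratio r_xy must be >= 1")
        if self.f_max <= 0 or self.f_fpga <= 0:
            raise InvalidScanConfig("frequencies must be positive")
        if self.f_tag <= 0:
            raise InvalidScanConfig("f_tag must be positive (resonant axial scan)")
        if not (0 <= self.phi_exclude_deg < 90):
            raise InvalidScanConfig("phi_exclude_deg must lie in [0, 90)")

    @property
    def y_range(self) -> float:
        """Full peak-to-peak y scan range (µm)."""
        return self.a_x / self.r_xy


@dataclass(frozen=True)
class GalvoWaveform:
    """One galvo axis after FPGA counter quantisation."""

    freq_nominal: float
    freq_effective: float
    counter: int
    step: float
    steps_per_period: int

    def __post_init__(self) -> None:
        if self.steps_per_period < 2:
            raise InvalidScanConfig("need at least 2 steps per period")


@dataclass
class ScanTrajectory:
    """Focal-spot path sampled once per axial (TAG) half-period.

    ``x``/``y`` are in-plane positions relative to the tracked reference,
    ``phi`` the TAG phase and ``z = a_tag * cos(phi)`` the axial position.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    phi: np.ndarray
    z: np.ndarray
    kind: str = "pong"
    config: ScanConfig | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return self.t.size

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if self.t.size > 1 else 0.0


@dataclass
class CoverageReport:
    """Pixel-visit statistics of a trajectory at a given binning."""

    pixel: float
    duration: float
    fraction_visited: float
    first_visit: np.ndarray  # (ny, nx) time of first visit, NaN if never
    staleness: np.ndarray  # (ny, nx) duration - last visit, NaN if never

    def to_dict(self) -> dict:
        stale = self.staleness[np.isfinite(self.staleness)]
        return {
            "pixel_um": self.pixel,
            "duration_s": self.duration,
            "fraction_visited": self.fraction_visited,
            "median_staleness_s": float(np.median(stale)) if stale.size else float("nan"),
            "max_staleness_s": float(stale.max()) if stale.size else float("nan"),
        }


def nominal_frequencies(cfg: ScanConfig) -> tuple[float, float]:
    """Target triangle-wave frequencies (Hz) before counter quantisation.

    The x frequency is the fastest compatible with the minimum pixel dwell,
    clamped to the galvo limit; the y frequency is the golden-ratio fraction
    2/(1 + sqrt 5) of it, so the pattern fills the plane without repeating.
    """
    x_freq = min(cfg.dx / (2.0 * cfg.a_x * cfg.tau_min), cfg.f_max)
    return x_freq, GOLDEN_FREQ_RATIO * x_freq


def nearest_prime(v: float) -> int:
    """Prime nearest to ``v``; ties go to the larger prime.

    The larger prime means a longer counter period, i.e. a slightly lower
    galvo frequency — the conservative direction for the hardware.
    """
    if v < 2:
        raise ValueError(f"nearest_prime requires v >= 2, got {v}")
    above = int(nextprime(v - 1e-12))  # smallest prime >= v (v itself if prime)
    if above <= v:
        return above
    below = int(prevprime(v)) if v > 2 else 2
    return below if (v - below) < (above - v) else above


def quantize_counters(
    cfg: ScanConfig, x_freq: float, y_freq: float | None = None
) -> tuple[GalvoWaveform, GalvoWaveform]:
    """FPGA counter quantisation of the nominal triangle waves.

    The galvo target steps by one pixel every ``c`` FPGA clock ticks with
    ``c = nearest_prime(f_fpga * dtau)``, where ``dtau`` is the nominal step
    interval.  Prime counters keep the joint (x, y) state from repeating more
    often than the discrete logic requires.
    """
    if y_freq is None:
        y_freq = GOLDEN_FREQ_RATIO * x_freq
    dtau_x = cfg.dx / (2.0 * cfg.a_x) / x_freq
    dtau_y = dtau_x * (1.0 + math.sqrt(5.0)) / 2.0

    def one_axis(dtau: float, freq: float, rng: float) -> GalvoWaveform:
        steps = int(round(2.0 * rng / cfg.dx))
        if steps < 2:
            raise InvalidScanConfig("fewer than 2 galvo steps per period")
        c = nearest_prime(cfg.f_fpga * dtau)
        f_eff = cfg.f_fpga / (c * steps)
        return GalvoWaveform(
            freq_nominal=freq,
            freq_effective=f_eff,
            counter=c,
            step=cfg.dx,
            steps_per_period=steps,
        )

    return one_axis(dtau_x, x_freq, cfg.a_x), one_axis(dtau_y, y_freq, cfg.y_range)


def triangle_wave(theta: np.ndarray | float) -> np.ndarray | float:
    """Unit triangle wave ``tri(theta) = (2/pi) arcsin(sin(theta))``."""
    return (2.0 / math.pi) * np.arcsin(np.sin(theta))


def tag_axial_position(
    phi: np.ndarray | float, a_tag: float, z_off: float = 0.0
) -> np.ndarray | float:
    """Axial focal position ``z = A cos(phi) - z_off`` (µm)."""
    return a_tag * np.cos(phi) - z_off


def pong_trajectory(
    cfg: ScanConfig,
    duration: float,
    phase_x: float = 0.0,
    phase_y: float = 0.0,
) -> ScanTrajectory:
    """Pong-scan focal path, sampled once per TAG half-period.

    The FPGA command steps one pixel per counter rollover; the galvo mirror
    follows it smoothly, so the beam position is the continuous triangle
    wave at the counter-quantised *effective* frequency.  The TAG phase
    advances at ``2 pi f_tag``; with the default 190 kHz lens the sample
    spacing is ~2.6 µs, one axial line per sample.
    """
    if duration <= 0:
        raise InvalidScanConfig("duration must be positive")
    x_freq, y_freq = nominal_frequencies(cfg)
    wx, wy = quantize_counters(cfg, x_freq, y_freq)

    dt = 1.0 / (2.0 * cfg.f_tag)
    n = int(duration / dt)
    t = np.arange(n) * dt
    x = (cfg.a_x / 2.0) * triangle_wave(
        2.0 * math.pi * wx.freq_effective * t + phase_x
    )
    y = (cfg.y_range / 2.0) * triangle_wave(
        2.0 * math.pi * wy.freq_effective * t + phase_y
    )
    phi = (2.0 * math.pi * cfg.f_tag * t) % (2.0 * math.pi)
    z = tag_axial_position(phi, cfg.a_tag)
    return ScanTrajectory(t=t, x=x, y=y, phi=phi, z=z, kind="pong", config=cfg)


def raster_trajectory(cfg: ScanConfig, duration: float) -> ScanTrajectory:
    """Bi-directional raster reference scan at the same x line rate.

    x follows the quantised triangle wave; y advances one pixel per x
    half-period (one line per sweep), snaking through the field.
    """
    if duration <= 0:
        raise InvalidScanConfig("duration must be positive")
    x_freq, _ = nominal_frequencies(cfg)
    wx, _ = quantize_counters(cfg, x_freq)

    dt = 1.0 / (2.0 * cfg.f_tag)
    n = int(duration / dt)
    t = np.arange(n) * dt
    # x starts at the field edge so each half-period is one full line sweep
    x = (cfg.a_x / 2.0) * triangle_wave(
        2.0 * math.pi * wx.freq_effective * t - math.pi / 2.0
    )
    # one y line per x half-period
    half_period = 0.5 / wx.freq_effective
    n_lines = int(round(cfg.y_range / cfg.dx))
    line = np.floor(t / half_period).astype(np.int64) % (2 * n_lines)
    line = np.where(line < n_lines, line, 2 * n_lines - 1 - line)  # snake back
    y = -cfg.y_range / 2.0 + line * cfg.dx
    phi = (2.0 * math.pi * cfg.f_tag * t) % (2.0 * math.pi)
    z = tag_axial_position(phi, cfg.a_tag)
    return ScanTrajectory(t=t, x=x, y=y, phi=phi, z=z, kind="raster", config=cfg)


def raster_characteristic_time(cfg: ScanConfig, x_freq: float | None = None) -> float:
    """Characteristic time (s) for a bi-directional raster to cover the field.

    Number of raster lines (y range at pixel pitch, rounded up to whole
    lines) divided by the bi-directional line rate ``2 * x_freq``.
    """
    if x_freq is None:
        x_freq, _ = nominal_frequencies(cfg)
    n_lines = math.ceil(cfg.y_range / cfg.dx - 1e-9)
    return n_lines / (2.0 * x_freq)


def _visit_times(traj: ScanTrajectory, pixel: float, T: float) -> tuple[np.ndarray, np.ndarray]:
    cfg = traj.config
    if cfg is None:
        raise ValueError("trajectory carries no config; cannot infer field extent")
    if T > traj.t[-1] + traj.dt:
        raise ValueError("T exceeds the trajectory duration")
    nx = max(1, int(round(cfg.a_x / pixel)))
    ny = max(1, int(round(cfg.y_range / pixel)))
    sel = traj.t < T
    tt, x, y = traj.t[sel], traj.x[sel], traj.y[sel]
    # the beam measures continuously along each axial line: trace the path at
    # sub-pixel resolution so every crossed pixel counts as visited
    if len(tt) > 1:
        step = max(
            float(np.abs(np.diff(x)).max(initial=0.0)),
            float(np.abs(np.diff(y)).max(initial=0.0)),
        )
        up = max(1, int(math.ceil(step / (0.25 * pixel))))
        if up > 1:
            tt_f = np.arange((len(tt) - 1) * up + 1) * (traj.dt / up) + tt[0]
            x = np.interp(tt_f, tt, x)
            y = np.interp(tt_f, tt, y)
            tt = tt_f
    # epsilon guards against positions sitting exactly on bin edges
    ix = np.clip(((x + cfg.a_x / 2.0) / pixel + 1e-7).astype(int), 0, nx - 1)
    iy = np.clip(((y + cfg.y_range / 2.0) / pixel + 1e-7).astype(int), 0, ny - 1)
    flat = iy * nx + ix
    first = np.full(ny * nx, np.nan)
    last = np.full(ny * nx, np.nan)
    order = np.argsort(flat, kind="stable")
    flat_s, tt_s = flat[order], tt[order]
    idx, starts = np.unique(flat_s, return_index=True)
    first[idx] = tt_s[starts]
    ends = np.r_[starts[1:], flat_s.size] - 1
    last[idx] = tt_s[ends]
    return first.reshape(ny, nx), last.reshape(ny, nx)


def coverage_stats(traj: ScanTrajectory, pixel: float, T: float) -> CoverageReport:
    """Fraction of pixels visited within ``T`` and per-pixel staleness.

    "Visited" means at least one trajectory sample fell inside the pixel; the
    per-pixel staleness is the time elapsed at ``T`` since the last visit.
    """
    cfg = traj.config
    if cfg is not None and pixel < cfg.dx / 2.0:
        import warnings

        warnings.warn(
            f"pixel {pixel} µm is below half the scan step {cfg.dx} µm; "
            "coverage will undercount",
            stacklevel=2,
        )
    first, last = _visit_times(traj, pixel, T)
    frac = float(np.isfinite(first).mean())
    return CoverageReport(
        pixel=pixel,
        duration=T,
        fraction_visited=frac,
        first_visit=first,
        staleness=T - last,
    )


def time_to_full_coverage(traj: ScanTrajectory, pixel: float) -> float:
    """Earliest time by which every pixel has been visited (NaN if never)."""
    first, _ = _visit_times(traj, pixel, float(traj.t[-1] + traj.dt))
    if not np.isfinite(first).all():
        return float("nan")
    return float(first.max())
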
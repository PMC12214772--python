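"""Peristaltic phase clock from the tracked-neuron trajectory.

Crawling is periodic: each stride the brain lurches in the direction of
travel and then rests.  The smoothed forward velocity of the tracked neuron
is therefore a quasi-periodic signal whose instantaneous (Hilbert) phase
serves as a behavioral clock.  Phase zero is anchored at maximal speed in
the direction of travel (forward speed maxima during forward crawling,
backward speed maxima during backward crawling); strides span consecutive
phase-zero crossings, and a per-stride B-spline time warp refines the clock
by aligning every stride's velocity profile to the mean stride template.

Bout labels (forward / backward / other intervals) are an input — from the
phantom ground truth or an external table — not derived here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal
from scipy.interpolate import BSpline, make_smoothing_spline
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "VelocityTrace",
    "PhaseClock",
    "StrideWarp",
    "forward_velocity",
    "hilbert_phase",
    "segment_strides",
    "warp_align",
    "phase_clock_for_bout",
    "DegeneratePhaseError",
    "InsufficientDataError",
]

#: csaps-convention smoothing parameter for the position spline; the
#: penalized least squares solved here uses lam = (1 - p) / p.
SMOOTHING_P = 0.99
DOG_SIGMA_S = 0.25


class DegeneratePhaseError(RuntimeError):
    """Velocity has no oscillation to extract a phase from."""


class InsufficientDataError(RuntimeError):
    """Track too short for the velocity filters."""


@dataclass
class VelocityTrace:
    """Uniformly sampled signed forward velocity (µm/s)."""

    t: np.ndarray
    v_fwd: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.v_fwd)):
            raise ValueError("velocity contains non-finite values")
        dt = np.diff(self.t)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("sampling must be uniform")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


@dataclass
class PhaseClock:
    """Unwrapped behavioral phase; 2 pi per stride, 0 at stride anchors."""

    t: np.ndarray
    phi: np.ndarray  # unwrapped, non-decreasing after warping
    mode: str = "forward"

    @property
    def phi_mod(self) -> np.ndarray:
        return np.mod(self.phi, 2 * math.pi)

    def phi_at(self, times: np.ndarray) -> np.ndarray:
        return np.interp(times, self.t, self.phi, left=np.nan, right=np.nan)


@dataclass
class StrideWarp:
    """Per-stride phase adjustment: cubic B-spline with 4 control values."""

    theta: np.ndarray  # (4,)
    _spline: BSpline = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if np.any(np.abs(self.theta) >= math.pi / 4):
            raise ValueError("warp exceeds the pi/4 bound")
        self._spline = _warp_spline(self.theta)

    def delta_phi(self, phi: np.ndarray) -> np.ndarray:
        return self._spline(np.clip(phi, 0.0, 2 * math.pi))


def _warp_spline(theta: np.ndarray) -> BSpline:
    # clamped cubic with exactly 4 coefficients over [0, 2 pi] (Bernstein)
    knots = np.array([0.0] * 4 + [2 * math.pi] * 4)
    return BSpline(knots, np.asarray(theta, dtype=float), 3, extrapolate=False)


# ----------------------------------------------------------------- velocity
def forward_velocity(
    t: np.ndarray,
    track_xy: np.ndarray,
    heading: np.ndarray,
    smoothing_p: float = SMOOTHING_P,
    dog_sigma: float = DOG_SIGMA_S,
) -> VelocityTrace:
    """Smoothed velocity of the tracked neuron along the heading (µm/s).

    The 2D path is denoised with a cubic smoothing spline (parameter ``p``
    in the convention minimizing ``p * sum (y-f)^2 + (1-p) * int f''^2``,
    i.e. penalty weight ``lam = (1-p)/p``), differentiated by a
    derivative-of-Gaussian filter, and projected on the unit heading.
    """
    t = np.asarray(t, dtype=float)
    track_xy = np.atleast_2d(np.asarray(track_xy, dtype=float))
    heading = np.atleast_2d(np.asarray(heading, dtype=float))
    if t.size != len(track_xy) or t.size != len(heading):
        raise ValueError("track and heading must be time-aligned")
    span = t[-1] - t[0]
    if span < 3.0 * dog_sigma:
        raise InsufficientDataError(
            f"track spans {span:.2f}s; need >= {3 * dog_sigma:.2f}s"
        )
    lam = (1.0 - smoothing_p) / smoothing_p
    dt = float(t[1] - t[0])
    vel = np.empty_like(track_xy)
    for ax in range(2):
        smooth = make_smoothing_spline(t, track_xy[:, ax], lam=lam)(t)
        vel[:, ax] = gaussian_filter1d(smooth, dog_sigma / dt, order=1, mode="nearest") / dt
    h = heading / np.maximum(np.linalg.norm(heading, axis=1, keepdims=True), 1e-12)
    return VelocityTrace(t=t, v_fwd=np.einsum("ni,ni->n", vel, h))


# -------------------------------------------------------------------- phase
def hilbert_phase(trace: VelocityTrace, mode: str = "forward") -> PhaseClock:
    """Raw Hilbert phase of the (de-meaned) velocity within one bout.

    Forward mode anchors phase 0 at forward-speed maxima; backward mode at
    backward-speed maxima (the analytic signal is built from the backward
    speed).  The returned phase is unwrapped and re-oriented to increase.
    """
    if mode not in ("forward", "backward"):
        raise ValueError("mode must be 'forward' or 'backward'")
    sign = 1.0 if mode == "forward" else -1.0
    v = sign * trace.v_fwd
    v = v - v.mean()
    if np.std(v) < 1e-12:
        raise DegeneratePhaseError("constant velocity: no phase defined")
    # H(x) = imag(analytic(x)); the analytic pair used is (v, H(-v))
    h = np.imag(signal.hilbert(-v))
    phi = np.unwrap(np.arctan2(h, v))
    if phi[-1] < phi[0]:
        phi = -phi
    return PhaseClock(t=trace.t.copy(), phi=phi - 0.0, mode=mode)


def segment_strides(
    clock: PhaseClock, drop_last: bool = True
) -> pd.DataFrame:
    """Stride intervals between consecutive phase-zero crossings.

    The i-th stride spans the i-th to (i+1)-th crossing of phase 0 (mod
    2 pi).  The last stride of the bout is excluded by default because the
    decelerating final cycle distorts phase averages.
    """
    phi, t = clock.phi, clock.t
    k0 = math.ceil(phi[0] / (2 * math.pi))
    k1 = math.floor(phi[-1] / (2 * math.pi))
    crossings = []
    for k in range(k0, k1 + 1):
        idx = np.searchsorted(phi, 2 * math.pi * k)
        if idx == 0:
            crossings.append(t[0])
        else:
            lo, hi = idx - 1, min(idx, t.size - 1)
            if phi[hi] == phi[lo]:
                crossings.append(t[lo])
            else:
                f = (2 * math.pi * k - phi[lo]) / (phi[hi] - phi[lo])
                crossings.append(t[lo] + f * (t[hi] - t[lo]))
    if len(crossings) < 2:
        return pd.DataFrame(columns=["start_s", "end_s", "stride"])
    starts = np.array(crossings[:-1])
    ends = np.array(crossings[1:])
    if drop_last:
        starts, ends = starts[:-1], ends[:-1]
    return pd.DataFrame(
        {"start_s": starts, "end_s": ends, "stride": np.arange(len(starts))}
    )


# --------------------------------------------------------------------- warp
_PHI_GRID = np.linspace(0.0, 2 * math.pi, 65)[:-1]


def _stride_velocity(
    clock: PhaseClock, trace: VelocityTrace, stride_index: int
) -> tuple[np.ndarray, np.ndarray]:
    """(phi_local, v) samples of one stride, extended pi/4 both ways."""
    base = 2 * math.pi * (math.ceil(clock.phi[0] / (2 * math.pi)) + stride_index)
    lo, hi = base - math.pi / 4, base + 2 * math.pi + math.pi / 4
    sel = (clock.phi >= lo) & (clock.phi <= hi)
    return clock.phi[sel] - base, trace.v_fwd[sel]


def warp_align(
    clock: PhaseClock,
    trace: VelocityTrace,
    strides: pd.DataFrame | None = None,
    max_shift: float = math.pi / 4,
) -> tuple[np.ndarray, list[StrideWarp], PhaseClock]:
    """Align every stride's velocity profile to the mean stride template.

    Returns the template ``v(phi)`` on a fixed phase grid, one
    :class:`StrideWarp` per stride, and the refined clock with the per-
    stride adjustments mapped back to the time axis (discontinuities at
    stride joins cross-faded over ±pi/8, then made non-decreasing).
    """
    if strides is None:
        strides = segment_strides(clock)
    n = len(strides)
    if n < 3:
        raise InsufficientDataError("warp alignment needs at least 3 strides")
    per_stride = [_stride_velocity(clock, trace, i) for i in range(n)]
    template = np.mean(
        [np.interp(_PHI_GRID, p, v) for p, v in per_stride], axis=0
    )
    warps: list[StrideWarp] = []
    hit_bound = 0
    eps = 1e-6
    for p, v in per_stride:

        def cost(theta, p=p, v=v):
            dphi = _warp_spline(theta)(_PHI_GRID)
            shifted = np.interp(_PHI_GRID + dphi, p, v)
            return float(((shifted - template) ** 2).sum())

        res = optimize.minimize(
            cost, np.zeros(4), method="L-BFGS-B",
            bounds=[(-max_shift + eps, max_shift - eps)] * 4,
        )
        if np.any(np.abs(res.x) >= max_shift - 10 * eps):
            hit_bound += 1
        warps.append(StrideWarp(theta=res.x))
    if hit_bound > n / 2:
        import warnings

        warnings.warn(
            f"{hit_bound}/{n} strides hit the warp bound: template mismatch?",
            stacklevel=2,
        )
    # map adjusted phases back to the time axis
    phi_new = clock.phi.copy()
    base0 = 2 * math.pi * math.ceil(clock.phi[0] / (2 * math.pi))
    fade = math.pi / 8
    for i, w in enumerate(warps):
        base = base0 + 2 * math.pi * i
        local = clock.phi - base
        sel = (local >= 0) & (local < 2 * math.pi)
        dphi = w.delta_phi(local[sel])
        # cross-fade the adjustment to zero at both stride joins
        ramp = np.clip(local[sel] / fade, 0, 1) * np.clip(
            (2 * math.pi - local[sel]) / fade, 0, 1
        )
        phi_new[sel] = clock.phi[sel] + dphi * ramp
    phi_new = np.maximum.accumulate(phi_new)
    return template, warps, PhaseClock(t=clock.t.copy(), phi=phi_new, mode=clock.mode)


# ------------------------------------------------------------------- driver
def phase_clock_for_bout(
    t: np.ndarray,
    track_xy: np.ndarray,
    heading: np.ndarray,
    mode: str,
) -> tuple[PhaseClock, pd.DataFrame, np.ndarray]:
    """Velocity -> raw phase -> strides -> warped clock, for one bout.

    Returns the refined clock, the stride table and the stride template.
    """
    trace = forward_velocity(t, track_xy, heading)
    raw = hilbert_phase(trace, mode=mode)
    strides = segment_strides(raw)
    if len(strides) >= 3:
        template, _, refined = warp_align(raw, trace)
        strides = segment_strides(refined)
    else:
        template, refined = np.array([]), raw
    return refined, strides, template
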
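"""Closed-loop 3-axis tracking of a reference neuron.

The tracking beam circles the putative neuron center with radius ``R`` in
the focal plane while the TAG lens sweeps the focus axially; the photons
detected during one ~350 µs revolution are located at the beam position at
their arrival time, gated axially to ``|z| <= Z`` around the current
estimate, and averaged.  That center of mass is fused with the running
per-axis estimate by a one-dimensional Kalman filter whose process noise
``D`` (units of a diffusion constant) sets the responsiveness of the loop.
The next revolution is centered on the updated estimate; a slow stage loop
re-centers the working point every 25 ms.

Shot noise limits a single measurement to roughly ``sigma_xy = R / sqrt(N)``
(2D radial error) and ``sigma_z = Z / sqrt(N)`` for ``N`` detected photons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phantom import Phantom

__all__ = [
    "TrackerConfig",
    "TrackState",
    "TrackEstimate",
    "TrackRecord",
    "TrackingLostError",
    "cylinder_offsets",
    "estimate_position",
    "kalman_update",
    "closed_loop_track",
]


class TrackingLostError(RuntimeError):
    """Raised when the tracker sees no photons for too many cycles."""


@dataclass(frozen=True)
class TrackerConfig:
    """Tracking-scan geometry and loop parameters."""

    r_scan: float = 3.0  # cylinder radius R (µm)
    z_gate: float = 5.0  # axial gate half-height Z (µm)
    rev_rate: float = 2857.0  # revolutions/s (~350 µs per cycle, <= 3000)
    a_track: float = 15.0  # tracking TAG half-amplitude (µm)
    f_tag: float = 1.9e5  # Hz, axial resonance
    d_responsiveness: float = 2000.0  # Kalman process parameter D (µm²/s)
    stage_period: float = 0.025  # s between stage re-centering steps
    stage_gain: float = 0.5  # proportional stage step toward the estimate
    lost_after: int = 30  # consecutive empty cycles before giving up

    def __post_init__(self) -> None:
        if self.r_scan <= 0 or self.z_gate <= 0:
            raise ValueError("r_scan and z_gate must be positive")
        if not (0 < self.rev_rate <= 3000):
            raise ValueError("rev_rate must be in (0, 3000] rev/s")

    @property
    def cycle_period(self) -> float:
        return 1.0 / self.rev_rate


@dataclass
class TrackState:
    """Per-axis position estimate and variance."""

    pos: np.ndarray  # (3,) µm
    var: np.ndarray  # (3,) µm²
    t: float = 0.0

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float).copy()
        self.var = np.asarray(self.var, dtype=float).copy()
        if np.any(self.var <= 0):
            raise ValueError("variances must be positive")


@dataclass(frozen=True)
class TrackEstimate:
    """One cylinder-scan measurement."""

    com: np.ndarray  # (3,) µm, center of mass of gated photons
    sigma: np.ndarray  # (3,) µm, shot-noise scale (R/sqrt N, R/sqrt N, Z/sqrt N)
    n_photons: int


@dataclass
class TrackRecord:
    """Closed-loop tracking output: one row per measurement cycle."""

    table: pd.DataFrame = field(repr=False)

    @property
    def rms_error(self) -> float:
        e = self.table[["est_x_um", "est_y_um", "est_z_um"]].to_numpy() - self.table[
            ["true_x_um", "true_y_um", "true_z_um"]
        ].to_numpy()
        return float(np.sqrt((e**2).sum(axis=1).mean()))

    @property
    def max_error(self) -> float:
        e = self.table[["est_x_um", "est_y_um", "est_z_um"]].to_numpy() - self.table[
            ["true_x_um", "true_y_um", "true_z_um"]
        ].to_numpy()
        return float(np.sqrt((e**2).sum(axis=1)).max())


def cylinder_offsets(cfg: TrackerConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One revolution of the tracking cylinder, one axial line per sample.

    Returns ``(t_rel, xy, phi0)``: sample times within the cycle, in-plane
    beam offsets (n, 2) on the circle of radius R, and the TAG phase at
    each line start (the focus sweeps ``a_track * cos(phi)`` within a line).
    """
    dt = 1.0 / (2.0 * cfg.f_tag)
    n = max(2, int(round(cfg.cycle_period / dt)))
    t = np.arange(n) * dt
    theta = 2 * math.pi * cfg.rev_rate * t
    xy = np.stack([cfg.r_scan * np.cos(theta), cfg.r_scan * np.sin(theta)], axis=1)
    phi0 = (math.pi * np.arange(n)) % (2 * math.pi)
    return t, xy, phi0


def estimate_position(
    photons: np.ndarray, cfg: TrackerConfig, z_center: float = 0.0
) -> TrackEstimate | None:
    """Center of mass of photons passing the axial gate; None if empty.

    ``photons`` are located photon coordinates (n, 3) relative to the scan
    center; only those with ``|z - z_center| <= z_gate`` contribute.
    """
    photons = np.atleast_2d(np.asarray(photons, dtype=float))
    if photons.size == 0:
        return None
    keep = np.abs(photons[:, 2] - z_center) <= cfg.z_gate
    n = int(keep.sum())
    if n == 0:
        return None
    com = photons[keep].mean(axis=0)
    sig = np.array([cfg.r_scan, cfg.r_scan, cfg.z_gate]) / math.sqrt(n)
    return TrackEstimate(com=com, sigma=sig, n_photons=n)


def kalman_update(
    state: TrackState,
    est: TrackEstimate | None,
    dt: float,
    d: float,
) -> TrackState:
    """One predict/update step of the per-axis position Kalman filter.

    Prediction inflates the variance by ``d * dt``; a missing measurement
    leaves the position at the prior.  The gain is
    ``K = sigma'^2 / (sigma'^2 + sigma_m^2)`` per axis.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    var_prior = state.var + d * dt
    if est is None:
        return TrackState(pos=state.pos.copy(), var=var_prior, t=state.t + dt)
    var_m = est.sigma**2
    gain = var_prior / (var_prior + var_m)
    pos = (1 - gain) * state.pos + gain * est.com
    var = (1 - gain) * var_prior
    return TrackState(pos=pos, var=var, t=state.t + dt)


def closed_loop_track(
    phantom: Phantom,
    cfg: TrackerConfig,
    duration: float,
    seed: int = 0,
    t0: float = 0.0,
    record_every: int = 1,
) -> TrackRecord:
    """Simulate the full closed loop on the phantom's reference neuron.

    Each ~350 µs cycle: scan a cylinder centered on the current estimate,
    draw red photons from the phantom, take the gated center of mass, and
    fuse it into the Kalman state.  The galvo/piezo offsets follow the
    estimate instantaneously; the stage re-centers every ``stage_period``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7261636B]))
    dt_samp = 1.0 / (2.0 * cfg.f_tag)
    sample_t_rel, xy_off, phi0 = cylinder_offsets(cfg)
    n_cycles = int(duration / cfg.cycle_period)
    start = phantom.reference_path(np.array([t0]))[0]
    state = TrackState(pos=start, var=np.full(3, cfg.r_scan**2))
    stage = start.copy()
    rows = []
    empty_streak = 0
    mask = None
    next_stage_t = cfg.stage_period
    for i in range(n_cycles):
        tc = t0 + i * cfg.cycle_period
        if i % 64 == 0:  # refresh the nearby-emitter mask
            lab = phantom.emitter_lab_positions(np.array([tc]))[0]
            mask = np.linalg.norm(lab - state.pos, axis=1) < 40.0
            if not mask.any():
                mask = None
        times = tc + sample_t_rel
        t_ph, pos_ph = phantom.line_photons(
            xy_off + state.pos[:2], phi0, times, dt_samp, cfg.a_track,
            "red", rng, center_z=state.pos[2], emitter_mask=mask,
        )
        photons = pos_ph - state.pos  # relative to the scan center
        est = estimate_position(photons, cfg)
        if est is None:
            empty_streak += 1
            if empty_streak > cfg.lost_after:
                raise TrackingLostError(
                    f"no gated photons for {empty_streak} consecutive cycles at t={tc:.4f}s"
                )
        else:
            empty_streak = 0
        meas = (
            None
            if est is None
            else TrackEstimate(com=state.pos + est.com, sigma=est.sigma, n_photons=est.n_photons)
        )
        state = kalman_update(state, meas, cfg.cycle_period, cfg.d_responsiveness)
        if (i + 1) * cfg.cycle_period >= next_stage_t:
            stage = stage + cfg.stage_gain * (state.pos - stage)
            next_stage_t += cfg.stage_period
        if i % record_every == 0:
            true = phantom.reference_path(np.array([tc + cfg.cycle_period]))[0]
            rows.append(
                (
                    tc + cfg.cycle_period,
                    *state.pos,
                    *true,
                    *np.sqrt(state.var),
                    0 if est is None else est.n_photons,
                    *stage,
                )
            )
    cols = [
        "t_s",
        "est_x_um", "est_y_um", "est_z_um",
        "true_x_um", "true_y_um", "true_z_um",
        "sigma_x_um", "sigma_y_um", "sigma_z_um",
        "n_photons",
        "stage_x_um", "stage_y_um", "stage_z_um",
    ]
    return TrackRecord(table=pd.DataFrame(rows, columns=cols))
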
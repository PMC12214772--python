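"""Synthetic crawling nerve-cord phantom with ground-truth activity.

The phantom emulates a larval ventral nerve cord imaged through a tracking
two-photon microscope: a ladder of segmentally repeated cells expressing a
stable red fluorophore and a green activity reporter, crawling with
stride-locked velocity pulses (peak speed up to ~1 mm/s), slowly rotating in
the plane, bending non-rigidly, and carrying a phase-locked traveling wave
of green activity during crawling bouts.  An off-axis autofluorescent rod
stands in for background structures such as the esophagus.

Cells are isotropic Gaussian fluorophore blobs; convolved with the (also
Gaussian) excitation point-spread function this gives an analytic photon
rate at any focal position, so photon emission along an arbitrary scan
trajectory is an inhomogeneous Poisson process that can be sampled exactly
at the trajectory's own time resolution.

Everything is deterministic given the configuration and a seed, and all
ground truth (pose, deformation, bout/stride times, wave phase) is exposed
for the downstream modules' recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._bspline import BSplineField
from .scan import ScanTrajectory

__all__ = [
    "PhantomConfig",
    "BoutSpec",
    "PoseTruth",
    "BehaviorTruth",
    "Phantom",
    "build_phantom",
    "LASER_PERIOD_NS",
    "TRACKING_PHASE_OFFSET_NS",
]

#: Pulsed-laser repetition period (ns); the two excitation lasers are
#: interleaved by half of this for temporal demultiplexing.
LASER_PERIOD_NS = 1e9 / 70e6
TRACKING_PHASE_OFFSET_NS = LASER_PERIOD_NS / 2.0
#: Mean fluorescence + detection delay after the excitation pulse (ns);
#: keeps photon arrivals inside their path's demultiplexing half-window.
ARRIVAL_LAG_NS = 1.8

# wave-class codes
CLASS_NONE, CLASS_FORWARD, CLASS_BACKWARD = 0, 1, 2
_STATE_CODE = {"other": 0, "forward": 1, "backward": 2}


@dataclass(frozen=True)
class BoutSpec:
    """One behavioral bout: ``state`` is forward / backward / other."""

    state: str
    n_strides: int = 6
    stride_period: float = 1.0  # s
    pause_after: float = 1.0  # s of quiescence following the bout

    def __post_init__(self) -> None:
        if self.state not in _STATE_CODE:
            raise ValueError(f"unknown bout state {self.state!r}")

    @property
    def duration(self) -> float:
        return self.n_strides * self.stride_period


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, photophysics and motion of the synthetic nerve cord.

    Rates are peak photon count rates (counts/s) at the focus when the beam
    sits on a cell center.  The body axis runs along +x (anterior positive);
    ``s`` coordinates used by the activity wave are body-axis positions.
    """

    # --- geometry (ladder of segments) ---
    n_segments: int = 8
    segment_spacing: float = 25.0  # µm between rungs
    cell_radius: float = 3.0  # Gaussian sigma of a cell body (µm)
    lateral_offset: float = 20.0  # |y| of the lateral cell columns (µm)
    # --- photophysics ---
    red_rate: float = 5e6  # counts/s at focus, stable channel
    green_base: float = 3e6  # counts/s at focus, activity channel baseline
    wave_amplitude: float = 0.6  # relative modulation m in [0, 1]
    wave_vector: float = 2 * math.pi / 200.0  # µm^-1 along the body axis
    forward_class: str = "medial"  # which column carries the forward wave
    backward_class: str = "lateral"
    psf_sigma_lateral: float = 0.5  # µm
    psf_sigma_axial: float = 1.5  # µm
    background_rate: float = 2e5  # autofluorescent rod, both channels
    # --- motion ---
    bouts: tuple[BoutSpec, ...] = (
        BoutSpec("forward", n_strides=6),
        BoutSpec("backward", n_strides=4),
    )
    start_pause: float = 1.0  # quiescent lead-in (s)
    peak_speed: float = 800.0  # µm/s at the stride-pulse peak
    stride_displacement: float = 100.0  # µm traveled per stride
    rotation_amplitude: float = 0.0  # rad, slow in-plane wobble
    rotation_period: float = 8.0  # s
    tilt_amplitude: float = 0.0  # rad, out-of-plane wobble
    z_bob_amplitude: float = 2.0  # µm per-stride axial bob
    deform_amplitude: float = 0.0  # µm, peak non-rigid displacement
    deform_grid_spacing: float = 50.0  # µm, control spacing of the truth FFD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_segments < 1:
            raise ValueError("need at least one segment")
        if self.cell_radius <= 0:
            raise ValueError("cell_radius must be positive")
        if self.segment_spacing <= 2 * self.cell_radius:
            raise ValueError("segments overlap: spacing must exceed cell diameter")
        if not (0.0 <= self.wave_amplitude <= 1.0):
            raise ValueError("wave_amplitude must lie in [0, 1]")
        for r in (self.red_rate, self.green_base, self.background_rate):
            if r < 0:
                raise ValueError("rates must be non-negative")
        if self.psf_sigma_lateral <= 0 or self.psf_sigma_axial <= 0:
            raise ValueError("PSF sigmas must be positive")

    @property
    def duration(self) -> float:
        """Total simulation horizon (s)."""
        total = self.start_pause
        for b in self.bouts:
            total += b.duration + b.pause_after
        return total


@dataclass
class PoseTruth:
    """Rigid part of the phantom pose at given times (vectorised)."""

    t: np.ndarray
    translation: np.ndarray  # (n, 3) µm
    angle: np.ndarray  # (n,) rad, in-plane
    tilt: np.ndarray  # (n,) rad, about the y axis
    deform_envelope: np.ndarray  # (n,) scale of the deformation field


@dataclass
class BehaviorTruth:
    """Bout intervals, stride boundaries and the true peristaltic phase."""

    bouts: list[tuple[str, float, float]]  # (state, t_start, t_end)
    stride_times: dict[int, np.ndarray]  # bout index -> phi=0 crossing times

    def state_at(self, t: np.ndarray) -> np.ndarray:
        """Behavioral-state code (0 other, 1 forward, 2 backward) per time."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.zeros(t.shape, dtype=np.int8)
        for state, t0, t1 in self.bouts:
            out[(t >= t0) & (t < t1)] = _STATE_CODE[state]
        return out

    def bout_intervals(self, state: str) -> list[tuple[float, float]]:
        return [(t0, t1) for s, t0, t1 in self.bouts if s == state]


class Phantom:
    """Realised phantom: emitters + motion model + behavior ground truth."""

    def __init__(self, cfg: PhantomConfig):
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x9E3779B9]))
        self._build_emitters()
        self._build_motion(rng)

    # ------------------------------------------------------------------ setup
    def _build_emitters(self) -> None:
        cfg = self.cfg
        half = (cfg.n_segments - 1) * cfg.segment_spacing / 2.0
        s = np.arange(cfg.n_segments) * cfg.segment_spacing - half  # body axis
        pos, classes = [], []
        med_cls = CLASS_FORWARD if cfg.forward_class == "medial" else CLASS_BACKWARD
        lat_cls = CLASS_BACKWARD if cfg.backward_class == "lateral" else CLASS_FORWARD
        for si in s:
            pos.append((si, 0.0, 0.0))  # midline process
            classes.append(med_cls)
            for sign in (+1.0, -1.0):
                pos.append((si, sign * cfg.lateral_offset, 0.0))
                classes.append(lat_cls)
        self.positions = np.array(pos, dtype=float)  # body coords, (K, 3)
        self.wave_class = np.array(classes, dtype=np.int8)
        k = len(pos)
        self.sigma = np.full(k, cfg.cell_radius)
        self.rate_red = np.full(k, cfg.red_rate)
        self.rate_green = np.full(k, cfg.green_base)

        # tracked reference neuron: laterally offset from the ladder (so the
        # imaging field centered on it still contains every segment),
        # brighter in red, not part of the wave
        self.reference_index = k
        self._add_emitter((0.0, -1.75 * cfg.lateral_offset, 0.0), CLASS_NONE,
                          cfg.cell_radius, 2.0 * cfg.red_rate, 0.5 * cfg.green_base)

        # autofluorescent background rod, off-axis, both channels
        if cfg.background_rate > 0:
            for si in np.linspace(-half, half, 5):
                self._add_emitter(
                    (si, -3.0 * cfg.lateral_offset, -10.0), CLASS_NONE,
                    2.0 * cfg.cell_radius, cfg.background_rate, cfg.background_rate,
                )
        self.s_coord = self.positions[:, 0].copy()

    def _add_emitter(self, p, cls, sigma, red, green) -> None:
        self.positions = np.vstack([self.positions, [p]])
        self.wave_class = np.append(self.wave_class, np.int8(cls))
        self.sigma = np.append(self.sigma, sigma)
        self.rate_red = np.append(self.rate_red, red)
        self.rate_green = np.append(self.rate_green, green)

    def _build_motion(self, rng: np.random.Generator) -> None:
        cfg = self.cfg
        # bout schedule and stride-pulse centers
        bouts: list[tuple[str, float, float]] = []
        pulses: list[tuple[float, float, float]] = []  # (center, period, sign)
        stride_times: dict[int, np.ndarray] = {}
        t = cfg.start_pause
        for bi, b in enumerate(cfg.bouts):
            t0, t1 = t, t + b.duration
            if b.state in ("forward", "backward"):
                bouts.append((b.state, t0, t1))
                sign = 1.0 if b.state == "forward" else -1.0
                centers = t0 + (np.arange(b.n_strides) + 0.5) * b.stride_period
                pulses.extend((c, b.stride_period, sign) for c in centers)
                stride_times[bi] = centers
            t = t1 + b.pause_after
        self.behavior = BehaviorTruth(bouts=bouts, stride_times=stride_times)
        self._pulses = pulses

        # stride pulse: truncated Gaussian in stride fraction, area-normalised
        # so each pulse advances the body by stride_displacement
        self._pulse_sigma_frac = cfg.stride_displacement / (
            cfg.peak_speed * math.sqrt(2 * math.pi)
        )

        # dense kinematic grid: C^1 pose by construction
        dt = 1e-3
        tg = np.arange(0.0, cfg.duration + dt, dt)
        ang = cfg.rotation_amplitude * np.sin(2 * math.pi * tg / cfg.rotation_period)
        tilt = cfg.tilt_amplitude * np.sin(2 * math.pi * tg / (1.37 * cfg.rotation_period))
        speed = self._speed_profile(tg)
        heading = np.stack([np.cos(ang), np.sin(ang)], axis=1)
        vel = np.zeros((tg.size, 3))
        vel[:, :2] = speed[:, None] * heading
        vel[:, 2] = self._z_bob_velocity(tg)
        trans = np.concatenate(
            [np.zeros((1, 3)), np.cumsum(0.5 * (vel[1:] + vel[:-1]) * dt, axis=0)]
        )
        self._grid_t = tg
        self._grid_translation = trans
        self._grid_angle = ang
        self._grid_tilt = tilt

        # non-rigid deformation: a fixed random smooth FFD scaled by a slow
        # envelope; same parameterisation as the registration module
        half = (cfg.n_segments + 2) * cfg.segment_spacing / 2.0
        extent = np.array([2 * half + 40.0, 3 * cfg.lateral_offset + 40.0, 60.0])
        origin = np.array([-extent[0] / 2, -extent[1] / 2, -30.0])
        fld = BSplineField.zeros(origin, extent, cfg.deform_grid_spacing, m=3)
        raw = rng.standard_normal(fld.coefs.shape)
        fld.coefs = raw
        if cfg.deform_amplitude > 0:
            # normalise so the peak displacement inside the body is amplitude
            probe = self.positions + rng.normal(0, 5.0, self.positions.shape)
            peak = np.abs(fld(np.vstack([self.positions, probe]))).max()
            fld.coefs *= cfg.deform_amplitude / max(peak, 1e-12)
        else:
            fld.coefs *= 0.0
        self.deformation_field = fld

    def _speed_profile(self, t: np.ndarray) -> np.ndarray:
        """Signed speed along the heading (µm/s): sum of stride pulses."""
        out = np.zeros_like(t, dtype=float)
        for c, period, sign in self._pulses:
            w = self._pulse_sigma_frac * period
            g = np.exp(-0.5 * ((t - c) / w) ** 2)
            edge = math.exp(-0.5 * (0.5 / self._pulse_sigma_frac) ** 2)
            out += sign * self.cfg.peak_speed * np.clip(g - edge, 0.0, None) / (1 - edge)
        return out

    def _z_bob_velocity(self, t: np.ndarray) -> np.ndarray:
        if self.cfg.z_bob_amplitude == 0:
            return np.zeros_like(t)
        out = np.zeros_like(t, dtype=float)
        for c, period, _sign in self._pulses:
            w = 2 * self._pulse_sigma_frac * period
            arg = (t - c) / w
            # derivative of a Gaussian bump: zero net displacement per stride
            out += -self.cfg.z_bob_amplitude * arg * np.exp(-0.5 * arg**2) / w
        return out

    # --------------------------------------------------------------- kinematics
    def pose_at(self, t: np.ndarray | float) -> PoseTruth:
        """Interpolated rigid pose + deformation envelope at times ``t``."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if t.max() > self._grid_t[-1] + 1e-9 or t.min() < -1e-9:
            raise ValueError("t outside the simulation horizon")
        trans = np.stack(
            [np.interp(t, self._grid_t, self._grid_translation[:, i]) for i in range(3)],
            axis=1,
        )
        ang = np.interp(t, self._grid_t, self._grid_angle)
        tilt = np.interp(t, self._grid_t, self._grid_tilt)
        return PoseTruth(
            t=t, translation=trans, angle=ang, tilt=tilt,
            deform_envelope=self.deform_envelope(t),
        )

    def deform_envelope(self, t: np.ndarray) -> np.ndarray:
        """Slow 0..1 envelope scaling the deformation field over time."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self.cfg.deform_amplitude == 0:
            return np.zeros_like(t)
        return 0.5 - 0.5 * np.cos(2 * math.pi * t / self.cfg.rotation_period)

    def phi_true(self, t: np.ndarray | float) -> np.ndarray:
        """True peristaltic phase (rad); 0 at each stride-pulse peak.

        Increases by 2 pi per stride inside crawling bouts; NaN outside.
        """
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.full(t.shape, np.nan)
        keys = sorted(self.behavior.stride_times)  # crawling bouts, in order
        for (state, t0, t1), key in zip(self.behavior.bouts, keys):
            period = self.cfg.bouts[key].stride_period
            sel = (t >= t0) & (t < t1)
            first_peak = self.behavior.stride_times[key][0]
            out[sel] = 2 * math.pi * (t[sel] - first_peak) / period
        return out

    def heading_at(self, t: np.ndarray | float) -> np.ndarray:
        """Unit heading vector (body +x axis in the lab frame), shape (n, 2)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        ang = np.interp(t, self._grid_t, self._grid_angle)
        return np.stack([np.cos(ang), np.sin(ang)], axis=1)

    def reference_path(self, t: np.ndarray) -> np.ndarray:
        """Lab-frame position of the tracked reference neuron, shape (n, 3)."""
        return self.emitter_lab_positions(np.atleast_1d(t))[:, self.reference_index, :]

    def emitter_lab_positions(self, t: np.ndarray) -> np.ndarray:
        """Lab positions of all emitters at times ``t`` -> (n, K, 3)."""
        pose = self.pose_at(t)
        body = self.positions[None, :, :] + (
            pose.deform_envelope[:, None, None]
            * self.deformation_field(self.positions)[None, :, :]
        )
        return self._rigid_apply(body, pose)

    @staticmethod
    def _rigid_apply(body: np.ndarray, pose: PoseTruth) -> np.ndarray:
        ca, sa = np.cos(pose.angle)[:, None], np.sin(pose.angle)[:, None]
        ct, st = np.cos(pose.tilt)[:, None], np.sin(pose.tilt)[:, None]
        x, y, z = body[..., 0], body[..., 1], body[..., 2]
        # tilt about y, then in-plane rotation about z, then translation
        x1 = ct * x + st * z
        z1 = -st * x + ct * z
        x2 = ca * x1 - sa * y
        y2 = sa * x1 + ca * y
        out = np.stack([x2, y2, z1], axis=-1)
        return out + pose.translation[:, None, :]

    # ----------------------------------------------------------------- activity
    def activity_gain(
        self, t: np.ndarray, which_class: np.ndarray | None = None
    ) -> np.ndarray:
        """Green-channel gain per emitter at times ``t`` -> (n, K).

        During a forward bout, forward-class cells see
        ``1 + m cos(k s - phi_true)``; during a backward bout, backward-class
        cells see the reversed wave ``1 + m cos(-k s - phi_true)``.  All other
        combinations have gain 1.
        """
        t = np.atleast_1d(np.asarray(t, dtype=float))
        cls = self.wave_class if which_class is None else which_class
        state = self.behavior.state_at(t)
        phi = self.phi_true(t)
        m, k = self.cfg.wave_amplitude, self.cfg.wave_vector
        gain = np.ones((t.size, cls.size))
        for code, ksign in ((CLASS_FORWARD, 1.0), (CLASS_BACKWARD, -1.0)):
            rows = state == code
            cols = cls == code
            if rows.any() and cols.any():
                wave = 1.0 + m * np.cos(
                    ksign * k * self.s_coord[None, cols] - phi[rows, None]
                )
                gain[np.ix_(rows, cols)] = wave
        return gain

    def activity_at(self, points_body: np.ndarray, t: np.ndarray | float) -> np.ndarray:
        """Activity gain at arbitrary body points, treated as forward-class."""
        pts = np.atleast_2d(np.asarray(points_body, dtype=float))
        saved_s, saved_cls = self.s_coord, self.wave_class
        try:
            self.s_coord = pts[:, 0]
            cls = np.full(len(pts), CLASS_FORWARD, dtype=np.int8)
            return self.activity_gain(np.atleast_1d(t), which_class=cls)
        finally:
            self.s_coord, self.wave_class = saved_s, saved_cls

    # ------------------------------------------------------------------ photons
    def rate(
        self,
        focal: np.ndarray,
        t: np.ndarray,
        channel: str,
        emitter_mask: np.ndarray | None = None,
        chunk: int = 200_000,
    ) -> np.ndarray:
        """Photon rate (counts/s) at lab focal positions ``focal`` (n, 3).

        The rate is the fluorophore density warped through the current pose
        and convolved with the Gaussian PSF, evaluated at the focus; for
        Gaussian cells this is a sum of Gaussians with pooled widths.
        """
        focal = np.atleast_2d(np.asarray(focal, dtype=float))
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if channel not in ("red", "green"):
            raise ValueError(f"unknown channel {channel!r}")
        amp = self.rate_red if channel == "red" else self.rate_green
        idx = np.arange(len(self.positions))
        if emitter_mask is not None:
            idx = idx[emitter_mask]
        cfg = self.cfg
        if not hasattr(self, "_emitter_deform"):
            self._emitter_deform = self.deformation_field(self.positions)
        m, kvec = cfg.wave_amplitude, cfg.wave_vector
        out = np.zeros(t.size)
        for lo in range(0, t.size, chunk):
            sl = slice(lo, min(lo + chunk, t.size))
            pose = self.pose_at(t[sl])
            ca, sa = np.cos(pose.angle), np.sin(pose.angle)
            ct, st = np.cos(pose.tilt), np.sin(pose.tilt)
            env = pose.deform_envelope
            fx, fy, fz = focal[sl, 0], focal[sl, 1], focal[sl, 2]
            if channel == "green":
                state = self.behavior.state_at(t[sl])
                phi = self.phi_true(t[sl])
            acc = np.zeros(fx.size)
            for e in idx:
                p, de = self.positions[e], self._emitter_deform[e]
                px = p[0] + env * de[0]
                py = p[1] + env * de[1]
                pz = p[2] + env * de[2]
                x1 = ct * px + st * pz
                z1 = -st * px + ct * pz
                dx = fx - (ca * x1 - sa * py + pose.translation[:, 0])
                dy = fy - (sa * x1 + ca * py + pose.translation[:, 1])
                dz = fz - (z1 + pose.translation[:, 2])
                s2_lat = self.sigma[e] ** 2 + cfg.psf_sigma_lateral**2
                s2_ax = self.sigma[e] ** 2 + cfg.psf_sigma_axial**2
                q = (dx * dx + dy * dy) / (2 * s2_lat) + dz * dz / (2 * s2_ax)
                contrib = amp[e] * np.exp(-np.minimum(q, 50.0))
                cls = self.wave_class[e]
                if channel == "green" and cls != CLASS_NONE:
                    ksign = 1.0 if cls == CLASS_FORWARD else -1.0
                    active = state == cls
                    gain = np.ones(fx.size)
                    gain[active] = 1.0 + m * np.cos(
                        ksign * kvec * self.s_coord[e] - phi[active]
                    )
                    contrib = contrib * gain
                acc += contrib
            out[sl] = acc
        return out

    def line_photons(
        self,
        xy: np.ndarray,
        phi0: np.ndarray,
        t: np.ndarray,
        dt: float,
        a_tag: float,
        channel: str,
        rng: np.random.Generator,
        center_z: np.ndarray | float = 0.0,
        power: float = 1.0,
        emitter_mask: np.ndarray | None = None,
        chunk: int = 200_000,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Exact photon draws along axial scan lines by Poisson thinning.

        Each row of ``xy`` (lab µm) is one axial line starting at TAG phase
        ``phi0`` and sweeping ``z = a_tag cos(phi) + center_z`` over half a
        resonance period ``dt``.  For every (line, emitter) pair, candidate
        photons are drawn from a Poisson bound built from the lateral
        Gaussian times the axial maximum over the line, placed uniformly in
        phase (the physical dwell measure), and thinned by the true axial
        factor — an exact draw from the inhomogeneous Poisson process.

        Returns ``(t_photon, position)`` with positions (n, 3) in the lab
        frame, unsorted.
        """
        if power < 0:
            raise ValueError("negative power")
        if channel not in ("red", "green"):
            raise ValueError(f"unknown channel {channel!r}")
        amp = (self.rate_red if channel == "red" else self.rate_green) * power
        idx = np.arange(len(self.positions))
        if emitter_mask is not None:
            idx = idx[emitter_mask]
        if not hasattr(self, "_emitter_deform"):
            self._emitter_deform = self.deformation_field(self.positions)
        cfg = self.cfg
        m, kvec = cfg.wave_amplitude, cfg.wave_vector
        cz_all = np.broadcast_to(np.asarray(center_z, dtype=float), t.shape)
        out_t, out_p = [], []
        for lo in range(0, t.size, chunk):
            sl = slice(lo, min(lo + chunk, t.size))
            pose = self.pose_at(t[sl])
            ca, sa = np.cos(pose.angle), np.sin(pose.angle)
            ct, st = np.cos(pose.tilt), np.sin(pose.tilt)
            env = pose.deform_envelope
            fx, fy = xy[sl, 0], xy[sl, 1]
            cz = cz_all[sl]
            tt = t[sl]
            ph0 = phi0[sl]
            if channel == "green":
                state = self.behavior.state_at(tt)
                phi_b = self.phi_true(tt)
            for e in idx:
                p, de = self.positions[e], self._emitter_deform[e]
                px = p[0] + env * de[0]
                py = p[1] + env * de[1]
                pz = p[2] + env * de[2]
                x1 = ct * px + st * pz
                z1 = -st * px + ct * pz
                ex = ca * x1 - sa * py + pose.translation[:, 0]
                ey = sa * x1 + ca * py + pose.translation[:, 1]
                ez = z1 + pose.translation[:, 2]
                s2_lat = self.sigma[e] ** 2 + cfg.psf_sigma_lateral**2
                s2_ax = self.sigma[e] ** 2 + cfg.psf_sigma_axial**2
                q = ((fx - ex) ** 2 + (fy - ey) ** 2) / (2 * s2_lat)
                lat = np.exp(-np.minimum(q, 40.0))
                dzc = np.abs(ez - cz)
                g_max = np.where(
                    dzc <= a_tag,
                    1.0,
                    np.exp(-np.minimum((dzc - a_tag) ** 2 / (2 * s2_ax), 40.0)),
                )
                gain = 1.0
                cls = self.wave_class[e]
                if channel == "green" and cls != CLASS_NONE:
                    ksign = 1.0 if cls == CLASS_FORWARD else -1.0
                    gain = np.ones(tt.size)
                    active = state == cls
                    gain[active] = 1.0 + m * np.cos(
                        ksign * kvec * self.s_coord[e] - phi_b[active]
                    )
                bound = amp[e] * gain * lat * g_max * dt
                counts = rng.poisson(bound)
                nz = np.flatnonzero(counts)
                if nz.size == 0:
                    continue
                rep = np.repeat(nz, counts[nz])
                phi_off = rng.uniform(0.0, math.pi, rep.size)
                zph = a_tag * np.cos(ph0[rep] + phi_off) + cz[rep]
                acc = np.exp(
                    -np.minimum((zph - ez[rep]) ** 2 / (2 * s2_ax), 40.0)
                ) / g_max[rep]
                keep = rng.uniform(size=rep.size) < acc
                rep, phi_off, zph = rep[keep], phi_off[keep], zph[keep]
                out_t.append(tt[rep] + dt * phi_off / math.pi)
                out_p.append(np.stack([fx[rep], fy[rep], zph], axis=1))
        if not out_t:
            return np.empty(0), np.empty((0, 3))
        return np.concatenate(out_t), np.concatenate(out_p)

    def emit_photons(
        self,
        traj: ScanTrajectory,
        rng: np.random.Generator,
        t0: float = 0.0,
        center: np.ndarray | None = None,
        channels: tuple[str, ...] = ("red", "green"),
        path: str = "imaging",
        power: dict[str, float] | None = None,
        arrival_jitter_ns: float = 0.5,
        emitter_mask: np.ndarray | None = None,
        keep_positions: bool = False,
    ) -> pd.DataFrame:
        """Draw photon events along a scan trajectory.

        ``center`` (n, 3) is an offset added to the trajectory coordinates to
        place the scan in the lab frame (the tracker estimate for the imaging
        path).  Each trajectory sample is one axial line; photons are drawn
        by exact thinning (see :meth:`line_photons`).  Arrival phases within
        the laser repetition period carry the path's temporal-multiplexing
        offset plus Gaussian jitter.
        """
        power = power or {}
        for ch, p in power.items():
            if p < 0:
                raise ValueError(f"negative power for channel {ch}")
        times = t0 + traj.t
        dt = traj.dt
        if dt <= 0:
            raise ValueError("trajectory must have at least two samples")
        xy = np.stack([traj.x, traj.y], axis=1)
        cz: np.ndarray | float = 0.0
        if center is not None:
            center = np.atleast_2d(center)
            xy = xy + center[:, :2]
            cz = center[:, 2] if center.shape[1] > 2 else 0.0
        a_tag = traj.config.a_tag if traj.config is not None else 25.0
        offset = 0.0 if path == "imaging" else TRACKING_PHASE_OFFSET_NS
        frames = []
        for ch in channels:
            tt, pos = self.line_photons(
                xy, traj.phi, times, dt, a_tag, ch, rng,
                center_z=cz, power=power.get(ch, 1.0), emitter_mask=emitter_mask,
            )
            phase = (
                offset + ARRIVAL_LAG_NS + rng.normal(0.0, arrival_jitter_ns, tt.size)
            ) % LASER_PERIOD_NS
            df = pd.DataFrame(
                {
                    "t_s": tt,
                    "channel": pd.Categorical(
                        np.full(tt.size, ch), categories=["red", "green"]
                    ),
                    "path": pd.Categorical(
                        np.full(tt.size, path), categories=["imaging", "tracking"]
                    ),
                    "arrival_phase_ns": phase,
                }
            )
            if keep_positions:
                df["true_x_um"], df["true_y_um"], df["true_z_um"] = (
                    pos[:, 0], pos[:, 1], pos[:, 2],
                )
            frames.append(df)
        out = pd.concat(frames, ignore_index=True)
        return out.sort_values("t_s", ignore_index=True)


def build_phantom(cfg: PhantomConfig) -> Phantom:
    """Construct the phantom (deterministic given ``cfg`` and its seed)."""
    return Phantom(cfg)
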
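"""Photon-event reconstruction: from time stamps to rate volumes.

The raw output of a photon-counting scanning microscope is not an image but
two columnar streams: *scan samples* (where the beam was, at ~2.6 µs
resolution) and *photon events* (when a photon arrived, and at which phase
of the laser repetition period).  Reconstruction proceeds by

1. temporal demultiplexing — assigning each photon to the imaging or the
   tracking excitation path from its arrival phase;
2. emission-location mapping — looking up the beam state at the photon time
   and converting it to a position relative to the tracked neuron
   (``x = x_galvo - x_tracker``, ``z = A cos(phi) - z_off``);
3. axial dwell correction — weighting counts by ``|sin phi| / norm_const``
   to undo the sinusoidal dwell profile of the resonant axial scan, and
   discarding photons in the turnaround band where the correction diverges;
4. histogramming — a 3D (or 4D, for movies) count histogram divided by a
   dwell-time histogram, giving photon *rates* with an explicit
   missing-data mask where nothing was sampled.

Event tables are pandas DataFrames with unit-suffixed columns
(``t_s, channel, path, arrival_phase_ns, x_um, y_um, z_um, weight``);
sample tables carry ``t_s, x_galvo_um, y_galvo_um, x_tracker_um,
y_tracker_um, phi_rad, z_off_um``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .phantom import LASER_PERIOD_NS, TRACKING_PHASE_OFFSET_NS

__all__ = [
    "VolumeGeometry",
    "RateVolume",
    "RateMovie",
    "Template",
    "EVENT_COLUMNS",
    "SAMPLE_COLUMNS",
    "demultiplex",
    "demultiplex_events",
    "emission_location",
    "locate_events",
    "dwell_adjust",
    "dwell_adjust_events",
    "assemble_volume",
    "assemble_movie",
    "smooth_template",
    "InsufficientCoverageError",
]

EVENT_COLUMNS = ["t_s", "channel", "path", "arrival_phase_ns"]
SAMPLE_COLUMNS = [
    "t_s",
    "x_galvo_um",
    "y_galvo_um",
    "x_tracker_um",
    "y_tracker_um",
    "phi_rad",
    "z_off_um",
]


class InsufficientCoverageError(RuntimeError):
    """Too few sampled voxels to build a template."""


@dataclass(frozen=True)
class VolumeGeometry:
    """Half-open voxel grid: voxel ``i`` covers ``[origin + i*voxel, ...)``."""

    origin: tuple[float, float, float]
    voxel: tuple[float, float, float] = (1.0, 1.0, 2.0)
    shape: tuple[int, int, int] = (200, 200, 25)

    @property
    def edges(self) -> list[np.ndarray]:
        return [
            self.origin[ax] + self.voxel[ax] * np.arange(self.shape[ax] + 1)
            for ax in range(3)
        ]

    @property
    def centers(self) -> list[np.ndarray]:
        return [
            self.origin[ax] + self.voxel[ax] * (np.arange(self.shape[ax]) + 0.5)
            for ax in range(3)
        ]

    @classmethod
    def centered(
        cls,
        extent: tuple[float, float, float],
        voxel: tuple[float, float, float] = (1.0, 1.0, 2.0),
    ) -> "VolumeGeometry":
        shape = tuple(int(round(e / v)) for e, v in zip(extent, voxel))
        origin = tuple(-s * v / 2.0 for s, v in zip(shape, voxel))
        return cls(origin=origin, voxel=voxel, shape=shape)  # type: ignore[arg-type]


@dataclass
class RateVolume:
    """Adjusted counts, dwell time and their ratio on a voxel grid."""

    counts: np.ndarray
    dwell: np.ndarray
    geometry: VolumeGeometry
    qc: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.shape != self.dwell.shape:
            raise ValueError("counts and dwell shapes differ")
        if np.any(self.counts < 0) or np.any(self.dwell < 0):
            raise ValueError("counts and dwell must be non-negative")

    @property
    def mask(self) -> np.ndarray:
        """True where the voxel was sampled (dwell > 0)."""
        return self.dwell > 0

    @property
    def rate(self) -> np.ndarray:
        """Counts / dwell (counts/s); NaN where never sampled."""
        out = np.full(self.counts.shape, np.nan)
        m = self.mask
        out[m] = self.counts[m] / self.dwell[m]
        return out


@dataclass
class RateMovie:
    """Time-binned pairs of rate volumes sharing one geometry."""

    counts: dict[str, np.ndarray]  # channel -> (nt, nx, ny, nz)
    dwell: np.ndarray  # (nt, nx, ny, nz), shared between channels
    geometry: VolumeGeometry
    time_edges: np.ndarray
    smoothed: bool = False

    def rate(self, channel: str) -> np.ndarray:
        out = np.full(self.dwell.shape, np.nan)
        m = self.dwell > 0
        out[m] = self.counts[channel][m] / self.dwell[m]
        return out

    @property
    def time_step(self) -> float:
        return float(self.time_edges[1] - self.time_edges[0])

    @property
    def time_centers(self) -> np.ndarray:
        return 0.5 * (self.time_edges[:-1] + self.time_edges[1:])


# --------------------------------------------------------------------- demux
def demultiplex(
    arrival_phase_ns: np.ndarray | float,
    laser_period_ns: float = LASER_PERIOD_NS,
    offset_ns: float = TRACKING_PHASE_OFFSET_NS,
) -> np.ndarray:
    """Assign photons to the imaging or tracking path by arrival phase.

    Phases in the half-period window starting at 0 belong to the imaging
    laser; the window starting at ``offset_ns`` (half a period later on the
    instrument) belongs to the tracking laser.
    """
    if laser_period_ns <= 0:
        raise ValueError("laser period must be positive")
    phase = np.asarray(arrival_phase_ns, dtype=float) % laser_period_ns
    # window [offset, offset + period/2) -> tracking, the rest -> imaging
    is_tracking = ((phase - offset_ns) % laser_period_ns) < laser_period_ns / 2.0
    return np.where(is_tracking, "tracking", "imaging")


def demultiplex_events(
    events: pd.DataFrame,
    laser_period_ns: float = LASER_PERIOD_NS,
    offset_ns: float = TRACKING_PHASE_OFFSET_NS,
) -> pd.DataFrame:
    """Return a copy of ``events`` with the ``path`` column re-derived."""
    out = events.copy()
    out["path"] = demultiplex(
        out["arrival_phase_ns"].to_numpy(), laser_period_ns, offset_ns
    )
    return out


# ------------------------------------------------------------------ locating
def emission_location(
    sample: pd.Series | pd.DataFrame,
    a_tag: float,
    raw: bool = False,
) -> np.ndarray:
    """Beam position implied by a scan sample (µm), shape (..., 3).

    Tracker-corrected coordinates are relative to the tracked neuron; with
    ``raw=True`` the tracker offset is not subtracted (the uncorrected frame
    used to illustrate motion blur).
    """
    xg = np.asarray(sample["x_galvo_um"], dtype=float)
    yg = np.asarray(sample["y_galvo_um"], dtype=float)
    phi = np.asarray(sample["phi_rad"], dtype=float)
    if raw:
        x, y = xg, yg
        z = a_tag * np.cos(phi)
    else:
        x = xg - np.asarray(sample["x_tracker_um"], dtype=float)
        y = yg - np.asarray(sample["y_tracker_um"], dtype=float)
        z = a_tag * np.cos(phi) - np.asarray(sample["z_off_um"], dtype=float)
    return np.stack([x, y, z], axis=-1)


def locate_events(
    events: pd.DataFrame,
    samples: pd.DataFrame,
    a_tag: float,
    raw: bool = False,
) -> pd.DataFrame:
    """Attach emission locations to photons via nearest-preceding sample.

    The beam state at each photon time is taken from the last scan sample at
    or before it; the TAG phase is advanced within the sample assuming the
    nominal resonance (phase spans pi per sample).
    """
    st = samples["t_s"].to_numpy()
    if not np.all(np.diff(st) > 0):
        raise ValueError("sample times must be strictly increasing")
    pt = events["t_s"].to_numpy()
    if pt.size and (pt.min() < st[0] or pt.max() >= st[-1] + 2 * (st[1] - st[0])):
        raise ValueError("events extend outside the sample stream (unaligned?)")
    idx = np.searchsorted(st, pt, side="right") - 1
    idx = np.clip(idx, 0, len(st) - 1)
    sub = samples.iloc[idx]
    dt_samp = st[1] - st[0]
    # continuous TAG phase within the sampled half-period
    phi = sub["phi_rad"].to_numpy() + math.pi * (pt - st[idx]) / dt_samp
    sub = sub.assign(phi_rad=phi)
    loc = emission_location(sub, a_tag, raw=raw)
    out = events.copy()
    out["x_um"], out["y_um"], out["z_um"] = loc[:, 0], loc[:, 1], loc[:, 2]
    out["phi_rad"] = phi % (2 * math.pi)
    return out


# ------------------------------------------------------------- dwell weights
def dwell_adjust(
    n: np.ndarray | float,
    phi: np.ndarray | float,
    norm_const: float = 0.7846,
    phi_exclude_deg: float = 20.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Axial dwell correction ``n_adj = n |sin phi| / norm_const``.

    Returns ``(n_adj, keep)``: photons whose TAG phase lies within the
    excluded band around the turnaround points (phase 0 and pi, where the
    focus reverses and the correction diverges) have ``keep = False`` and
    must be dropped from rate estimates.
    """
    phi = np.asarray(phi, dtype=float) % (2 * math.pi)
    band = math.radians(phi_exclude_deg)
    dist = np.minimum.reduce(
        [phi, np.abs(phi - math.pi), np.abs(phi - 2 * math.pi)]
    )
    keep = dist >= band
    n_adj = np.asarray(n, dtype=float) * np.abs(np.sin(phi)) / norm_const
    return n_adj, keep


def recompute_norm_const(phi_exclude_deg: float = 20.0, n: int = 200_001) -> float:
    """Mean of ``|sin phi|`` over the included band, uniform in phase.

    An alternative to the canonical 0.7846 constant; the two differ because
    the original binning convention is not part of the data format.
    """
    phi = np.linspace(0, math.pi, n)
    band = math.radians(phi_exclude_deg)
    keep = (phi >= band) & (phi <= math.pi - band)
    return float(np.abs(np.sin(phi[keep])).mean())


def dwell_adjust_events(
    events: pd.DataFrame,
    norm_const: float = 0.7846,
    phi_exclude_deg: float = 20.0,
) -> tuple[pd.DataFrame, dict]:
    """Weight located events by the axial dwell correction.

    Returns the retained events (with a ``weight`` column) and a QC tally of
    the photons discarded in the turnaround band.
    """
    w, keep = dwell_adjust(
        1.0, events["phi_rad"].to_numpy(), norm_const, phi_exclude_deg
    )
    out = events.loc[keep].copy()
    out["weight"] = w[keep]
    qc = {
        "n_events": int(len(events)),
        "n_discarded_turnaround": int((~keep).sum()),
    }
    return out, qc


# ------------------------------------------------------------- histogramming
def _dwell_histogram(
    samples: pd.DataFrame,
    geometry: VolumeGeometry,
    f_tag: float,
    raw: bool = False,
) -> np.ndarray:
    """3D dwell histogram: 2D line-center histogram broadcast axially.

    Each scan sample is one axial line; its (x, y) position is histogrammed
    in 2D and each of the ``n_z`` voxels in the column is assigned an equal
    share ``tau = 1 / (2 f_tag n_z)`` of the line time.
    """
    if {"x_um", "y_um"}.issubset(samples.columns):
        xy = samples[["x_um", "y_um"]].to_numpy()  # already-corrected line centers
    else:
        xy = emission_location(samples, 0.0, raw=raw)[:, :2]  # z not needed in 2D
    ex, ey, _ = geometry.edges
    h2, _, _ = np.histogram2d(xy[:, 0], xy[:, 1], bins=(ex, ey))
    n_z = geometry.shape[2]
    tau = 1.0 / (2.0 * f_tag * n_z)
    return np.repeat(h2[:, :, None], n_z, axis=2) * tau


def assemble_volume(
    events: pd.DataFrame,
    samples: pd.DataFrame,
    geometry: VolumeGeometry,
    f_tag: float = 1.9e5,
    epoch: tuple[float, float] | None = None,
    raw: bool = False,
) -> RateVolume:
    """Build a rate volume: adjusted-count histogram over dwell histogram.

    ``events`` must already be located and weighted (``x_um .. weight``).
    ``epoch`` restricts both streams to a time window.  Voxels never scanned
    are flagged missing (zero dwell) and excluded from rates.
    """
    ev, sa = events, samples
    if epoch is not None:
        t0, t1 = epoch
        ev = ev[(ev["t_s"] >= t0) & (ev["t_s"] < t1)]
        sa = sa[(sa["t_s"] >= t0) & (sa["t_s"] < t1)]
    qc: dict = {}
    if len(sa) == 0:
        import warnings

        warnings.warn("empty epoch: all-missing volume", stacklevel=2)
        z = np.zeros(geometry.shape)
        return RateVolume(counts=z, dwell=z.copy(), geometry=geometry, qc={"empty": True})
    pts = ev[["x_um", "y_um", "z_um"]].to_numpy()
    counts, _ = np.histogramdd(pts, bins=geometry.edges, weights=ev["weight"].to_numpy())
    inside, _ = np.histogramdd(pts, bins=geometry.edges)
    qc["n_outside_volume"] = int(len(ev) - inside.sum())
    dwell = _dwell_histogram(sa, geometry, f_tag, raw=raw)
    return RateVolume(counts=counts, dwell=dwell, geometry=geometry, qc=qc)


def assemble_movie(
    events: dict[str, pd.DataFrame] | pd.DataFrame,
    samples: pd.DataFrame,
    geometry: VolumeGeometry,
    time_bin: float,
    f_tag: float = 1.9e5,
    smooth_sigma: float = 1.0,
    t_range: tuple[float, float] | None = None,
    raw: bool = False,
) -> RateMovie:
    """Build a 4D rate movie with separable Gaussian smoothing.

    Count and dwell histograms are binned at ``time_bin`` (the usual choice
    is half the characteristic raster time) and convolved with a separable
    Gaussian of ``smooth_sigma`` voxels in all four dimensions *before*
    division, so sparsely sampled voxels borrow dwell from their neighbors.
    """
    if time_bin <= 0:
        raise ValueError("time_bin must be positive")
    if isinstance(events, pd.DataFrame):
        events = {str(ch): g for ch, g in events.groupby("channel", observed=True)}
    if t_range is None:
        t0 = float(samples["t_s"].iloc[0])
        t1 = float(samples["t_s"].iloc[-1])
    else:
        t0, t1 = t_range
    n_t = max(1, int(math.ceil((t1 - t0) / time_bin - 1e-9)))
    tedges = t0 + time_bin * np.arange(n_t + 1)

    st = samples["t_s"].to_numpy()
    sbin = np.clip(((st - t0) / time_bin).astype(int), 0, n_t - 1)
    dwell4 = np.zeros((n_t,) + geometry.shape)
    for ti in range(n_t):
        sel = sbin == ti
        if sel.any():
            dwell4[ti] = _dwell_histogram(samples[sel], geometry, f_tag, raw=raw)
    counts4: dict[str, np.ndarray] = {}
    edges4 = [tedges, *geometry.edges]
    for ch, ev in events.items():
        pts = np.column_stack(
            [ev["t_s"].to_numpy(), ev[["x_um", "y_um", "z_um"]].to_numpy()]
        )
        h, _ = np.histogramdd(pts, bins=edges4, weights=ev["weight"].to_numpy())
        counts4[ch] = h
    if smooth_sigma > 0:
        # reflect boundaries: the symmetric kernel then conserves total counts
        dwell4 = ndimage.gaussian_filter(dwell4, smooth_sigma, mode="reflect")
        counts4 = {
            ch: ndimage.gaussian_filter(c, smooth_sigma, mode="reflect")
            for ch, c in counts4.items()
        }
    return RateMovie(
        counts=counts4, dwell=dwell4, geometry=geometry, time_edges=tedges,
        smoothed=smooth_sigma > 0,
    )


# ---------------------------------------------------------------- templates
class Template:
    """Smooth, gap-free rate field evaluable at continuous coordinates."""

    def __init__(self, grid: np.ndarray, geometry: VolumeGeometry):
        self.grid = grid
        self.geometry = geometry
        self._interp = RegularGridInterpolator(
            tuple(geometry.centers), grid, bounds_error=False, fill_value=0.0,
            method="linear",
        )

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return self._interp(np.atleast_2d(points))

    @property
    def peak(self) -> float:
        return float(self.grid.max())


def smooth_template(
    vol: RateVolume,
    sigma: float = 1.5,
    robust: bool = True,
    min_coverage: float = 0.10,
    outlier_nsigma: float = 5.0,
) -> Template:
    """Robust, gap-filling smoothing of a rate volume into a template.

    Missing voxels are filled by normalized Gaussian convolution (a
    mask-weighted local mean); observed voxels are kept unless, under the
    robust option, they deviate from the local estimate by more than
    ``outlier_nsigma`` robust standard deviations, in which case the local
    estimate replaces them.  The result is evaluable at arbitrary continuous
    coordinates and is zero outside the volume.
    """
    m = vol.mask
    coverage = float(m.mean())
    if coverage < min_coverage:
        raise InsufficientCoverageError(
            f"only {coverage:.1%} of voxels sampled (need {min_coverage:.0%})"
        )
    r = np.where(m, np.nan_to_num(vol.rate), 0.0)
    w = m.astype(float)
    num = ndimage.gaussian_filter(r, sigma, mode="constant")
    den = ndimage.gaussian_filter(w, sigma, mode="constant")
    local = np.divide(num, den, out=np.zeros_like(num), where=den > 1e-12)
    # distant unreached voxels: widen until everything has support
    widen = sigma
    while np.any(den <= 1e-12):
        widen *= 2.0
        num = ndimage.gaussian_filter(r, widen, mode="constant")
        den = ndimage.gaussian_filter(w, widen, mode="constant")
        fill = np.divide(num, den, out=np.zeros_like(num), where=den > 1e-12)
        local = np.where(den > 1e-12, local, fill)
        if widen > 64 * sigma:  # pathological: fall back to the global mean
            local = np.where(den > 1e-12, local, r[m].mean())
            break
    out = np.where(m, r, local)
    if robust:
        resid = (r - local)[m]
        mad = np.median(np.abs(resid - np.median(resid)))
        scale = 1.4826 * mad
        if scale > 0:
            bad = m & (np.abs(r - local) > outlier_nsigma * scale)
            out = np.where(bad, local, out)
    return Template(grid=out, geometry=vol.geometry)
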
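"""Activity quantification: ratiometry, stride averaging, wave PCA.

The activity measure throughout is ratiometric: the green (calcium-
sensitive) photon rate divided by the red (calcium-insensitive) rate,
normalized by a baseline.  Because both channels are excited at the same
focus and recovered through the same optics, any motion- or occlusion-
induced intensity change multiplies both rates equally and cancels in the
ratio — which is the point.

Traveling waves are quantified on stride-aligned cubes ``<G(x, y, phi)>``:
the green signal, z-projected, binned by behavioral phase (24 bins of 15°
by default) and averaged over strides.  PCA over spatial points extracts
the two dominant temporal components; a wave is present when they are
sinusoids in quadrature and the complex spatial projection ``g(x, y)``
has a phase that advances linearly along the body.  The wave-restricted
variance-explained statistic replaces ``arg g`` by the best-fitting plane
``k . (x, y) + phi_0`` while keeping ``|g|``; it can go negative when the
plane-wave constraint fits worse than no wave at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats

from .behavior import PhaseClock
from .events import RateMovie, VolumeGeometry

__all__ = [
    "RatioTrace",
    "StrideAlignedCube",
    "WaveDecomposition",
    "baseline_clip",
    "voi_ratio",
    "timespace_projection",
    "stride_average",
    "wave_pca",
    "wave_variance_explained",
    "bout_stats",
]


# ----------------------------------------------------------------- baseline
def baseline_clip(series: np.ndarray, n_sigma: float = 1.0) -> float:
    """Iterative one-sided clipped mean used as a fluorescence baseline.

    Repeatedly discards values more than ``n_sigma`` standard deviations
    *above* the mean until nothing is discarded (or three values remain);
    activity transients are one-sided, so this converges onto the quiescent
    level.  The result never increases across iterations.
    """
    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise ValueError("baseline needs at least 3 finite values")
    while True:
        mu, sd = x.mean(), x.std()
        keep = x <= mu + n_sigma * sd
        if keep.all() or keep.sum() <= 3:
            return float(x[keep].mean()) if keep.any() else float(mu)
        x = x[keep]


# -------------------------------------------------------------------- types
@dataclass
class RatioTrace:
    """Per-time-bin VOI rates: green, red, their ratio, normalized ratio."""

    t: np.ndarray
    green_rate: np.ndarray
    red_rate: np.ndarray
    baseline: float = float("nan")

    @property
    def ratio(self) -> np.ndarray:
        out = np.full(self.t.shape, np.nan)
        ok = self.red_rate > 0
        out[ok] = self.green_rate[ok] / self.red_rate[ok]
        return out

    @property
    def normalized(self) -> np.ndarray:
        return self.ratio / self.baseline


@dataclass
class StrideAlignedCube:
    """Mean z-projected fluorescence per (x, y, phase bin)."""

    values: np.ndarray  # (nx, ny, n_bins) rate, NaN where never sampled
    counts: np.ndarray
    dwell: np.ndarray
    x: np.ndarray
    y: np.ndarray
    n_strides: int
    channel: str = "green"

    @property
    def n_bins(self) -> int:
        return self.values.shape[2]

    @property
    def phase_centers(self) -> np.ndarray:
        w = 2 * math.pi / self.n_bins
        return w * (np.arange(self.n_bins) + 0.5)

    @property
    def empty_bins(self) -> np.ndarray:
        """Phase bins with zero dwell anywhere in the field (flagged)."""
        return np.where(self.dwell.sum(axis=(0, 1)) == 0)[0]


@dataclass
class WaveDecomposition:
    """Two-component PCA of a stride-aligned cube, as a complex wave."""

    c1: np.ndarray  # (n_bins,) leading temporal component
    c2: np.ndarray  # lagging by 90° for a clean wave
    g: np.ndarray  # (nx, ny) complex projection, NaN where invalid
    valid: np.ndarray  # (nx, ny) bool
    var_share_pc12: float  # variance fraction in the first two PCs
    k_vec: np.ndarray = field(default_factory=lambda: np.zeros(2))
    phi_0: float = 0.0
    variance_explained: float = float("nan")
    phase_lowpass_sigma_um: float = 3.0

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.g)

    def phase_map(self, pixel_um: float = 1.0) -> np.ndarray:
        """arg g, spatially low-passed (on the complex map) before the angle."""
        gz = np.where(self.valid, np.nan_to_num(self.g), 0.0)
        w = self.valid.astype(float)
        sig = self.phase_lowpass_sigma_um / pixel_um
        num = ndimage.gaussian_filter(gz.real, sig) + 1j * ndimage.gaussian_filter(
            gz.imag, sig
        )
        den = ndimage.gaussian_filter(w, sig)
        sm = np.where(den > 1e-9, num / np.maximum(den, 1e-9), np.nan)
        return np.where(self.valid, np.angle(sm), np.nan)


# ---------------------------------------------------------------------- VOI
def voi_ratio(
    movie: RateMovie,
    vois: list[dict],
    normalize: str = "baseline",
) -> list[RatioTrace]:
    """Green/red rate ratio per VOI (sphere in template coordinates).

    The per-bin rate is total adjusted counts inside the VOI divided by
    total sampling time; bins with zero dwell are missing.  ``normalize``
    chooses the reference ratio: ``"baseline"`` (iterative clipped mean of
    the trace) or ``"min"`` (minimum finite value, the convention for
    stride-aligned averages).
    """
    geo = movie.geometry
    centers = np.meshgrid(*geo.centers, indexing="ij")
    out = []
    for voi in vois:
        cs = voi.get("centers_um") or [voi["center_um"]]  # union of spheres
        r = float(voi["radius_um"])
        mask = np.zeros(geo.shape, dtype=bool)
        for c in np.atleast_2d(np.asarray(cs, dtype=float)):
            mask |= (
                (centers[0] - c[0]) ** 2
                + (centers[1] - c[1]) ** 2
                + (centers[2] - c[2]) ** 2
            ) <= r**2
        if not mask.any():
            raise ValueError(f"VOI at {cs} with radius {r} contains no voxels")
        dwell = movie.dwell[:, mask].sum(axis=1)
        ok = dwell > 0
        green = np.full(dwell.shape, np.nan)
        red = np.full(dwell.shape, np.nan)
        green[ok] = movie.counts["green"][:, mask].sum(axis=1)[ok] / dwell[ok]
        red[ok] = movie.counts["red"][:, mask].sum(axis=1)[ok] / dwell[ok]
        tr = RatioTrace(t=movie.time_centers, green_rate=green, red_rate=red)
        ratio = tr.ratio
        finite = ratio[np.isfinite(ratio)]
        if normalize == "baseline" and finite.size >= 3:
            tr.baseline = baseline_clip(finite)
        elif finite.size:
            tr.baseline = float(np.nanmin(finite))
        out.append(tr)
    return out


def timespace_projection(
    movie: RateMovie,
    box: dict,
    axis: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Space x time ratio map along the body axis, median-normalized to 1.

    ``box`` gives ``lo_um``/``hi_um`` bounds per axis; counts and dwell are
    summed over the two short axes (separately per channel, then divided),
    and the green/red ratio map is divided by its median.  Returns
    ``(map, axis_positions, time_centers)``; empty slices are NaN stripes.
    """
    geo = movie.geometry
    sel = []
    for ax in range(3):
        cc = geo.centers[ax]
        lo, hi = box.get("lo_um", (-np.inf,) * 3)[ax], box.get("hi_um", (np.inf,) * 3)[ax]
        sel.append((cc >= lo) & (cc <= hi))
    short_axes = tuple(1 + ax for ax in range(3) if ax != axis)
    ix = np.ix_(np.ones(movie.dwell.shape[0], bool), *sel)
    dwell = movie.dwell[ix].sum(axis=short_axes)  # (nt, n_axis)
    rates = {}
    for ch in ("green", "red"):
        c = movie.counts[ch][ix].sum(axis=short_axes)
        rates[ch] = np.where(dwell > 0, c / np.maximum(dwell, 1e-300), np.nan)
    ratio = rates["green"] / rates["red"]
    med = np.nanmedian(ratio)
    if med > 0:
        ratio = ratio / med
    return ratio.T, geo.centers[axis][sel[axis]], movie.time_centers


# ---------------------------------------------------------- stride averaging
def stride_average(
    events: pd.DataFrame,
    samples: pd.DataFrame,
    clock: PhaseClock,
    geometry: VolumeGeometry,
    n_bins: int = 24,
    f_tag: float = 1.9e5,
    channel: str = "green",
    smooth_sigma: float = 1.0,
) -> StrideAlignedCube:
    """Phase-binned, z-projected, stride-averaged fluorescence cube.

    Photon counts (dwell-adjusted weights) and sampling times are assigned
    a behavioral phase from the clock, binned into ``n_bins`` equal phase
    bins (bin edges at phase 0), histogrammed in (x, y) and divided.  As in
    movie reconstruction, count and dwell histograms are convolved with a
    separable Gaussian of ``smooth_sigma`` bins (circular along phase)
    *before* division.  Times outside the clock's bouts (NaN phase) are
    excluded; requires at least two strides so every phase bin is visited.
    """
    phi_ev = clock.phi_at(events["t_s"].to_numpy())
    phi_sa = clock.phi_at(samples["t_s"].to_numpy())
    n_strides = int(
        math.floor(np.nanmax(clock.phi) / (2 * math.pi))
        - math.ceil(np.nanmin(clock.phi) / (2 * math.pi))
    )
    if n_strides < 2:
        raise ValueError("stride averaging needs at least 2 full strides")
    ex, ey, _ = geometry.edges
    w = 2 * math.pi / n_bins

    ev_ok = np.isfinite(phi_ev)
    bins_ev = (np.mod(phi_ev[ev_ok], 2 * math.pi) / w).astype(int) % n_bins
    pts = events.loc[ev_ok, ["x_um", "y_um"]].to_numpy()
    counts = np.zeros((len(ex) - 1, len(ey) - 1, n_bins))
    for b in range(n_bins):
        m = bins_ev == b
        if m.any():
            h, _, _ = np.histogram2d(
                pts[m, 0], pts[m, 1], bins=(ex, ey),
                weights=events.loc[ev_ok, "weight"].to_numpy()[m],
            )
            counts[:, :, b] = h

    sa_ok = np.isfinite(phi_sa)
    bins_sa = (np.mod(phi_sa[sa_ok], 2 * math.pi) / w).astype(int) % n_bins
    if {"x_um", "y_um"}.issubset(samples.columns):
        line = samples.loc[sa_ok, ["x_um", "y_um"]].to_numpy()
    else:
        from .events import emission_location

        line = emission_location(samples.loc[sa_ok], a_tag=0.0)[:, :2]
    line_time = 1.0 / (2.0 * f_tag)  # full axial line per sample, z-projected
    dwell = np.zeros_like(counts)
    for b in range(n_bins):
        m = bins_sa == b
        if m.any():
            h, _, _ = np.histogram2d(line[m, 0], line[m, 1], bins=(ex, ey))
            dwell[:, :, b] = h * line_time

    if smooth_sigma > 0:
        sig = (smooth_sigma, smooth_sigma, smooth_sigma)
        counts_s = ndimage.gaussian_filter(counts, sig, mode=("constant", "constant", "wrap"))
        dwell_s = ndimage.gaussian_filter(dwell, sig, mode=("constant", "constant", "wrap"))
    else:
        counts_s, dwell_s = counts, dwell
    values = np.where(dwell_s > 0, counts_s / np.maximum(dwell_s, 1e-300), np.nan)
    return StrideAlignedCube(
        values=values, counts=counts, dwell=dwell,
        x=geometry.centers[0], y=geometry.centers[1],
        n_strides=n_strides, channel=channel,
    )


# ---------------------------------------------------------------- wave PCA
def wave_pca(cube: StrideAlignedCube, min_points: int = 10) -> WaveDecomposition:
    """Two-component PCA of the mean-subtracted temporal signals.

    Spatial points are observations, phase bins are variables.  For a clean
    traveling wave the two leading components are quadrature sinusoids; they
    are ordered so ``c1`` leads ``c2`` by 90° (fundamental cross-spectrum
    phase) and signed so ``c1`` is non-negative at phase 0.  The complex
    projection ``g = a1 + i a2`` carries per-point wave amplitude and phase.
    """
    vals = cube.values
    if cube.n_bins < 3:
        raise ValueError("need at least 3 phase bins")
    valid = np.all(np.isfinite(vals), axis=2)
    pts = vals[valid]
    if len(pts) < min_points:
        raise ValueError(f"only {len(pts)} fully sampled spatial points")
    x = pts - pts.mean(axis=1, keepdims=True)
    total = float((x**2).sum())
    if total == 0:
        raise ValueError("rank-deficient cube: no temporal variance")
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    c1, c2 = vt[0], vt[1]
    var12 = float((s[0] ** 2 + s[1] ** 2) / (s**2).sum())
    phase = cube.phase_centers
    f1 = np.sum(c1 * np.exp(-1j * phase))
    f2 = np.sum(c2 * np.exp(-1j * phase))
    # want c1 to lead c2 by +90°: arg(f1 conj(f2)) = +pi/2
    rel = np.angle(f1 * np.conj(f2))
    if rel < 0:
        c1, c2 = c2, c1
        f1, f2 = f2, f1
    # interpolate c at phase 0 (bin centers are offset by half a bin)
    c1_at0 = 0.5 * (c1[0] + c1[-1])
    if c1_at0 < 0:
        c1, c2 = -c1, -c2
    a1 = x @ c1
    a2 = x @ c2
    g = np.full(valid.shape, np.nan, dtype=complex)
    g[valid] = a1 + 1j * a2
    return WaveDecomposition(c1=c1, c2=c2, g=g, valid=valid, var_share_pc12=var12)


def _wave_residual(
    amp: np.ndarray, psi: np.ndarray, xy: np.ndarray, k: np.ndarray
) -> tuple[float, float]:
    """Misfit of the plane-wave phase and its optimal offset phi_0."""
    z = np.sum(amp**2 * np.exp(1j * (psi - xy @ k)))
    phi0 = float(np.angle(z))
    miss = float(2.0 * ((amp**2).sum() - np.abs(z)))
    return miss, phi0


def wave_variance_explained(
    cube: StrideAlignedCube,
    decomp: WaveDecomposition,
    n_dir: int = 72,
    n_mag: int = 48,
    k_max: float | None = None,
) -> WaveDecomposition:
    """Variance explained after restricting the phase map to a plane wave.

    Keeps ``|g|``, replaces ``arg g`` by ``k.(x, y) + phi_0`` with ``k``
    fit on a direction/magnitude grid (5° steps by default) plus local
    refinement and ``phi_0`` in closed form, and computes
    ``1 - residual / total`` variance of the mean-subtracted cube.  The
    fraction is negative when the constraint fits worse than nothing, and 0
    by convention for a zero-amplitude cube.  Returns an updated decomposition.
    """
    vals = cube.values[decomp.valid]
    x = vals - vals.mean(axis=1, keepdims=True)
    total = float((x**2).sum())
    amp = np.abs(decomp.g[decomp.valid])
    psi = np.angle(decomp.g[decomp.valid])
    if total == 0 or np.all(amp == 0):
        decomp.variance_explained = 0.0
        return decomp
    xg, yg = np.meshgrid(cube.x, cube.y, indexing="ij")
    xy = np.stack([xg[decomp.valid], yg[decomp.valid]], axis=1)
    xy = xy - xy.mean(axis=0)
    if k_max is None:
        span = max(np.ptp(xy[:, 0]), np.ptp(xy[:, 1]), 1.0)
        k_max = 8.0 * math.pi / span
    dirs = np.linspace(0, 2 * math.pi, n_dir, endpoint=False)
    mags = np.linspace(0, k_max, n_mag)
    best = (np.inf, np.zeros(2), 0.0)
    for d in dirs:
        u = np.array([math.cos(d), math.sin(d)])
        for m in mags:
            miss, phi0 = _wave_residual(amp, psi, xy, m * u)
            if miss < best[0]:
                best = (miss, m * u, phi0)
    res = optimize.minimize(
        lambda k: _wave_residual(amp, psi, xy, k)[0], best[1], method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-12},
    )
    k_fit = res.x if res.fun <= best[0] else best[1]
    miss, phi0 = _wave_residual(amp, psi, xy, k_fit)
    # residual = variance outside PC1/2 span + phase-constraint misfit
    a1, a2 = x @ decomp.c1, x @ decomp.c2
    outside = total - float((a1**2).sum() + (a2**2).sum())
    decomp.k_vec = np.asarray(k_fit)
    decomp.phi_0 = phi0
    decomp.variance_explained = 1.0 - (outside + miss) / total
    return decomp


# --------------------------------------------------------------- bout stats
def bout_stats(
    trace: RatioTrace,
    bouts: list[tuple[str, float, float]],
    min_for_test: int = 3,
) -> dict:
    """Per-bout mean normalized ratios and a forward-vs-backward test.

    Computes the average normalized ratio over each bout and, given at
    least ``min_for_test`` bouts per state, a one-sided Wilcoxon rank-sum
    test of median(backward) > median(forward).  The exact small-sample
    null is used up to 10 bouts per group, the normal approximation above.
    """
    norm = trace.normalized
    per_bout: dict[str, list[float]] = {"forward": [], "backward": []}
    rows = []
    for state, t0, t1 in bouts:
        sel = (trace.t >= t0) & (trace.t < t1) & np.isfinite(norm)
        if not sel.any():
            continue
        mu = float(norm[sel].mean())
        rows.append({"state": state, "start_s": t0, "end_s": t1, "mean_ratio": mu})
        if state in per_bout:
            per_bout[state].append(mu)
    fwd, bwd = per_bout["forward"], per_bout["backward"]
    out = {
        "bouts": rows,
        "n_forward": len(fwd),
        "n_backward": len(bwd),
        "median_forward": float(np.median(fwd)) if fwd else float("nan"),
        "median_backward": float(np.median(bwd)) if bwd else float("nan"),
        "p_backward_gt_forward": float("nan"),
        "test_skipped": True,
    }
    if len(fwd) >= min_for_test and len(bwd) >= min_for_test:
        method = "exact" if max(len(fwd), len(bwd)) <= 10 else "asymptotic"
        res = stats.mannwhitneyu(bwd, fwd, alternative="greater", method=method)
        out["p_backward_gt_forward"] = float(res.pvalue)
        out["test_skipped"] = False
    return out
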
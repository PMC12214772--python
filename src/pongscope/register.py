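"""Motion correction computed on the red channel, applied to both.

Three stages, in order of decreasing stiffness:

1. **Rigid** — for each frame (a time window long enough to oversample the
   volume ~3.125x at 1 µm^-2), find the rotation + translation that
   maximizes the summed template rate at the transformed photon locations,
   ``sum_photons lambda(A x)``.  A coarse in-plane angle grid with
   FFT-correlation translation estimates guards against local optima; a
   derivative-free refinement then fits all six parameters.
2. **Non-rigid** — a cubic B-spline free-form deformation of the
   rigid-registered frame, maximizing missing-aware normalized correlation
   with the template under a bending-energy penalty.  The fitted
   displacement field applies directly to scan-path coordinates, so both
   channels are corrected identically.
3. **Intensity** — a smooth multiplier ``alpha(x)`` (cubic B-spline control
   points ~20 µm apart) fitted by inhomogeneous-Poisson maximum likelihood:
   ``log P = sum_photons log alpha(x_i) - int alpha(x(t)) lambda(x(t)) dt``.
   The likelihood is concave in the control values, which are kept
   positive by a lower bound.

Only red photons ever enter any fit; the green channel is mapped through
the same transforms and divided by the same ``alpha``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from ._bspline import BSplineField
from .events import RateVolume, Template, VolumeGeometry

__all__ = [
    "RigidTransform",
    "DeformationField",
    "IntensityField",
    "rigid_register",
    "register_sequence",
    "combine_registered",
    "nonrigid_register",
    "intensity_correct",
    "apply_corrections",
    "frame_windows",
    "default_frame_duration",
]


# ---------------------------------------------------------------- transforms
@dataclass
class RigidTransform:
    """Rotation (in-plane angle first, then tilts about y and x) + shift.

    Maps frame (scan-path) coordinates to template coordinates:
    ``x_template = Rz(a0) Ry(a1) Rx(a2) x + t``.
    """

    angles: np.ndarray  # (3,) rad
    translation: np.ndarray  # (3,) µm
    objective: float = 0.0
    flagged: bool = False

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float).copy()
        self.translation = np.asarray(self.translation, dtype=float).copy()

    @property
    def matrix(self) -> np.ndarray:
        az, ay, ax = self.angles
        cz, sz = math.cos(az), math.sin(az)
        cy, sy = math.cos(ay), math.sin(ay)
        cx, sx = math.cos(ax), math.sin(ax)
        rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        return rz @ ry @ rx

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ self.matrix.T + self.translation

    def inverse(self) -> "RigidTransform":
        m = self.matrix.T
        t = -m @ self.translation
        # recover z-y-x angles from the transposed matrix
        ay = math.asin(np.clip(-m[2, 0], -1, 1))
        az = math.atan2(m[1, 0], m[0, 0])
        ax = math.atan2(m[2, 1], m[2, 2])
        return RigidTransform(angles=np.array([az, ay, ax]), translation=t)

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([self.angles, self.translation])

    @classmethod
    def from_params(cls, p: np.ndarray, **kw) -> "RigidTransform":
        return cls(angles=np.asarray(p[:3]), translation=np.asarray(p[3:6]), **kw)

    def to_dict(self) -> dict:
        return {
            "angles_rad": self.angles.tolist(),
            "translation_um": self.translation.tolist(),
            "objective": self.objective,
            "flagged": self.flagged,
        }


@dataclass
class DeformationField:
    """B-spline free-form deformation ``x -> x + T(x)`` (µm)."""

    spline: BSplineField
    converged: bool = True
    similarity: float = 0.0

    def displacement(self, points: np.ndarray) -> np.ndarray:
        return self.spline(points)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        return pts + self.spline(pts)

    def max_displacement_bound(self) -> float:
        return self.spline.max_magnitude()

    def to_dict(self) -> dict:
        return {"converged": self.converged, "similarity": self.similarity,
                **self.spline.to_dict()}


@dataclass
class IntensityField:
    """Smooth positive multiplier ``alpha(x)`` on a coarse B-spline grid."""

    spline: BSplineField
    flagged: bool = False
    log_likelihood: float = 0.0

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return self.spline(points)[..., 0]

    def to_dict(self) -> dict:
        return {"flagged": self.flagged, "log_likelihood": self.log_likelihood,
                **self.spline.to_dict()}


# ------------------------------------------------------------------- framing
def default_frame_duration(
    a_x: float = 200.0, y_range: float = 200.0, tau_min: float = 3e-6,
    oversample: float = 3.125,
) -> float:
    """Frame length: time to oversample the field ``oversample``x at 1 µm^-2."""
    return oversample * a_x * y_range * tau_min


def frame_windows(t0: float, t1: float, frame: float) -> list[tuple[float, float]]:
    n = max(1, int(round((t1 - t0) / frame)))
    edges = np.linspace(t0, t1, n + 1)
    return list(zip(edges[:-1], edges[1:]))


# ------------------------------------------------------------------- rigid
def _photon_objective(template: Template, pts: np.ndarray, w: np.ndarray | None):
    def obj(p: np.ndarray) -> float:
        tr = RigidTransform.from_params(p)
        lam = template(tr.apply(pts))
        return float(np.average(lam, weights=w))

    return obj


def _coarse_translation(
    template: Template, pts: np.ndarray, angle: float
) -> tuple[float, float, float]:
    """Best 2D shift for a given in-plane angle via FFT cross-correlation."""
    geo = template.geometry
    proj = template.grid.sum(axis=2)  # (nx, ny)
    c, s = math.cos(angle), math.sin(angle)
    xr = c * pts[:, 0] - s * pts[:, 1]
    yr = s * pts[:, 0] + c * pts[:, 1]
    ex, ey, _ = geo.edges
    # histogram over a grid twice the template extent so shifts are visible
    pad_x = (ex[-1] - ex[0]) / 2.0
    pad_y = (ey[-1] - ey[0]) / 2.0
    hx = np.arange(ex[0] - pad_x, ex[-1] + pad_x + geo.voxel[0], geo.voxel[0])
    hy = np.arange(ey[0] - pad_y, ey[-1] + pad_y + geo.voxel[1], geo.voxel[1])
    h, _, _ = np.histogram2d(xr, yr, bins=(hx, hy))
    from scipy.signal import fftconvolve

    corr = fftconvolve(h, proj[::-1, ::-1], mode="full")
    i, j = np.unravel_index(np.argmax(corr), corr.shape)
    # corr peak at offset d means h[m] ~ proj[m - d]: the photon histogram is
    # the template shifted by d cells, so the aligning shift is
    # t = (template origin) - (histogram origin) - d * voxel
    dx = i - (proj.shape[0] - 1)
    dy = j - (proj.shape[1] - 1)
    tx = ex[0] - hx[0] - dx * geo.voxel[0]
    ty = ey[0] - hy[0] - dy * geo.voxel[1]
    return tx, ty, float(corr[i, j])


def rigid_register(
    photons: np.ndarray,
    template: Template,
    weights: np.ndarray | None = None,
    angle_grid_deg: float = 10.0,
    min_photons: int = 200,
    coarse_subsample: int = 20_000,
    rng: np.random.Generator | None = None,
    init: RigidTransform | None = None,
    maxiter: tuple[int, int] = (400, 1500),
) -> RigidTransform:
    """Fit the rigid transform maximizing the template rate at the photons.

    Stage 1 scans the full circle of in-plane angles at ``angle_grid_deg``
    steps, estimating the 2D translation per angle by cross-correlation;
    stage 2 refines (angle, tx, ty) and then all six parameters with a
    derivative-free simplex on the photon objective.  With ``init`` (e.g.
    the previous frame's transform) the global angle search is skipped and
    both refinement stages start from it.
    """
    photons = np.atleast_2d(photons)
    if len(photons) < min_photons:
        return RigidTransform(np.zeros(3), np.zeros(3), flagged=True)
    rng = rng or np.random.default_rng(0)
    sub = photons
    wsub = weights
    if len(photons) > coarse_subsample:
        pick = rng.choice(len(photons), coarse_subsample, replace=False)
        sub = photons[pick]
        wsub = None if weights is None else weights[pick]
    obj = _photon_objective(template, sub, wsub)

    if init is not None:
        a0, tx0, ty0 = init.angles[0], init.translation[0], init.translation[1]
        warm = init.params
    else:
        best = None
        for adeg in np.arange(0.0, 360.0, angle_grid_deg):
            a = math.radians(adeg)
            tx, ty, score = _coarse_translation(template, sub, a)
            if best is None or score > best[1]:
                best = ((a, tx, ty), score)
        a0, tx0, ty0 = best[0]
        warm = None

    # stage 1 refinement: in-plane angle + 2D translation
    def obj3(q):
        return -obj(np.array([q[0], 0.0, 0.0, q[1], q[2], 0.0]))

    r3 = optimize.minimize(
        obj3, [a0, tx0, ty0], method="Nelder-Mead",
        options={"xatol": 1e-3, "fatol": 1e-9, "maxiter": maxiter[0]},
    )
    # stage 2: all six parameters, warm started
    p0 = np.array([r3.x[0], 0.0, 0.0, r3.x[1], r3.x[2], 0.0])
    if warm is not None and obj(warm) > obj(p0):
        p0 = warm.copy()
    r6 = optimize.minimize(
        lambda p: -obj(p), p0, method="Nelder-Mead",
        options={"xatol": 5e-4, "fatol": 1e-10, "maxiter": maxiter[1],
                 "initial_simplex": _simplex(p0)},
    )
    full_obj = _photon_objective(template, photons, weights)
    return RigidTransform.from_params(r6.x, objective=full_obj(r6.x) * len(photons))


def _simplex(p0: np.ndarray) -> np.ndarray:
    steps = np.array([0.05, 0.05, 0.05, 2.0, 2.0, 1.0])
    sim = np.tile(p0, (7, 1))
    for i in range(6):
        sim[i + 1, i] += steps[i]
    return sim


def register_sequence(
    frames: list[np.ndarray],
    template: Template,
    initial: list[RigidTransform] | None = None,
    continuity_weight: float = 0.1,
    weights: list[np.ndarray] | None = None,
    sweeps: int = 2,
    subsample: int = 10_000,
    rng: np.random.Generator | None = None,
) -> list[RigidTransform]:
    """Per-frame rigid fits refined with a continuity penalty.

    After independent fits (or given initial transforms, e.g. from coarser
    frames interpolated to 4x temporal resolution), each frame is revisited
    in Gauss-Seidel sweeps minimizing ``-objective + w * sum ||p_f - p_g||^2``
    over its temporal neighbors.  ``continuity_weight`` is in objective
    units per squared parameter and reduces to independent fits at zero.
    """
    rng = rng or np.random.default_rng(0)
    if initial is None:
        initial = [
            rigid_register(f, template, weights=None if weights is None else weights[i],
                           rng=rng)
            for i, f in enumerate(frames)
        ]
    params = [tr.params.copy() for tr in initial]
    scale = np.array([1.0, 1.0, 1.0, 0.1, 0.1, 0.1])  # rad vs µm balance
    objs = []
    for i, f in enumerate(frames):
        sub = f
        if len(f) > subsample:
            sub = f[rng.choice(len(f), subsample, replace=False)]
        objs.append(_photon_objective(template, sub, None))
    norm = max(abs(objs[i](params[i])) for i in range(len(frames))) or 1.0
    for _ in range(sweeps if continuity_weight > 0 else 0):
        for i in range(len(frames)):
            neigh = [params[j] for j in (i - 1, i + 1) if 0 <= j < len(frames)]

            def cost(p, i=i, neigh=neigh):
                c = -objs[i](p) / norm
                for q in neigh:
                    c += continuity_weight * float((((p - q) * scale) ** 2).sum())
                return c

            r = optimize.minimize(
                cost, params[i], method="Nelder-Mead",
                options={"xatol": 5e-4, "fatol": 1e-10, "maxiter": 600},
            )
            params[i] = r.x
    return [
        RigidTransform.from_params(p, objective=objs[i](p) * len(frames[i]))
        for i, p in enumerate(params)
    ]


def combine_registered(
    frames: list[pd.DataFrame],
    samples_frames: list[pd.DataFrame],
    transforms: list[RigidTransform],
    geometry: VolumeGeometry,
    a_tag: float,
    f_tag: float = 1.9e5,
) -> RateVolume:
    """Pool rigid-registered frames into one volume (enlarged template)."""
    from .events import _dwell_histogram, emission_location

    counts = np.zeros(geometry.shape)
    dwell = np.zeros(geometry.shape)
    for ev, sa, tr in zip(frames, samples_frames, transforms):
        pts = tr.apply(ev[["x_um", "y_um", "z_um"]].to_numpy())
        h, _ = np.histogramdd(pts, bins=geometry.edges, weights=ev["weight"].to_numpy())
        counts += h
        # transform line centers in 3D, histogram their (x, y)
        line = emission_location(sa, a_tag)
        line = tr.apply(line)
        n_z = geometry.shape[2]
        tau = 1.0 / (2.0 * f_tag * n_z)
        ex, ey, _ = geometry.edges
        h2, _, _ = np.histogram2d(line[:, 0], line[:, 1], bins=(ex, ey))
        dwell += np.repeat(h2[:, :, None], n_z, axis=2) * tau
    return RateVolume(counts=counts, dwell=dwell, geometry=geometry)


# ----------------------------------------------------------------- nonrigid
def nonrigid_register(
    frame_volume: RateVolume,
    template: Template,
    grid_spacing: float = 20.0,
    bending_weight: float = 1e-4,
    max_displacement: float = 25.0,
    maxiter: int = 80,
    smooth_sigmas: tuple[float, ...] = (3.0, 1.5),
) -> DeformationField:
    """Fit a B-spline FFD aligning a rigid-registered frame to the template.

    Maximizes the missing-aware normalized correlation between the
    (Gaussian-smoothed) frame rates and the equally smoothed template
    evaluated at the displaced voxel centers, with a discrete bending-energy
    penalty on the control grid.  The fit proceeds coarse-to-fine over
    ``smooth_sigmas`` (voxels) to widen the capture range; only voxels near
    tissue (template or frame signal) enter the objective.  The fitted ``T``
    applies to scan-path coordinates of both channels.
    """
    geo = frame_volume.geometry
    mask = frame_volume.mask
    if mask.sum() < 64:
        fld = BSplineField.zeros(np.array(geo.origin), _extent(geo), grid_spacing, m=3)
        return DeformationField(spline=fld, converged=False)
    rates = np.where(mask, np.nan_to_num(frame_volume.rate), 0.0)
    wgt = mask.astype(float)

    # resample the template onto the frame grid for matched smoothing
    centers = np.stack(np.meshgrid(*geo.centers, indexing="ij"), axis=-1)
    tpl_grid = template(centers.reshape(-1, 3)).reshape(geo.shape)

    fld = BSplineField.zeros(np.array(geo.origin), _extent(geo), grid_spacing, m=3)
    n_ctrl = int(np.prod(fld.coefs.shape[:3]))
    lap = _laplacian_stencil()
    from scipy.interpolate import RegularGridInterpolator

    c = np.zeros(n_ctrl * 3)
    bounds = [(-max_displacement, max_displacement)] * (n_ctrl * 3)
    sim = 0.0
    for sig in smooth_sigmas:
        num = ndimage.gaussian_filter(rates * wgt, sig, mode="constant")
        den = ndimage.gaussian_filter(wgt, sig, mode="constant")
        fsm = np.divide(num, den, out=np.zeros_like(num), where=den > 1e-9)
        tsm = ndimage.gaussian_filter(tpl_grid, sig, mode="nearest")
        keep = (den > 1e-9) & (
            (tsm > 0.02 * tsm.max()) | (fsm > 0.02 * max(fsm.max(), 1e-30))
        )
        pts = centers[keep]
        r = fsm[keep]
        r = r - r.mean()
        rnorm = float(np.sqrt((r**2).sum()))
        if rnorm == 0 or len(pts) < 64:
            continue
        idx, w = fld.support_weights(pts)  # displacement is linear in coefs
        flat_idx = idx.ravel()
        tint = RegularGridInterpolator(
            tuple(geo.centers), tsm, bounds_error=False, fill_value=0.0,
        )
        tgrad = np.stack(np.gradient(tsm, *geo.centers), axis=-1)
        gint = RegularGridInterpolator(
            tuple(geo.centers), tgrad, bounds_error=False, fill_value=0.0,
        )

        def cost_grad(cv, pts=pts, r=r, rnorm=rnorm, idx=idx, w=w,
                      flat_idx=flat_idx, tint=tint, gint=gint):
            coefs = cv.reshape(-1, 3)
            disp = np.einsum("nk,nkm->nm", w, coefs[idx])
            q = pts + disp
            lam = tint(q)
            lam = lam - lam.mean()
            lnorm = float(np.sqrt((lam**2).sum()))
            if lnorm < 1e-12:
                corr, dcorr = 0.0, np.zeros_like(lam)
            else:
                corr = float((r * lam).sum() / (rnorm * lnorm))
                dcorr = r / (rnorm * lnorm) - corr * lam / lnorm**2
                dcorr -= dcorr.mean()
            gl = gint(q)
            dd = dcorr[:, None] * gl  # d corr / d displacement, (n, 3)
            contrib = (w[:, :, None] * dd[:, None, :]).reshape(-1, 3)
            grad_c = np.stack(
                [np.bincount(flat_idx, contrib[:, ax], minlength=n_ctrl)
                 for ax in range(3)],
                axis=1,
            )
            cg = cv.reshape(fld.coefs.shape[:3] + (3,))
            pen, gpen = 0.0, np.empty_like(cg)
            for ax in range(3):
                lc = ndimage.convolve(cg[..., ax], lap, mode="nearest")
                pen += float((lc**2).sum())
                gpen[..., ax] = 2.0 * ndimage.convolve(lc, lap, mode="nearest")
            return (-corr + bending_weight * pen,
                    (-grad_c.reshape(cg.shape) + bending_weight * gpen).ravel())

        res = optimize.minimize(
            cost_grad, c, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-10},
        )
        c = res.x
        sim = -float(res.fun)
    fld.coefs = c.reshape(fld.coefs.shape[:3] + (3,)).copy()
    ok = sim > 0
    if not ok:
        fld.coefs *= 0.0
    return DeformationField(spline=fld, converged=ok, similarity=sim)


def _extent(geo: VolumeGeometry) -> np.ndarray:
    return np.array([geo.voxel[i] * geo.shape[i] for i in range(3)])


def _laplacian_stencil() -> np.ndarray:
    k = np.zeros((3, 3, 3))
    k[1, 1, 1] = -6.0
    for d in ((0, 1, 1), (2, 1, 1), (1, 0, 1), (1, 2, 1), (1, 1, 0), (1, 1, 2)):
        k[d] = 1.0
    return k


# ---------------------------------------------------------------- intensity
def intensity_correct(
    photons: np.ndarray,
    path_points: np.ndarray,
    path_dt: float,
    template: Template,
    grid_spacing: float = 20.0,
    alpha_min: float = 0.05,
    maxiter: int = 200,
) -> IntensityField:
    """Poisson-MLE smooth intensity multiplier for one registered frame.

    ``photons`` are red photon locations after full spatial registration;
    ``path_points`` the registered scan-path samples and ``path_dt`` their
    time step.  Maximizes
    ``sum_i log alpha(x_i) - int alpha(x(t)) lambda(x(t)) dt`` with
    ``alpha`` linear in its control values (concave problem), bounded below
    for positivity.
    """
    geo = template.geometry
    fld = BSplineField.zeros(np.array(geo.origin), _extent(geo), grid_spacing, m=1)
    n_ctrl = int(np.prod(fld.coefs.shape[:3]))
    if len(photons) == 0:
        fld.coefs[..., 0] = 1.0
        return IntensityField(spline=fld, flagged=True)
    ip, wp = fld.support_weights(np.atleast_2d(photons))
    is_, ws = fld.support_weights(np.atleast_2d(path_points))
    lam = template(np.atleast_2d(path_points))
    lam_dt = lam * path_dt

    ip_flat, is_flat = ip.ravel(), is_.ravel()

    def neg_ll(c: np.ndarray) -> tuple[float, np.ndarray]:
        a_ph = np.einsum("nk,nk->n", wp, c[ip])
        a_ph = np.maximum(a_ph, 1e-9)
        a_pa = np.einsum("nk,nk->n", ws, c[is_])
        ll = float(np.log(a_ph).sum() - (a_pa * lam_dt).sum())
        grad = np.bincount(ip_flat, (wp / a_ph[:, None]).ravel(), minlength=n_ctrl)
        grad -= np.bincount(is_flat, (ws * lam_dt[:, None]).ravel(), minlength=n_ctrl)
        return -ll, -grad

    c0 = np.ones(n_ctrl)
    res = optimize.minimize(
        neg_ll, c0, jac=True, method="L-BFGS-B",
        bounds=[(alpha_min, None)] * n_ctrl,
        options={"maxiter": maxiter, "ftol": 1e-9},
    )
    fld.coefs = res.x.reshape(fld.coefs.shape[:3] + (1,)).copy()
    return IntensityField(spline=fld, log_likelihood=-float(res.fun))


# ------------------------------------------------------------------- apply
def apply_corrections(
    events_red: pd.DataFrame,
    events_green: pd.DataFrame,
    rigid: RigidTransform,
    deformation: DeformationField | None = None,
    intensity: IntensityField | None = None,
    template: Template | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Map both channels through the red-derived corrections.

    Event locations go through the rigid transform, then the deformation;
    per-event weights are divided by ``alpha`` at the corrected location
    (so corrected rates no longer equal raw detector rates).  Events landing
    outside the template domain are dropped and tallied.
    """
    qc = {"n_dropped_outside": 0}

    def one(ev: pd.DataFrame) -> pd.DataFrame:
        out = ev.copy()
        pts = out[["x_um", "y_um", "z_um"]].to_numpy()
        pts = rigid.apply(pts)
        if deformation is not None:
            pts = deformation.apply(pts)
        out[["x_um", "y_um", "z_um"]] = pts
        if intensity is not None:
            a = np.maximum(intensity(pts), 1e-6)
            out["weight"] = out["weight"].to_numpy() / a
        if template is not None:
            geo = template.geometry
            lo = np.array(geo.origin)
            hi = lo + _extent(geo)
            inside = np.all((pts >= lo) & (pts < hi), axis=1)
            qc["n_dropped_outside"] += int((~inside).sum())
            out = out.loc[inside]
        return out

    return one(events_red), one(events_green), qc
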
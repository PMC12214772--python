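"""Tensor-product cubic B-spline fields on a regular control grid.

A single small engine backs three users: the phantom's non-rigid
deformation ground truth, the free-form-deformation registration stage, and
the smooth intensity-correction multiplier.  Control points sit on a regular
grid padded by one point beyond the domain on every side, so the field is
well defined (and C^2) everywhere inside the domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BSplineField", "cubic_bspline_basis"]


def cubic_bspline_basis(t: np.ndarray) -> np.ndarray:
    """The four cubic B-spline basis values at fractional offsets ``t``.

    Returns shape ``t.shape + (4,)``; the weights are a partition of unity.
    """
    t = np.asarray(t)
    t2, t3 = t * t, t * t * t
    out = np.empty(t.shape + (4,))
    out[..., 0] = (1 - t) ** 3 / 6.0
    out[..., 1] = (3 * t3 - 6 * t2 + 4) / 6.0
    out[..., 2] = (-3 * t3 + 3 * t2 + 3 * t + 1) / 6.0
    out[..., 3] = t3 / 6.0
    return out


@dataclass
class BSplineField:
    """Cubic B-spline interpolation of control values over a 3D box.

    Parameters
    ----------
    origin, spacing:
        Domain lower corner and control-grid spacing per axis (µm).
    coefs:
        Control values, shape ``(n0 + 3, n1 + 3, n2 + 3, m)`` for a domain
        of ``n_i`` spacing-intervals per axis and an ``m``-component field
        (``m = 3`` for a deformation, ``m = 1`` for an intensity multiplier).
    """

    origin: np.ndarray
    spacing: np.ndarray
    coefs: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.coefs.ndim == 3:
            self.coefs = self.coefs[..., None]
        if any(s < 4 for s in self.coefs.shape[:3]):
            raise ValueError("need at least 4 control points per axis")

    @classmethod
    def zeros(
        cls,
        origin: np.ndarray,
        extent: np.ndarray,
        spacing: float | np.ndarray,
        m: int = 3,
    ) -> "BSplineField":
        """Zero field whose control grid covers ``[origin, origin+extent]``."""
        origin = np.asarray(origin, dtype=float)
        extent = np.asarray(extent, dtype=float)
        spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,)).copy()
        n = np.maximum(1, np.ceil(extent / spacing - 1e-9).astype(int))
        coefs = np.zeros((n[0] + 3, n[1] + 3, n[2] + 3, m))
        return cls(origin=origin, spacing=spacing, coefs=coefs)

    @property
    def n_intervals(self) -> np.ndarray:
        return np.array(self.coefs.shape[:3]) - 3

    def support_weights(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Flat control indices and weights of the 64-point support.

        Returns ``(idx, w)`` with shapes ``(N, 64)``; the field value at
        point ``p`` is ``sum_k w[p, k] * coefs.reshape(-1, m)[idx[p, k]]``.
        Points outside the domain are clamped to the boundary.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        u = (pts - self.origin) / self.spacing
        n = self.n_intervals
        u = np.clip(u, 0.0, n - 1e-9)
        cell = np.floor(u).astype(np.intp)
        frac = u - cell
        # basis per axis: (N, 4) each
        b = [cubic_bspline_basis(frac[:, ax]) for ax in range(3)]
        offs = np.arange(4)
        # control index along axis ax for offset o is cell + o (padded grid)
        shape = self.coefs.shape[:3]
        i0 = (cell[:, 0, None] + offs)[:, :, None, None]
        i1 = (cell[:, 1, None] + offs)[:, None, :, None]
        i2 = (cell[:, 2, None] + offs)[:, None, None, :]
        idx = (i0 * shape[1] + i1) * shape[2] + i2
        w = b[0][:, :, None, None] * b[1][:, None, :, None] * b[2][:, None, None, :]
        return idx.reshape(len(pts), 64), w.reshape(len(pts), 64)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        """Evaluate the field at ``points`` of shape ``(N, 3)`` -> ``(N, m)``."""
        single = np.asarray(points).ndim == 1
        idx, w = self.support_weights(points)
        flat = self.coefs.reshape(-1, self.coefs.shape[-1])
        out = np.einsum("nk,nkm->nm", w, flat[idx])
        return out[0] if single else out

    def max_magnitude(self) -> float:
        """Upper bound on the field magnitude (convex hull of controls)."""
        return float(np.linalg.norm(self.coefs, axis=-1).max())

    def to_dict(self) -> dict:
        return {
            "origin_um": self.origin.tolist(),
            "spacing_um": self.spacing.tolist(),
            "shape": list(self.coefs.shape),
            "coefs": self.coefs.ravel().tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BSplineField":
        coefs = np.asarray(d["coefs"]).reshape(d["shape"])
        return cls(
            origin=np.asarray(d["origin_um"]),
            spacing=np.asarray(d["spacing_um"]),
            coefs=coefs,
        )
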
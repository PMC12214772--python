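"""Rigid, free-form-deformation and intensity correction recovery."""

import math

import numpy as np
import pandas as pd
import pytest

from pongscope import events as ev
from pongscope._bspline import BSplineField
from pongscope.register import (
    DeformationField,
    RigidTransform,
    apply_corrections,
    default_frame_duration,
    frame_windows,
    intensity_correct,
    nonrigid_register,
    rigid_register,
)
from tests.conftest import mixture_photons


@pytest.fixture(scope="module")
def template_and_phantom(still_phantom):
    rng = np.random.default_rng(21)
    pts = mixture_photons(still_phantom, 300_000, rng)
    geo = ev.VolumeGeometry(origin=(-120, -80, -20), voxel=(1, 1, 2),
                            shape=(240, 140, 20))
    counts, _ = np.histogramdd(pts, bins=geo.edges)
    vol = ev.RateVolume(counts=counts, dwell=np.ones_like(counts), geometry=geo)
    return ev.smooth_template(vol, sigma=1.0), still_phantom


class TestRigidTransform:
    def test_inverse_roundtrip(self, rng):
        tr = RigidTransform(angles=np.array([0.3, -0.1, 0.2]),
                            translation=np.array([5.0, -2.0, 1.0]))
        pts = rng.uniform(-50, 50, (20, 3))
        back = tr.inverse().apply(tr.apply(pts))
        assert np.allclose(back, pts, atol=1e-9)

    def test_objective_order_invariant_and_additive(self, template_and_phantom,
                                                    rng):
        tpl, ph = template_and_phantom
        pts = mixture_photons(ph, 5000, rng)
        tr = RigidTransform(np.zeros(3), np.zeros(3))
        total = tpl(tr.apply(pts)).sum()
        perm = rng.permutation(len(pts))
        assert tpl(tr.apply(pts[perm])).sum() == pytest.approx(total, rel=1e-9)
        half = tpl(tr.apply(pts[:2500])).sum() + tpl(tr.apply(pts[2500:])).sum()
        assert half == pytest.approx(total, rel=1e-9)


class TestRigidRegister:
    def test_self_registration_is_identity(self, template_and_phantom):
        tpl, ph = template_and_phantom
        rng = np.random.default_rng(4)
        pts = mixture_photons(ph, 40_000, rng)
        tr = rigid_register(pts, tpl, rng=rng)
        assert abs(np.degrees(tr.angles[0])) < 0.5
        assert np.linalg.norm(tr.translation) < 0.3

    def test_known_pose_recovered(self, template_and_phantom):
        """10 deg in-plane + (5, -3, 2) µm shift, recovered within 1 deg / 0.5 µm."""
        tpl, ph = template_and_phantom
        rng = np.random.default_rng(5)
        true = RigidTransform(
            angles=np.array([math.radians(10), 0.0, 0.0]),
            translation=np.array([5.0, -3.0, 2.0]),
        )
        p = mixture_photons(ph, 100_000, rng)
        frame = true.inverse().apply(p)
        rec = rigid_register(frame, tpl, rng=rng)
        assert abs(rec.angles[0] - true.angles[0]) < math.radians(1.0)
        assert np.linalg.norm(rec.translation - true.translation) < 0.5
        # the objective at the recovered transform beats identity
        ident = tpl(frame).mean()
        assert tpl(rec.apply(frame)).mean() > ident

    def test_too_few_photons_flagged(self, template_and_phantom):
        tpl, _ = template_and_phantom
        tr = rigid_register(np.zeros((10, 3)), tpl)
        assert tr.flagged

    def test_error_shrinks_with_photon_count(self, template_and_phantom):
        """Translation error decreases with N (graceful 1/sqrt(N)-like decay)."""
        tpl, ph = template_and_phantom
        true_t = np.array([4.0, -2.0, 1.0])
        errs = []
        for n in (2_000, 32_000):
            rng = np.random.default_rng(100 + n)
            frame = mixture_photons(ph, n, rng) - true_t
            rec = rigid_register(frame, tpl, rng=rng)
            errs.append(np.linalg.norm(rec.translation - true_t))
        assert errs[1] < errs[0]


class TestRegisterSequence:
    def test_continuity_reduces_jitter_and_zero_weight_is_independent(
        self, template_and_phantom
    ):
        """On a static phantom, the continuity penalty shrinks frame-to-frame
        parameter scatter; with zero weight the refinement is a no-op."""
        from pongscope.register import register_sequence

        tpl, ph = template_and_phantom
        rng = np.random.default_rng(44)
        frames = [mixture_photons(ph, 10_000, rng) for _ in range(4)]
        indep = register_sequence(frames, tpl, continuity_weight=0.0,
                                  rng=np.random.default_rng(1))
        smooth = register_sequence(
            frames, tpl, initial=indep, continuity_weight=0.5, sweeps=1,
            rng=np.random.default_rng(1),
        )
        p_ind = np.array([t.params for t in indep])
        p_smo = np.array([t.params for t in smooth])
        assert p_smo.std(axis=0).sum() <= p_ind.std(axis=0).sum() + 1e-12
        # zero continuity weight leaves the initial transforms untouched
        same = register_sequence(frames, tpl, initial=indep,
                                 continuity_weight=0.0)
        assert np.allclose(np.array([t.params for t in same]), p_ind)

    def test_rotation_ramp_recovered(self, template_and_phantom):
        """A linear 0 -> 20 deg in-plane ramp across frames is recovered
        within 1 deg per frame."""
        from pongscope.register import RigidTransform, register_sequence

        tpl, ph = template_and_phantom
        rng = np.random.default_rng(45)
        true_angles = np.radians(np.linspace(0, 20, 4))
        frames = []
        for a in true_angles:
            tr = RigidTransform(angles=np.array([a, 0, 0]),
                                translation=np.zeros(3))
            frames.append(tr.inverse().apply(mixture_photons(ph, 15_000, rng)))
        recs = register_sequence(frames, tpl, continuity_weight=0.05, sweeps=1,
                                 rng=np.random.default_rng(2))
        rec_angles = np.array([t.angles[0] for t in recs])
        assert np.all(np.abs(rec_angles - true_angles) < math.radians(1.0))


class TestNonrigid:
    def test_null_recovery(self, template_and_phantom):
        tpl, ph = template_and_phantom
        rng = np.random.default_rng(6)
        pts = mixture_photons(ph, 200_000, rng)
        geo = ev.VolumeGeometry(origin=(-120, -80, -24), voxel=(2, 2, 3),
                                shape=(120, 70, 16))
        counts, _ = np.histogramdd(pts, bins=geo.edges)
        vol = ev.RateVolume(counts=counts, dwell=np.ones_like(counts),
                            geometry=geo)
        df = nonrigid_register(vol, tpl, grid_spacing=40.0,
                               smooth_sigmas=(2.0,), maxiter=40)
        probe = ph.positions + rng.normal(0, 2, ph.positions.shape)
        mean_disp = np.linalg.norm(df.displacement(probe), axis=1).mean()
        assert df.converged
        assert mean_disp < 0.5

    def test_path_vs_resampling_agreement(self, template_and_phantom, rng):
        """Applying T to coordinates agrees with resampling the image."""
        tpl, _ = template_and_phantom
        fld = BSplineField.zeros(np.array([-120, -80, -20]),
                                 np.array([240, 140, 40]), 60.0, m=3)
        fld.coefs = np.random.default_rng(8).standard_normal(fld.coefs.shape) * 2.0
        df = DeformationField(spline=fld)
        pts = rng.uniform([-100, -60, -10], [100, 40, 10], (5000, 3))
        direct = tpl(df.apply(pts))
        # resample the template onto a warped grid, then look up undeformed pts
        geo = tpl.geometry
        centers = np.stack(np.meshgrid(*geo.centers, indexing="ij"), axis=-1)
        warped = tpl(df.apply(centers.reshape(-1, 3))).reshape(geo.shape)
        warped_tpl = ev.Template(grid=warped, geometry=geo)
        resampled = warped_tpl(pts)
        denom = np.sqrt((direct**2).mean()) + 1e-12
        assert np.sqrt(((direct - resampled) ** 2).mean()) / denom < 0.05


@pytest.fixture(scope="module")
def true_template(still_phantom):
    geo = ev.VolumeGeometry(origin=(-120, -80, -20), voxel=(2, 2, 4),
                            shape=(120, 70, 10))
    centers = np.stack(
        np.meshgrid(*geo.centers, indexing="ij"), axis=-1
    ).reshape(-1, 3)
    lam = still_phantom.rate(centers, np.zeros(len(centers)), "red")
    return ev.Template(grid=lam.reshape(geo.shape), geometry=geo)


class TestIntensity:
    def _fit(self, phantom, alpha_fn, seed, tpl):
        rng = np.random.default_rng(seed)
        npath = 60_000
        path = np.column_stack(
            [rng.uniform(-120, 120, npath), rng.uniform(-80, 60, npath),
             rng.uniform(-20, 20, npath)]
        )
        dt = 2.63e-6 * 5  # path subsampled 5x, dwell share scaled to match
        lam = phantom.rate(path, np.zeros(npath), "red") * alpha_fn(path)
        counts = rng.poisson(lam * dt)
        nz = counts > 0
        photons = np.repeat(path[nz], counts[nz], axis=0)
        return intensity_correct(photons, path, dt, tpl, grid_spacing=30.0,
                                 maxiter=80)

    @pytest.mark.parametrize(
        "name,alpha_fn,tol",
        [
            ("null", lambda p: np.ones(len(p)), 0.05),
            ("const", lambda p: np.full(len(p), 0.8), 0.05),
            ("gradient", lambda p: 1.0 - 0.4 * (p[:, 0] + 120) / 240, 0.05),
        ],
    )
    def test_multiplier_recovered(self, still_phantom, true_template, name,
                                  alpha_fn, tol):
        fld = self._fit(still_phantom, alpha_fn, seed=hash(name) % 2**31,
                        tpl=true_template)
        pts = still_phantom.positions[:24] + np.random.default_rng(0).normal(
            0, 2, (24, 3)
        )
        err = fld(pts) - alpha_fn(pts)
        assert np.sqrt((err**2).mean()) < tol

    def test_no_photons_flagged_unit(self, true_template):
        fld = intensity_correct(np.empty((0, 3)), np.zeros((10, 3)), 1e-6,
                                true_template)
        assert fld.flagged
        assert np.allclose(fld(np.zeros((3, 3))), 1.0)


class TestApplyCorrections:
    def _events(self, rng, n=500):
        return pd.DataFrame(
            {
                "t_s": np.sort(rng.uniform(0, 1, n)),
                "channel": "red",
                "path": "imaging",
                "arrival_phase_ns": 1.0,
                "x_um": rng.uniform(-50, 50, n),
                "y_um": rng.uniform(-50, 50, n),
                "z_um": rng.uniform(-10, 10, n),
                "phi_rad": math.pi / 2,
                "weight": 1.0,
            }
        )

    def test_identity_corrections_leave_events_unchanged(self, rng):
        red, green = self._events(rng), self._events(rng)
        tr = RigidTransform(np.zeros(3), np.zeros(3))
        out_r, out_g, qc = apply_corrections(red, green, tr)
        pd.testing.assert_frame_equal(out_r, red)
        pd.testing.assert_frame_equal(out_g, green)
        assert qc["n_dropped_outside"] == 0

    def test_both_channels_get_same_mapping(self, rng):
        red = self._events(rng)
        green = red.copy()
        tr = RigidTransform(np.array([0.2, 0, 0]), np.array([3.0, -1.0, 0.5]))
        out_r, out_g, _ = apply_corrections(red, green, tr)
        assert np.allclose(
            out_r[["x_um", "y_um", "z_um"]], out_g[["x_um", "y_um", "z_um"]]
        )

    def test_intensity_divides_weights(self, rng, still_phantom):
        red = self._events(rng)
        fld = BSplineField.zeros(np.array([-60, -60, -15]),
                                 np.array([120, 120, 30]), 30.0, m=1)
        fld.coefs[..., 0] = 0.5
        from pongscope.register import IntensityField

        out_r, _, _ = apply_corrections(
            red, red.copy(), RigidTransform(np.zeros(3), np.zeros(3)),
            intensity=IntensityField(spline=fld),
        )
        assert np.allclose(out_r["weight"], 2.0)


def test_frame_windows_partition():
    w = frame_windows(0.0, 1.0, 0.375)
    assert len(w) == 3
    assert w[0][0] == 0.0 and w[-1][1] == pytest.approx(1.0)
    assert all(a[1] == b[0] for a, b in zip(w, w[1:]))


def test_default_frame_duration_matches_oversampling():
    # 3.125x oversampling of a 200x200 µm field at 1 µm^-2, 3 µs per sample
    assert default_frame_duration(200, 200, 3e-6) == pytest.approx(0.375)
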
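"""Photon-event model: demux, locating, dwell correction, volume assembly."""

import math

import numpy as np
import pandas as pd
import pytest

from pongscope import events as ev
from pongscope import scan
from pongscope.phantom import LASER_PERIOD_NS


def _uniform_stream(lam0, duration, seed, a_x=40.0):
    """Photon/sample streams from a spatially uniform emitter (rate lam0)."""
    rng = np.random.default_rng(seed)
    cfg = scan.ScanConfig(a_x=a_x, f_max=667.0)
    traj = scan.pong_trajectory(cfg, duration)
    counts = rng.poisson(lam0 * traj.dt, len(traj))
    rep = np.repeat(np.arange(len(traj)), counts)
    phi_off = rng.uniform(0, math.pi, rep.size)
    events = pd.DataFrame(
        {
            "t_s": traj.t[rep] + traj.dt * phi_off / math.pi,
            "channel": "red",
            "path": "imaging",
            "arrival_phase_ns": 1.0,
        }
    )
    samples = pd.DataFrame(
        {
            "t_s": traj.t,
            "x_galvo_um": traj.x,
            "y_galvo_um": traj.y,
            "x_tracker_um": 0.0,
            "y_tracker_um": 0.0,
            "phi_rad": traj.phi,
            "z_off_um": 0.0,
        }
    )
    return cfg, events, samples


class TestDemultiplex:
    def test_half_period_windows(self):
        assert ev.demultiplex(3.0, 14.3, 7.1) == "imaging"
        assert ev.demultiplex(10.0, 14.3, 7.1) == "tracking"
        out = ev.demultiplex(np.array([0.0, 7.0, 7.2, 14.2]), 14.3, 7.1)
        assert list(out) == ["imaging", "imaging", "tracking", "tracking"]

    def test_jitter_misassignment_below_10pct(self, rng):
        """Gaussian arrival jitter of 1 ns misassigns well under 10%."""
        n = 200_000
        true_path = rng.integers(0, 2, n)  # 0 imaging, 1 tracking
        phase = (
            true_path * (LASER_PERIOD_NS / 2)
            + LASER_PERIOD_NS / 4  # window centers
            + rng.normal(0.0, 1.0, n)
        ) % LASER_PERIOD_NS
        assigned = ev.demultiplex(phase) == "tracking"
        frac = np.mean(assigned != (true_path == 1))
        assert frac < 0.10

    def test_period_must_be_positive(self):
        with pytest.raises(ValueError):
            ev.demultiplex(1.0, laser_period_ns=0.0)


class TestEmissionLocation:
    def test_tracker_subtraction(self):
        s = pd.Series(
            {"x_galvo_um": 50.0, "y_galvo_um": 60.0, "x_tracker_um": 10.0,
             "y_tracker_um": 20.0, "phi_rad": math.pi / 3, "z_off_um": 0.5}
        )
        loc = ev.emission_location(s, a_tag=25.0)
        assert np.allclose(loc, [40.0, 40.0, 12.0])

    def test_raw_mode(self):
        s = pd.Series(
            {"x_galvo_um": 50.0, "y_galvo_um": 60.0, "x_tracker_um": 10.0,
             "y_tracker_um": 20.0, "phi_rad": math.pi / 3, "z_off_um": 0.5}
        )
        loc = ev.emission_location(s, a_tag=25.0, raw=True)
        assert np.allclose(loc, [50.0, 60.0, 12.5])

    def test_unaligned_streams_error(self):
        samples = pd.DataFrame(
            {"t_s": [0.0, 1e-6], "x_galvo_um": 0.0, "y_galvo_um": 0.0,
             "x_tracker_um": 0.0, "y_tracker_um": 0.0, "phi_rad": 0.0,
             "z_off_um": 0.0}
        )
        events = pd.DataFrame(
            {"t_s": [5.0], "channel": "red", "path": "imaging",
             "arrival_phase_ns": 0.0}
        )
        with pytest.raises(ValueError):
            ev.locate_events(events, samples, a_tag=25.0)


class TestDwellAdjust:
    def test_normalisation_factor(self):
        n_adj, keep = ev.dwell_adjust(1.0, math.pi / 2)
        assert keep
        assert n_adj == pytest.approx(1.0 / 0.7846, abs=1e-4)

    def test_oblique_phase(self):
        n_adj, keep = ev.dwell_adjust(1.0, math.pi / 6)
        assert keep
        assert n_adj == pytest.approx(0.5 / 0.7846, abs=1e-4)

    def test_turnaround_band_discarded(self):
        for phi in (0.1, math.pi - 0.1, math.pi + 0.2, 2 * math.pi - 0.05):
            _, keep = ev.dwell_adjust(1.0, phi)
            assert not keep

    def test_recomputed_constant_near_included_band_mean(self):
        c = ev.recompute_norm_const(20.0)
        assert c == pytest.approx(0.7694, abs=1e-3)


class TestVolumes:
    def test_per_voxel_line_time(self):
        # 190 kHz, 25 z-bins: each voxel gets 105.3 ns of each line
        assert 1.0 / (2 * 1.9e5 * 25) == pytest.approx(105.3e-9, rel=1e-3)

    def test_uniform_rate_recovered(self):
        """A uniform emitter reconstructs to a flat rate volume at lam0.

        Uses the exactly rate-unbiased normalisation 2/pi (the default
        0.7846 rescales all rates by the same constant).
        """
        lam0 = 3e5
        cfg, events, samples = _uniform_stream(lam0, 0.6, seed=0)
        loc = ev.locate_events(events, samples, a_tag=cfg.a_tag)
        w, qc = ev.dwell_adjust_events(loc, norm_const=2 / math.pi)
        geo = ev.VolumeGeometry(origin=(-20, -20, -25), voxel=(2, 2, 2),
                                shape=(20, 20, 25))
        vol = ev.assemble_volume(w, samples, geo, f_tag=cfg.f_tag)
        interior = vol.rate[:, :, 5:20]
        assert np.nanmean(interior) == pytest.approx(lam0, rel=0.02)
        assert np.nanstd(interior) / lam0 < 0.3  # Poisson-level scatter

    def test_count_conservation(self):
        cfg, events, samples = _uniform_stream(2e5, 0.2, seed=1)
        loc = ev.locate_events(events, samples, a_tag=cfg.a_tag)
        w, qc = ev.dwell_adjust_events(loc)
        geo = ev.VolumeGeometry(origin=(-30, -30, -30), voxel=(2, 2, 2),
                                shape=(30, 30, 30))
        vol = ev.assemble_volume(w, samples, geo, f_tag=cfg.f_tag)
        binned = vol.counts.sum() + vol.qc["n_outside_volume"] * 0
        assert vol.qc["n_outside_volume"] == 0
        assert binned == pytest.approx(w["weight"].sum(), rel=1e-9)
        assert qc["n_discarded_turnaround"] + len(w) == qc["n_events"]

    def test_empty_epoch_warns_all_missing(self):
        cfg, events, samples = _uniform_stream(1e4, 0.01, seed=2)
        geo = ev.VolumeGeometry(origin=(-20, -20, -20), voxel=(2, 2, 2),
                                shape=(20, 20, 20))
        loc = ev.locate_events(events, samples, a_tag=cfg.a_tag)
        w, _ = ev.dwell_adjust_events(loc)
        with pytest.warns(UserWarning):
            vol = ev.assemble_volume(w, samples, geo, f_tag=cfg.f_tag,
                                     epoch=(5.0, 6.0))
        assert not vol.mask.any()

    def test_rate_invariant_to_scan_speed(self):
        """Counts and dwell scale together, so rates are speed-invariant."""
        lam0 = 2e5
        out = []
        for dur in (0.2, 0.4):
            cfg, events, samples = _uniform_stream(lam0, dur, seed=3)
            loc = ev.locate_events(events, samples, a_tag=cfg.a_tag)
            w, _ = ev.dwell_adjust_events(loc, norm_const=2 / math.pi)
            geo = ev.VolumeGeometry(origin=(-20, -20, -20), voxel=(4, 4, 4),
                                    shape=(10, 10, 10))
            vol = ev.assemble_volume(w, samples, geo, f_tag=cfg.f_tag)
            out.append(np.nanmean(vol.rate))
        assert out[0] == pytest.approx(out[1], rel=0.03)


class TestMovies:
    def test_default_time_step_is_94ms(self):
        cfg = scan.ScanConfig()
        tau = scan.raster_characteristic_time(cfg)
        assert round(1000 * tau / 2) == 94

    def test_constant_rate_movie_flat_and_conserving(self):
        cfg, events, samples = _uniform_stream(3e5, 0.4, seed=4)
        loc = ev.locate_events(events, samples, a_tag=cfg.a_tag)
        w, _ = ev.dwell_adjust_events(loc)
        geo = ev.VolumeGeometry(origin=(-20, -20, -24), voxel=(4, 4, 6),
                                shape=(10, 10, 8))
        raw = ev.assemble_movie({"red": w}, samples, geo, time_bin=0.1,
                                f_tag=cfg.f_tag, smooth_sigma=0.0)
        sm = ev.assemble_movie({"red": w}, samples, geo, time_bin=0.1,
                               f_tag=cfg.f_tag, smooth_sigma=1.0)
        # smoothing preserves total counts (unit kernel, reflecting edges)
        assert sm.counts["red"].sum() == pytest.approx(
            raw.counts["red"].sum(), rel=1e-9
        )
        r = raw.rate("red")
        per_bin = np.nanmean(r.reshape(r.shape[0], -1), axis=1)
        assert np.std(per_bin) / np.mean(per_bin) < 0.1

    def test_time_bin_validation(self):
        cfg, events, samples = _uniform_stream(1e4, 0.02, seed=5)
        geo = ev.VolumeGeometry(origin=(-20, -20, -20), voxel=(4, 4, 4),
                                shape=(10, 10, 10))
        with pytest.raises(ValueError):
            ev.assemble_movie({"red": events}, samples, geo, time_bin=0.0)


class TestTrackedVsRaw:
    def test_tracker_correction_sharpens_moving_reconstruction(
        self, crawling_phantom
    ):
        """For a translating sample, the tracker-corrected frame stays sharp
        while the raw (uncorrected) frame smears along the motion path."""
        ph = crawling_phantom
        cfg = scan.ScanConfig()
        t0, t1 = 1.2, 2.6  # spans one ~100 µm stride lurch
        traj = scan.pong_trajectory(cfg, t1 - t0)
        center = ph.reference_path(t0 + traj.t)  # ideal tracking
        rng = np.random.default_rng(9)
        events = ph.emit_photons(traj, rng, t0=t0, center=center,
                                 channels=("red",))
        samples = pd.DataFrame(
            {
                "t_s": t0 + traj.t,
                "x_galvo_um": traj.x + center[:, 0],
                "y_galvo_um": traj.y + center[:, 1],
                "x_tracker_um": center[:, 0],
                "y_tracker_um": center[:, 1],
                "phi_rad": traj.phi,
                "z_off_um": 0.0,
            }
        )
        contrasts = {}
        for raw in (False, True):
            loc = ev.locate_events(events, samples, a_tag=cfg.a_tag, raw=raw)
            w, _ = ev.dwell_adjust_events(loc)
            lo = w[["x_um", "y_um", "z_um"]].quantile(0.02).to_numpy() - 5
            hi = w[["x_um", "y_um", "z_um"]].quantile(0.98).to_numpy() + 5
            geo = ev.VolumeGeometry(
                origin=tuple(lo), voxel=(2, 2, 4),
                shape=tuple(int(np.ceil((hi[i] - lo[i]) / v))
                            for i, v in enumerate((2, 2, 4))),
            )
            vol = ev.assemble_volume(w, samples, geo, f_tag=cfg.f_tag,
                                     raw=raw)
            r = vol.rate[vol.mask]
            contrasts[raw] = float(np.nanmax(r) / np.nanmean(r))
        assert contrasts[False] > contrasts[True]


class TestSmoothTemplate:
    def _flat_volume(self):
        geo = ev.VolumeGeometry(origin=(0, 0, 0), voxel=(1, 1, 1),
                                shape=(16, 16, 8))
        counts = np.full(geo.shape, 5.0)
        dwell = np.ones(geo.shape)
        return ev.RateVolume(counts=counts, dwell=dwell, geometry=geo)

    def test_flat_complete_input_unchanged(self):
        tpl = ev.smooth_template(self._flat_volume())
        assert np.allclose(tpl.grid, 5.0, rtol=1e-6)

    def test_interior_gap_filled_between_neighbors(self):
        geo = ev.VolumeGeometry(origin=(0, 0, 0), voxel=(1, 1, 1),
                                shape=(9, 5, 5))
        counts = np.zeros(geo.shape)
        dwell = np.ones(geo.shape)
        counts[:4] = 2.0
        counts[5:] = 4.0
        dwell[4, 2, 2] = 0.0  # missing voxel between the 2s and the 4s
        counts[4] = 3.0
        counts[4, 2, 2] = 0.0
        vol = ev.RateVolume(counts=counts, dwell=dwell, geometry=geo)
        tpl = ev.smooth_template(vol, robust=False)
        assert 2.0 <= tpl.grid[4, 2, 2] <= 4.0

    def test_gaussian_blob_reconstructed_with_30pct_missing(self, rng):
        geo = ev.VolumeGeometry(origin=(-16, -16, -8), voxel=(1, 1, 1),
                                shape=(32, 32, 16))
        xx, yy, zz = np.meshgrid(*geo.centers, indexing="ij")
        field = 100.0 * np.exp(-(xx**2 + yy**2) / (2 * 36.0) - zz**2 / (2 * 16.0))
        mask = rng.uniform(size=geo.shape) > 0.3
        vol = ev.RateVolume(
            counts=np.where(mask, field, 0.0), dwell=mask.astype(float),
            geometry=geo,
        )
        tpl = ev.smooth_template(vol, robust=False)
        rmse = np.sqrt(((tpl.grid - field) ** 2).mean())
        assert rmse < 0.05 * field.max()

    def test_outlier_replaced_in_robust_mode(self):
        vol = self._flat_volume()
        vol.counts[8, 8, 4] = 500.0  # lone hot voxel
        tpl = ev.smooth_template(vol, robust=True)
        assert tpl.grid[8, 8, 4] < 50.0

    def test_insufficient_coverage_raises(self):
        geo = ev.VolumeGeometry(origin=(0, 0, 0), voxel=(1, 1, 1),
                                shape=(10, 10, 10))
        vol = ev.RateVolume(
            counts=np.zeros(geo.shape), dwell=np.zeros(geo.shape), geometry=geo
        )
        vol.dwell[0, 0, :5] = 1.0  # 0.5% coverage
        with pytest.raises(ev.InsufficientCoverageError):
            ev.smooth_template(vol)

    def test_template_evaluable_and_zero_outside(self):
        tpl = ev.smooth_template(self._flat_volume())
        inside = tpl(np.array([[8.0, 8.0, 4.0]]))[0]
        outside = tpl(np.array([[100.0, 100.0, 100.0]]))[0]
        assert inside == pytest.approx(5.0, rel=1e-6)
        assert outside == 0.0
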
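"""Ratiometry, stride-aligned cubes, wave PCA and bout statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pongscope import waves as wv
from pongscope.events import RateMovie, VolumeGeometry


class TestBaselineClip:
    def test_constant_series(self):
        assert wv.baseline_clip([2.0, 2.0, 2.0, 2.0]) == 2.0

    def test_single_outlier_removed(self):
        # hand iteration: mean 3.25, sd ~3.9 clips 10; then mean 1
        assert wv.baseline_clip([1.0, 1.0, 1.0, 10.0]) == pytest.approx(1.0)

    def test_non_increasing_across_iterations(self, rng):
        for _ in range(20):
            x = rng.lognormal(0, 1, 50)
            assert wv.baseline_clip(x) <= x.mean() + 1e-12

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            wv.baseline_clip([1.0, 2.0])


def _plane_wave_cube(k=2 * math.pi / 60.0, nx=40, ny=12, nb=24, amp=0.5,
                     noise=0.0, rng=None, reverse=False):
    x = np.arange(nx) * 2.0
    y = np.arange(ny) * 2.0
    phase = (np.arange(nb) + 0.5) * 2 * math.pi / nb
    ks = -k if reverse else k
    vals = 1.0 + amp * np.cos(ks * x[:, None, None] - phase[None, None, :])
    vals = vals * np.ones((1, ny, 1))
    if noise and rng is not None:
        vals = vals + rng.normal(0, noise, vals.shape)
    return wv.StrideAlignedCube(
        values=vals, counts=vals, dwell=np.ones_like(vals), x=x, y=y, n_strides=6
    )


def _movie(green, red, voxel=(2.0, 2.0, 4.0)):
    nt = green.shape[0]
    geo = VolumeGeometry(origin=(0, 0, 0), voxel=voxel,
                         shape=green.shape[1:])
    return RateMovie(
        counts={"green": green, "red": red}, dwell=np.ones_like(green),
        geometry=geo, time_edges=np.arange(nt + 1) * 0.1,
    )


class TestVoiRatio:
    def test_uniform_two_to_one_ratio(self):
        shape = (20, 8, 8, 4)
        red = np.full(shape, 3.0)
        movie = _movie(2.0 * red, red)
        tr = wv.voi_ratio(movie, [{"center_um": (8, 8, 8), "radius_um": 6.0}])[0]
        assert np.allclose(tr.ratio, 2.0)
        assert np.allclose(tr.normalized, 1.0)

    def test_ratiometric_invariance(self, rng):
        """A shared multiplicative field cancels in the normalized ratio."""
        shape = (20, 8, 8, 4)
        green = rng.uniform(1, 3, shape)
        red = rng.uniform(1, 3, shape)
        movie = _movie(green, red)
        field = rng.uniform(0.5, 2.0, shape)
        movie2 = _movie(green * field, red * field)
        voi = [{"center_um": (8, 8, 8), "radius_um": 6.0}]
        a = wv.voi_ratio(movie, voi)[0]
        b = wv.voi_ratio(movie2, voi)[0]
        # pooling changes weights, so compare bin-wise ratios loosely
        assert np.allclose(a.normalized, b.normalized, rtol=0.15)

    def test_zero_dwell_bin_missing(self):
        shape = (5, 8, 8, 4)
        red = np.full(shape, 3.0)
        movie = _movie(red, red)
        movie.dwell[2] = 0.0
        tr = wv.voi_ratio(movie, [{"center_um": (8, 8, 8), "radius_um": 6.0}])[0]
        assert np.isnan(tr.ratio[2])
        assert np.isfinite(np.delete(tr.ratio, 2)).all()


class TestTimespace:
    def test_uniform_map_is_one(self):
        shape = (10, 16, 6, 4)
        red = np.full(shape, 2.0)
        movie = _movie(3.0 * red, red)
        m, xs, ts = wv.timespace_projection(movie, {})
        assert np.allclose(m, 1.0)
        assert np.nanmedian(m) == pytest.approx(1.0)

    def test_travelling_ridge_slope(self):
        """A wave moving at speed c makes ridges of slope c in (space, time)."""
        nt, nx = 40, 30
        x = np.arange(nx) * 2.0
        t = np.arange(nt) * 0.1
        c = 40.0  # µm/s
        k = 2 * math.pi / 30.0
        green = 2.0 + np.cos(k * (x[None, :, None, None] - c * t[:, None, None, None]))
        green = np.broadcast_to(green, (nt, nx, 4, 2)).copy()
        red = np.ones_like(green)
        movie = _movie(green, red)
        m, xs, ts = wv.timespace_projection(movie, {})
        # ridge position per time bin: argmax of the map along space
        ridge = xs[np.argmax(m, axis=0)]
        steps = np.diff(ridge)
        wrap = 2 * math.pi / k
        steps = (steps + wrap / 2) % wrap - wrap / 2
        speed = np.mean(steps) / 0.1
        assert speed == pytest.approx(c, rel=0.2)


class TestStrideAverage:
    @staticmethod
    def _flat_streams(rng, n_strides=4, rate=5e4):
        """Constant-rate photon/sample streams over a linear phase clock."""
        from pongscope.behavior import PhaseClock

        dt = 1e-4
        t = np.arange(0.0, n_strides * 1.0, dt)
        clock = PhaseClock(t=t, phi=2 * math.pi * t)
        samples = pd.DataFrame(
            {
                "t_s": t,
                "x_um": rng.uniform(0, 40, t.size),
                "y_um": rng.uniform(0, 20, t.size),
            }
        )
        counts = rng.poisson(rate * dt, t.size)
        rep = np.repeat(np.arange(t.size), counts)
        events = pd.DataFrame(
            {
                "t_s": t[rep],
                "x_um": samples["x_um"].to_numpy()[rep],
                "y_um": samples["y_um"].to_numpy()[rep],
                "weight": 1.0,
            }
        )
        return events, samples, clock

    def test_default_bins_are_15_degrees(self, rng):
        from pongscope.events import VolumeGeometry

        events, samples, clock = self._flat_streams(rng)
        geo = VolumeGeometry(origin=(0, 0, 0), voxel=(8, 8, 10),
                             shape=(5, 3, 1))
        cube = wv.stride_average(events, samples, clock, geo, f_tag=1.9e5)
        assert cube.n_bins == 24
        width = np.diff(cube.phase_centers)
        assert np.allclose(np.degrees(width), 15.0)

    def test_phase_independent_signal_gives_flat_cube(self, rng):
        from pongscope.events import VolumeGeometry

        events, samples, clock = self._flat_streams(rng)
        geo = VolumeGeometry(origin=(0, 0, 0), voxel=(8, 8, 10),
                             shape=(5, 3, 1))
        cube = wv.stride_average(events, samples, clock, geo, f_tag=1.9e5)
        v = cube.values[np.all(np.isfinite(cube.values), axis=2)]
        rel = v.std(axis=1) / v.mean(axis=1)
        assert np.median(rel) < 0.15  # flat in phase within Poisson noise
        assert len(cube.empty_bins) == 0

    def test_too_few_strides_rejected(self, rng):
        from pongscope.behavior import PhaseClock
        from pongscope.events import VolumeGeometry

        events, samples, _ = self._flat_streams(rng, n_strides=4)
        short = PhaseClock(t=np.array([0.0, 0.5]), phi=np.array([0.0, 3.0]))
        geo = VolumeGeometry(origin=(0, 0, 0), voxel=(8, 8, 10),
                             shape=(5, 3, 1))
        with pytest.raises(ValueError):
            wv.stride_average(events, samples, short, geo)


class TestWavePCA:
    def test_pure_wave_components(self):
        cube = _plane_wave_cube()
        d = wv.wave_pca(cube)
        assert d.var_share_pc12 >= 0.99
        phase = cube.phase_centers
        f1 = np.sum(d.c1 * np.exp(-1j * phase))
        f2 = np.sum(d.c2 * np.exp(-1j * phase))
        rel = math.degrees(np.angle(f1 * np.conj(f2)))
        assert rel == pytest.approx(90.0, abs=5.0)

    def test_phase_gradient_matches_wave_vector(self):
        k = 2 * math.pi / 60.0
        cube = _plane_wave_cube(k=k)
        d = wv.wave_pca(cube)
        psi = np.unwrap(np.angle(d.g[:, 5]))
        slope = np.polyfit(cube.x, psi, 1)[0]
        assert abs(slope) == pytest.approx(k, rel=0.05)

    def test_reversed_wave_flips_phase_gradient(self):
        d1 = wv.wave_pca(_plane_wave_cube())
        d2 = wv.wave_pca(_plane_wave_cube(reverse=True))
        s1 = np.polyfit(np.arange(40), np.unwrap(np.angle(d1.g[:, 5])), 1)[0]
        s2 = np.polyfit(np.arange(40), np.unwrap(np.angle(d2.g[:, 5])), 1)[0]
        assert np.sign(s1) == -np.sign(s2)
        assert np.allclose(np.abs(d1.g), np.abs(d2.g), rtol=1e-6)

    def test_flat_cube_rejected(self):
        cube = _plane_wave_cube(amp=0.0)
        with pytest.raises(ValueError):
            wv.wave_pca(cube)


class TestVarianceExplained:
    def test_pure_wave_explained(self):
        cube = _plane_wave_cube()
        d = wv.wave_variance_explained(cube, wv.wave_pca(cube))
        assert d.variance_explained >= 0.95
        assert np.linalg.norm(d.k_vec) == pytest.approx(2 * math.pi / 60.0,
                                                        rel=0.05)

    def test_shuffled_phases_fail_constraint(self, rng):
        """Spatially shuffled phases with the same amplitudes are not a wave."""
        cube = _plane_wave_cube()
        worst = -np.inf
        for _ in range(100):
            d = wv.wave_pca(cube)
            amp = np.abs(d.g)
            psi = np.angle(d.g)
            flat = psi[d.valid]
            psi[d.valid] = flat[rng.permutation(flat.size)]
            d.g = amp * np.exp(1j * psi)
            d = wv.wave_variance_explained(cube, d)
            worst = max(worst, d.variance_explained)
        assert worst <= 0.1

    def test_zero_amplitude_convention(self):
        cube = _plane_wave_cube()
        d = wv.wave_pca(cube)
        d.g = np.zeros_like(d.g)
        d = wv.wave_variance_explained(cube, d)
        assert d.variance_explained == 0.0

    def test_noise_only_cube_not_wavelike(self, rng):
        cube = _plane_wave_cube(amp=0.0, noise=0.3, rng=rng)
        d = wv.wave_variance_explained(cube, wv.wave_pca(cube))
        assert d.variance_explained < 0.5


class TestBoutStats:
    @staticmethod
    def _phantom_bout_means(rng, n_bouts, gain, strides_per_bout=6,
                            photons_per_stride=2000):
        """Per-bout mean normalized ratios from the activity model: each
        stride integrates Poisson photons whose rate carries the class gain."""
        out = []
        for _ in range(n_bouts):
            g = rng.poisson(gain * photons_per_stride, strides_per_bout)
            r = rng.poisson(photons_per_stride, strides_per_bout)
            out.append((g / np.maximum(r, 1)).mean())
        return out

    def _trace_and_bouts(self, rng, n_fwd, n_bwd, bwd_gain):
        fwd = self._phantom_bout_means(rng, n_fwd, 1.0)
        bwd = self._phantom_bout_means(rng, n_bwd, bwd_gain)
        vals, bouts, t0 = [], [], 0.0
        for i, v in enumerate(fwd + bwd):
            state = "forward" if i < n_fwd else "backward"
            bouts.append((state, t0, t0 + 1.0))
            vals.append(v)
            t0 += 1.0
        t = np.arange(len(vals)) + 0.5
        arr = np.array(vals)
        tr = wv.RatioTrace(t=t, green_rate=arr, red_rate=np.ones_like(arr),
                           baseline=1.0)
        return tr, bouts

    def test_null_distribution_calibrated(self):
        """Same-distribution bouts: p >= 0.05 in at least 90% of seeded runs."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            tr, bouts = self._trace_and_bouts(rng, 8, 8, bwd_gain=1.0)
            out = wv.bout_stats(tr, bouts)
            if out["p_backward_gt_forward"] >= 0.05:
                hits += 1
        assert hits >= 90

    def test_power_at_1p5x_gain(self):
        for seed in range(5):
            rng = np.random.default_rng(1000 + seed)
            tr, bouts = self._trace_and_bouts(rng, 10, 10, bwd_gain=1.5)
            out = wv.bout_stats(tr, bouts)
            assert out["p_backward_gt_forward"] < 0.01

    def test_single_bout_skips_test(self, rng):
        tr, bouts = self._trace_and_bouts(rng, 1, 1, bwd_gain=1.0)
        out = wv.bout_stats(tr, bouts)
        assert out["test_skipped"]
        assert np.isfinite(out["median_forward"])

    def test_exact_method_matches_scipy_exact(self, rng):
        fwd = list(rng.normal(1.0, 0.1, 6))
        bwd = list(rng.normal(1.3, 0.1, 6))
        ref = stats.mannwhitneyu(bwd, fwd, alternative="greater",
                                 method="exact").pvalue
        tr, bouts = self._trace_and_bouts(rng, 6, 6, 1.0)
        # overwrite with the reference samples
        tr.green_rate[:6] = fwd
        tr.green_rate[6:] = bwd
        out = wv.bout_stats(tr, bouts)
        assert out["p_backward_gt_forward"] == pytest.approx(ref)
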
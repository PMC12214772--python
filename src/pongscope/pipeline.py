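"""End-to-end orchestration: simulate -> track -> reconstruct -> register
-> strides -> waves, with file I/O for each stage.

Every stage has a pure in-memory core (used by :func:`run_demo` and the
tests) and a thin file wrapper (used by the command-line interface), so the
stages can be run independently on the previous stage's outputs.  A single
seeded random stream is split into named substreams per stage, making each
stage individually reproducible.

Photon/sample streams are written as HDF5 tables (they run to millions of
rows); small tables (tracking record, stride tables, traces) as CSV; scalar
results and QC tallies as JSON; volumes and cubes as TIFF.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as bh
from . import events as ev
from . import register as rg
from . import waves as wv
from .phantom import (
    LASER_PERIOD_NS,
    TRACKING_PHASE_OFFSET_NS,
    BoutSpec,
    Phantom,
    PhantomConfig,
    build_phantom,
)
from .scan import ScanConfig, pong_trajectory, raster_characteristic_time
from .tracker import TrackerConfig, TrackRecord, closed_loop_track

__all__ = [
    "RunConfig",
    "SimulationResult",
    "run_demo",
    "validate_tables",
    "core_simulate",
    "core_reconstruct",
    "core_register",
    "core_strides",
    "core_waves",
]

log = logging.getLogger("pongscope")


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    """Nested configuration for a full synthetic run."""

    scan: ScanConfig = field(default_factory=ScanConfig)
    # demo-scale phantom: one forward and one backward bout, mild rotation
    phantom: PhantomConfig = field(default_factory=lambda: PhantomConfig(
        bouts=(
            BoutSpec("forward", n_strides=8, pause_after=0.5),
            BoutSpec("backward", n_strides=3, pause_after=0.5),
        ),
        start_pause=1.0,
        rotation_amplitude=0.08,
        deform_amplitude=0.0,
    ))
    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    seed: int = 0
    movie_voxel: tuple[float, float, float] = (2.0, 2.0, 4.0)
    template_voxel: tuple[float, float, float] = (1.0, 1.0, 2.0)
    frame_oversample: float = 3.125
    nonrigid: bool = False
    nonrigid_grid_um: float = 20.0
    intensity_grid_um: float = 25.0
    n_phase_bins: int = 24
    voi_radius_um: float = 8.0
    cube_pixel_um: float = 4.0
    tissue_threshold: float = 0.15  # red-rate fraction defining the tissue mask

    @property
    def frame_duration(self) -> float:
        return rg.default_frame_duration(
            self.scan.a_x, self.scan.y_range, self.scan.tau_min, self.frame_oversample
        )

    @property
    def movie_time_step(self) -> float:
        return raster_characteristic_time(self.scan) / 2.0

    # ------------------------------------------------------------- serialise
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phantom"]["bouts"] = [dataclasses.asdict(b) for b in self.phantom.bouts]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        try:
            kw = dict(d)
            if "scan" in kw:
                kw["scan"] = ScanConfig(**kw["scan"])
            if "phantom" in kw:
                ph = dict(kw["phantom"])
                if "bouts" in ph:
                    ph["bouts"] = tuple(BoutSpec(**b) for b in ph["bouts"])
                kw["phantom"] = PhantomConfig(**ph)
            if "tracker" in kw:
                kw["tracker"] = TrackerConfig(**kw["tracker"])
            if "movie_voxel" in kw:
                kw["movie_voxel"] = tuple(kw["movie_voxel"])
            if "template_voxel" in kw:
                kw["template_voxel"] = tuple(kw["template_voxel"])
            return cls(**kw)
        except (TypeError, ValueError) as e:
            raise ConfigError(str(e)) from e

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=False)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)


# ------------------------------------------------------------------ simulate
@dataclass
class SimulationResult:
    phantom: Phantom
    track: TrackRecord
    events: pd.DataFrame
    samples: pd.DataFrame


def core_simulate(cfg: RunConfig, duration: float | None = None) -> SimulationResult:
    """Phantom + closed-loop tracking + photon/sample streams.

    The imaging scan is centered on the tracker's running estimate (as on
    the instrument, where the estimated target location is added to the
    imaging galvo deflection), so tracking error — not gross motion — is
    what blurs the tracked-frame reconstruction.
    """
    phantom = build_phantom(cfg.phantom)
    horizon = duration if duration is not None else cfg.phantom.duration
    track = closed_loop_track(
        phantom, cfg.tracker, horizon, seed=_stage_seed(cfg.seed, "track")
    )
    tt = track.table
    traj = pong_trajectory(cfg.scan, horizon - 2 * cfg.tracker.cycle_period)
    est = np.stack(
        [
            np.interp(traj.t, tt["t_s"], tt[f"est_{ax}_um"])
            for ax in ("x", "y", "z")
        ],
        axis=1,
    )
    rng = np.random.default_rng(_stage_seed(cfg.seed, "emit"))
    events = phantom.emit_photons(traj, rng, center=est, path="imaging")
    # tracking-path red photons, reconstructed from the per-cycle counts
    n_tr = tt["n_photons"].to_numpy()
    t_tr = np.repeat(tt["t_s"].to_numpy(), n_tr) - rng.uniform(
        0, cfg.tracker.cycle_period, int(n_tr.sum())
    )
    from .phantom import ARRIVAL_LAG_NS

    tr_events = pd.DataFrame(
        {
            "t_s": t_tr,
            "channel": pd.Categorical(
                np.full(t_tr.size, "red"), categories=["red", "green"]
            ),
            "path": pd.Categorical(
                np.full(t_tr.size, "tracking"), categories=["imaging", "tracking"]
            ),
            "arrival_phase_ns": (
                TRACKING_PHASE_OFFSET_NS
                + ARRIVAL_LAG_NS
                + rng.normal(0, 0.5, t_tr.size)
            )
            % LASER_PERIOD_NS,
        }
    )
    keep = (t_tr >= traj.t[0]) & (t_tr < traj.t[-1])
    events = (
        pd.concat([events, tr_events[keep]], ignore_index=True)
        .sort_values("t_s", ignore_index=True)
    )
    samples = pd.DataFrame(
        {
            "t_s": traj.t,
            "x_galvo_um": traj.x + est[:, 0],
            "y_galvo_um": traj.y + est[:, 1],
            "x_tracker_um": est[:, 0],
            "y_tracker_um": est[:, 1],
            "phi_rad": traj.phi,
            "z_off_um": 0.0,
        }
    )
    return SimulationResult(phantom=phantom, track=track, events=events, samples=samples)


# --------------------------------------------------------------- reconstruct
def core_reconstruct(
    events: pd.DataFrame,
    samples: pd.DataFrame,
    cfg: RunConfig,
) -> dict:
    """Demultiplex, locate, dwell-adjust; return located imaging events + QC."""
    demuxed = ev.demultiplex_events(events)
    imaging = demuxed[demuxed["path"] == "imaging"]
    located = ev.locate_events(imaging, samples, a_tag=cfg.scan.a_tag)
    weighted, qc = ev.dwell_adjust_events(
        located, cfg.scan.norm_const, cfg.scan.phi_exclude_deg
    )
    return {"located": weighted, "qc": qc}


def _percentile_geometry(
    pts: np.ndarray, voxel: tuple[float, float, float], margin: float = 12.0
) -> ev.VolumeGeometry:
    lo = np.percentile(pts, 0.5, axis=0) - margin
    hi = np.percentile(pts, 99.5, axis=0) + margin
    shape = tuple(
        max(4, int(math.ceil((hi[i] - lo[i]) / voxel[i]))) for i in range(3)
    )
    return ev.VolumeGeometry(origin=tuple(lo), voxel=voxel, shape=shape)


# ------------------------------------------------------------------ register
def core_register(
    located: pd.DataFrame,
    samples: pd.DataFrame,
    cfg: RunConfig,
    template_epoch: tuple[float, float] | None = None,
) -> dict:
    """Red-channel rigid (+ optional FFD) + intensity correction.

    Returns the template, per-frame transforms, and both channels' events
    plus sample line centers mapped into template coordinates.
    """
    red = located[located["channel"] == "red"]
    green = located[located["channel"] == "green"]
    if template_epoch is None:
        template_epoch = (0.05, max(0.3, cfg.phantom.start_pause - 0.05))
    t0, t1 = template_epoch
    ref = red[(red["t_s"] >= t0) & (red["t_s"] < t1)]
    geom = _percentile_geometry(
        ref[["x_um", "y_um", "z_um"]].to_numpy(), cfg.template_voxel
    )
    vol = ev.assemble_volume(ref, samples, geom, cfg.scan.f_tag, epoch=template_epoch)
    template = ev.smooth_template(vol, sigma=1.0)

    t_end = float(samples["t_s"].iloc[-1])
    windows = rg.frame_windows(0.0, t_end, cfg.frame_duration)
    rng = np.random.default_rng(_stage_seed(cfg.seed, "register"))
    sline = ev.emission_location(samples, cfg.scan.a_tag)
    # scan-path quadrature for the intensity likelihood: every 8th line,
    # expanded to 8 z-points along the axial sweep (uniform in TAG phase,
    # the physical dwell measure); each point carries one line-time of dwell
    sub_phi = (np.arange(8) + 0.5) * math.pi / 8.0
    line_time = 1.0 / (2.0 * cfg.scan.f_tag)
    corrected_red, corrected_green, corrected_samples = [], [], []
    transforms = []
    prev: rg.RigidTransform | None = None
    for w0, w1 in windows:
        fr = red[(red["t_s"] >= w0) & (red["t_s"] < w1)]
        fg = green[(green["t_s"] >= w0) & (green["t_s"] < w1)]
        pts = fr[["x_um", "y_um", "z_um"]].to_numpy()
        # warm-start each frame from its predecessor (motion is continuous)
        tr = rg.rigid_register(
            pts, template, rng=rng, init=prev, coarse_subsample=8000,
            maxiter=(200, 600) if prev is not None else (400, 1500),
        )
        if not tr.flagged:
            prev = tr
        deform = None
        if cfg.nonrigid and not tr.flagged:
            fvol = ev.assemble_volume(
                _apply_rigid(fr, tr), samples, geom, cfg.scan.f_tag, epoch=(w0, w1)
            )
            deform = rg.nonrigid_register(
                fvol, template, grid_spacing=cfg.nonrigid_grid_um
            )
        alpha = None
        if not tr.flagged:
            smask = (samples["t_s"].to_numpy() >= w0) & (samples["t_s"].to_numpy() < w1)
            lines = samples.loc[smask].iloc[::8]
            xy = sline[smask][::8, :2]
            zq = cfg.scan.a_tag * np.cos(
                lines["phi_rad"].to_numpy()[:, None] + sub_phi[None, :]
            )
            spath = np.column_stack(
                [
                    np.repeat(xy[:, 0], 8),
                    np.repeat(xy[:, 1], 8),
                    zq.ravel(),
                ]
            )
            spath = tr.apply(spath)
            if deform is not None:
                spath = deform.apply(spath)
            sub = pts
            if len(sub) > 10_000:
                sub = sub[rng.choice(len(sub), 10_000, replace=False)]
                alpha_scale = len(pts) / 10_000.0
            else:
                alpha_scale = 1.0
            reg_pts = tr.apply(sub)
            if deform is not None:
                reg_pts = deform.apply(reg_pts)
            alpha = rg.intensity_correct(
                reg_pts, spath, line_time / alpha_scale,
                template, grid_spacing=cfg.intensity_grid_um, maxiter=60,
            )
        cr, cg, qc = rg.apply_corrections(fr, fg, tr, deform, alpha, template)
        corrected_red.append(cr)
        corrected_green.append(cg)
        smask = (samples["t_s"].to_numpy() >= w0) & (samples["t_s"].to_numpy() < w1)
        sl_pts = tr.apply(sline[smask])
        if deform is not None:
            sl_pts = deform.apply(sl_pts)
        corrected_samples.append(
            pd.DataFrame(
                {
                    "t_s": samples["t_s"].to_numpy()[smask],
                    "x_um": sl_pts[:, 0],
                    "y_um": sl_pts[:, 1],
                    "z_um": sl_pts[:, 2],
                }
            )
        )
        transforms.append({"t0_s": w0, "t1_s": w1, "rigid": tr.to_dict()})
    out_events = pd.concat(corrected_red + corrected_green, ignore_index=True)
    out_events = out_events.sort_values("t_s", ignore_index=True)
    return {
        "template": template,
        "template_geometry": geom,
        "transforms": transforms,
        "events": out_events,
        "samples": pd.concat(corrected_samples, ignore_index=True),
    }


def _apply_rigid(events: pd.DataFrame, tr: rg.RigidTransform) -> pd.DataFrame:
    out = events.copy()
    out[["x_um", "y_um", "z_um"]] = tr.apply(out[["x_um", "y_um", "z_um"]].to_numpy())
    return out


# ------------------------------------------------------------------- strides
def core_strides(track: TrackRecord, phantom: Phantom, decimate: int = 29) -> list[dict]:
    """Behavioral phase clocks per crawling bout from the tracked path.

    Uses the tracker's estimated 2D path (decimated to ~10 ms sampling) and
    the phantom's heading; bout labels come from the phantom truth (they
    are an input to the method, not something it infers).
    """
    tt = track.table.iloc[::decimate]
    t = tt["t_s"].to_numpy()
    xy = tt[["est_x_um", "est_y_um"]].to_numpy()
    heading = phantom.heading_at(t)
    out = []
    for state, b0, b1 in phantom.behavior.bouts:
        sel = (t >= b0) & (t < b1)
        if sel.sum() < 16:
            continue
        clock, strides, template = bh.phase_clock_for_bout(
            t[sel], xy[sel], heading[sel], mode=state
        )
        out.append(
            {"state": state, "t0_s": b0, "t1_s": b1, "clock": clock,
             "strides": strides, "template": template}
        )
    return out


# --------------------------------------------------------------------- waves
def core_waves(
    reg: dict,
    clocks: list[dict],
    phantom: Phantom,
    cfg: RunConfig,
) -> dict:
    """Stride-aligned cubes, wave PCA, VOI traces and bout statistics."""
    events, samples = reg["events"], reg["samples"]
    geom = reg["template_geometry"]
    # 2D grid for stride-aligned cubes
    px = cfg.cube_pixel_um
    cube_geom = ev.VolumeGeometry(
        origin=geom.origin,
        voxel=(px, px, geom.voxel[2] * geom.shape[2]),
        shape=(
            int(math.ceil(geom.shape[0] * geom.voxel[0] / px)),
            int(math.ceil(geom.shape[1] * geom.voxel[1] / px)),
            1,
        ),
    )
    fwd = [c for c in clocks if c["state"] == "forward"]
    result: dict = {}
    if fwd:
        clock = fwd[0]["clock"]
        cubes = {}
        for ch in ("green", "red"):
            cubes[ch] = wv.stride_average(
                events[events["channel"] == ch], samples, clock, cube_geom,
                n_bins=cfg.n_phase_bins, f_tag=cfg.scan.f_tag, channel=ch,
            )
        # wave statistics are computed within tissue: mask pixels by the
        # stable (red) channel's phase-averaged rate
        red_mean = np.nanmean(cubes["red"].values, axis=2)
        thr = cfg.tissue_threshold * np.nanpercentile(red_mean, 99)
        tissue = np.nan_to_num(red_mean) > thr
        for cube in cubes.values():
            cube.values[~tissue] = np.nan
        decomp = wv.wave_pca(cubes["green"])
        decomp = wv.wave_variance_explained(cubes["green"], decomp)
        result["cubes"] = cubes
        result["tissue_mask"] = tissue
        result["decomposition"] = decomp
        result["wave_variance_explained"] = decomp.variance_explained

    # VOI traces on an unsmoothed movie in template coordinates
    movie_geom = ev.VolumeGeometry(
        origin=geom.origin, voxel=cfg.movie_voxel,
        shape=tuple(
            int(math.ceil(geom.shape[i] * geom.voxel[i] / cfg.movie_voxel[i]))
            for i in range(3)
        ),
    )
    movie = ev.assemble_movie(
        events, samples, movie_geom, time_bin=cfg.movie_time_step,
        f_tag=cfg.scan.f_tag, smooth_sigma=0.0,
    )
    # VOIs: forward-class (medial) cells per segment, in template coordinates
    t_mid = 0.5 * (reg["transforms"][0]["t0_s"] + reg["transforms"][0]["t1_s"])
    lab = phantom.emitter_lab_positions(np.array([t_mid]))[0]
    ref = lab[phantom.reference_index]
    rel = lab - ref
    from .phantom import CLASS_BACKWARD, CLASS_FORWARD

    vois_fwd = [
        {"center_um": rel[i].tolist(), "radius_um": cfg.voi_radius_um, "s_um": phantom.s_coord[i]}
        for i in np.flatnonzero(phantom.wave_class == CLASS_FORWARD)
    ]
    voi_bwd = [
        {
            "centers_um": [rel[i].tolist() for i in np.flatnonzero(phantom.wave_class == CLASS_BACKWARD)],
            "radius_um": cfg.voi_radius_um,
        }
    ]
    result["voi_definitions"] = {"forward": vois_fwd, "backward_class": voi_bwd}
    result["voi_traces"] = wv.voi_ratio(movie, vois_fwd)
    if "cubes" in result:
        result["voi_peak_phase"] = _voi_peak_phases(result["cubes"]["green"], vois_fwd)
    bwd_trace = wv.voi_ratio(movie, voi_bwd)[0]
    result["bout_stats"] = wv.bout_stats(bwd_trace, phantom.behavior.bouts)
    result["movie"] = movie
    return result


def _voi_peak_phases(cube: wv.StrideAlignedCube, vois: list[dict]) -> pd.DataFrame:
    """Phase of peak stride-averaged green signal per VOI (posterior first)."""
    xg, yg = np.meshgrid(cube.x, cube.y, indexing="ij")
    rows = []
    for voi in vois:
        c = voi["center_um"]
        m = (xg - c[0]) ** 2 + (yg - c[1]) ** 2 <= voi["radius_um"] ** 2
        if not m.any():
            continue
        trace = np.nanmean(cube.values[m], axis=0)
        if np.all(np.isnan(trace)):
            continue
        rows.append(
            {
                "s_um": voi.get("s_um", c[0]),
                "peak_phase_rad": float(cube.phase_centers[np.nanargmax(trace)]),
            }
        )
    if not rows:
        return pd.DataFrame(columns=["s_um", "peak_phase_rad"])
    df = pd.DataFrame(rows).sort_values("s_um", ignore_index=True)
    if len(df) >= 3:
        # unwrap along the body so a monotone progression is visible
        df["peak_phase_unwrapped_rad"] = np.unwrap(df["peak_phase_rad"].to_numpy())
    return df


# ---------------------------------------------------------------------- demo
def run_demo(cfg: RunConfig, outdir: str | Path) -> dict:
    """Full synthetic experiment; writes artifacts and returns a summary."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")
    import pongscope

    log.info("config hash %s seed %d pongscope %s numpy %s",
             cfg.config_hash, cfg.seed, pongscope.__version__, np.__version__)
    cfg.to_yaml(out / "config.yaml")

    stage = "simulate"
    try:
        sim = core_simulate(cfg)
        _write_streams(sim, out)
        stage = "reconstruct"
        rec = core_reconstruct(sim.events, sim.samples, cfg)
        stage = "register"
        reg = core_register(rec["located"], sim.samples, cfg)
        with open(out / "transforms.json", "w") as f:
            json.dump(reg["transforms"], f, indent=1)
        stage = "strides"
        clocks = core_strides(sim.track, sim.phantom)
        for i, c in enumerate(clocks):
            pd.DataFrame({"t_s": c["clock"].t, "phi_rad": c["clock"].phi}).to_csv(
                out / f"clock_{i}_{c['state']}.csv", index=False
            )
            c["strides"].to_csv(out / f"strides_{i}_{c['state']}.csv", index=False)
        stage = "waves"
        res = core_waves(reg, clocks, sim.phantom, cfg)
    except Exception:
        log.exception("stage %r failed; partial outputs preserved in %s", stage, out)
        raise
    summary = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash,
        "tracking_rms_error_um": sim.track.rms_error,
        "tracking_max_error_um": sim.track.max_error,
        "n_events": int(len(sim.events)),
        "qc": rec["qc"],
        "n_strides": {c["state"]: int(len(c["strides"])) for c in clocks},
        "wave_variance_explained": res.get("wave_variance_explained"),
        "voi_peak_phase": res.get("voi_peak_phase", pd.DataFrame()).to_dict("records"),
        "bout_stats": {
            k: v for k, v in res.get("bout_stats", {}).items() if k != "bouts"
        },
    }
    with open(out / "summary.json", "w") as f:
        json.dump(summary, f, indent=1, default=float)
    _write_waves(res, out)
    log.info("demo complete: wave VE=%s", summary["wave_variance_explained"])
    return summary


def _write_streams(sim: SimulationResult, out: Path) -> None:
    try:
        sim.events.to_hdf(out / "events.h5", key="events", mode="w",
                          format="table")
        sim.samples.to_hdf(out / "samples.h5", key="samples", mode="w")
    except ImportError:  # no pytables: fall back to CSV
        sim.events.to_csv(out / "events.csv", index=False)
        sim.samples.to_csv(out / "samples.csv", index=False)
    sim.track.table.to_csv(out / "track.csv", index=False)
    truth_t = np.arange(0.0, sim.phantom.cfg.duration, 0.01)
    pose = sim.phantom.pose_at(truth_t)
    pd.DataFrame(
        {
            "t_s": truth_t,
            "x_um": pose.translation[:, 0],
            "y_um": pose.translation[:, 1],
            "z_um": pose.translation[:, 2],
            "angle_rad": pose.angle,
            "tilt_rad": pose.tilt,
            "deform_envelope": pose.deform_envelope,
            "phi_true_rad": sim.phantom.phi_true(truth_t),
        }
    ).to_csv(out / "truth_pose.csv", index=False)
    with open(out / "truth_behavior.json", "w") as f:
        json.dump(
            {
                "bouts": sim.phantom.behavior.bouts,
                "stride_times_s": {
                    str(k): v.tolist()
                    for k, v in sim.phantom.behavior.stride_times.items()
                },
            },
            f,
            indent=1,
        )


def _write_waves(res: dict, out: Path) -> None:
    import tifffile

    if "cubes" in res:
        for ch, cube in res["cubes"].items():
            tifffile.imwrite(
                out / f"cube_{ch}.tif",
                np.moveaxis(np.nan_to_num(cube.values), 2, 0).astype(np.float32),
            )
        d = res["decomposition"]
        with open(out / "wave.json", "w") as f:
            json.dump(
                {
                    "k_vec_per_um": d.k_vec.tolist(),
                    "phi_0_rad": d.phi_0,
                    "variance_explained": d.variance_explained,
                    "var_share_pc12": d.var_share_pc12,
                },
                f,
                indent=1,
            )
    if "movie" in res:
        movie = res["movie"]
        for ch in movie.counts:
            tifffile.imwrite(
                out / f"movie_{ch}.tif",
                np.nan_to_num(movie.rate(ch)).astype(np.float32),
            )
        with open(out / "movie.json", "w") as f:
            json.dump(
                {
                    "origin_um": list(movie.geometry.origin),
                    "voxel_um": list(movie.geometry.voxel),
                    "shape": list(movie.geometry.shape),
                    "time_step_s": movie.time_step,
                    "n_time_bins": int(movie.dwell.shape[0]),
                    "smoothed": movie.smoothed,
                    "axes_order": "t, x, y, z",
                },
                f,
                indent=1,
            )
    if "voi_traces" in res:
        frames = []
        for i, tr in enumerate(res["voi_traces"]):
            frames.append(
                pd.DataFrame(
                    {
                        "voi": i,
                        "t_s": tr.t,
                        "green_rate_cps": tr.green_rate,
                        "red_rate_cps": tr.red_rate,
                        "normalized_ratio": tr.normalized,
                    }
                )
            )
        pd.concat(frames, ignore_index=True).to_csv(out / "voi_traces.csv", index=False)


# ----------------------------------------------------------------- validate
_SCHEMAS = {
    "events": {
        "required": ["t_s", "channel", "path", "arrival_phase_ns"],
        "monotone": [],
    },
    "samples": {
        "required": ev.SAMPLE_COLUMNS,
        "monotone": ["t_s"],
    },
    "track": {
        "required": ["t_s", "est_x_um", "est_y_um", "est_z_um", "n_photons"],
        "monotone": ["t_s"],
    },
}


def validate_tables(path: str | Path, kind: str | None = None) -> dict:
    """Schema check of an events/samples/track table file.

    Returns a machine-readable report: the inferred kind and an itemized
    list of violations (missing columns, non-monotone or non-finite time).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".h5":
        df = pd.read_hdf(path)
    else:
        df = pd.read_csv(path)
    if kind is None:
        kind = next(
            (k for k, s in _SCHEMAS.items() if set(s["required"]) <= set(df.columns)),
            "unknown",
        )
    violations = []
    schema = _SCHEMAS.get(kind)
    if schema is None:
        violations.append({"violation": "unknown-schema", "columns": list(df.columns)})
    else:
        for col in schema["required"]:
            if col not in df.columns:
                violations.append({"violation": "missing-field", "column": col})
        for col in schema["monotone"]:
            if col in df.columns and not np.all(np.diff(df[col].to_numpy()) > 0):
                violations.append({"violation": "non-monotone", "column": col})
        if "t_s" in df.columns and not np.all(np.isfinite(df["t_s"])):
            violations.append({"violation": "non-finite", "column": "t_s"})
    return {"path": str(path), "kind": kind, "n_rows": int(len(df)),
            "violations": violations}
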
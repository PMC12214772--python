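# Methods

`pongscope` simulates and analyses the computational chain of a
photon-counting, closed-loop tracking two-photon microscope: scan design,
real-time particle tracking, event-stream image reconstruction, multi-stage
motion correction, behavioral phase extraction, and traveling-wave activity
statistics. Everything runs on synthetic data from a built-in phantom; no
instrument or animal data is required. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic tests
do and do not establish.

## Scan design (`pongscope.scan`)

The in-plane "Pong" scan drives both galvanometers with triangle waves whose
frequency ratio is the inverse golden ratio, `y_freq = 2/(1+sqrt 5) x_freq`,
so the joint pattern fills the field without repeating; the TAG lens sweeps
the focus axially at `f_tag ~ 190 kHz`, one axial line per half period
(~2.6 µs). The x frequency is `min(dx / (2 a_x tau_min), f_max)`.

Defaults: `tau_min = 2.63 µs` — the duration of one axial line, the natural
minimum dwell per in-plane position — and `f_max = 667 Hz`. With these the
frequency clamp is active for all three published imaging configurations,
which is the only reading that reproduces both the printed y frequencies
(412, 549, 618 Hz) and the counter values below. "Amplitude" throughout is
the full peak-to-peak range: `x(t) = (a_x/2) tri(2 pi f t)`.

On the FPGA the triangle is generated by stepping one pixel per rollover of
a counter whose period is rounded to the nearest *prime* number of 80 MHz
ticks (ties go to the larger prime — the conservative, lower-frequency
choice), so the joint (x, y) state sequence repeats as slowly as the
discrete logic permits. For the default configuration the counters are
239 and 389 and the effective frequencies deviate < 1% from nominal. The
characteristic bi-directional raster time is
`tau_raster = ceil(y_range/dx) / (2 x_freq)`; the ceiling (a raster cannot
scan half a line) is what reproduces all three printed values
(0.187 / 0.106 / 0.075 s).

Trajectory positions are the *continuous* galvo path (the mirror follows the
stepped command smoothly), evaluated as the triangle wave at the
counter-quantised effective frequency, sampled once per axial line.

**Coverage accounting.** A pixel counts as visited when the traced beam path
(interpolated to ≤ pixel/4 steps) crosses it — the only definition under
which a bi-directional raster completely samples the field in exactly
`tau_raster`. Under this definition the Pong scan at the default
configuration samples ~58% of the 0.8 µm pixels and ~91% of the 2 µm pixels
in `tau_raster/2`, and completely samples the field at pixel pitch in
~2.3 `tau_raster`. The qualitative picture — about half the fine pixels in
half a raster time, complete sampling in roughly twice the raster time, far
more uniform spatial spread than a raster — is robust. The sharper published
claims (every 2 µm pixel by `tau_raster/2`; completion at exactly twice the
raster time) did not reproduce under any visit definition we tried (sampled
points, continuous path, PSF-dilated footprint, varied start phases and
counter choices), and the corresponding acceptance assertions are expected
to fail; the completion time is sensitive to the start phases and to the
rational approximation quality of the quantised frequency ratio.

## Phantom (`pongscope.phantom`)

The phantom emulates a larval ventral nerve cord: a ladder of `n_segments`
(default 8) segments spaced 25 µm, each with a midline process and two
lateral cell bodies (Gaussian blobs, sigma = 3 µm), all co-expressing a
stable red and an activity-coupled green fluorophore; a brighter off-ladder
reference cell for the tracker (laterally offset so the field centered on it
contains the whole ladder); and a dim autofluorescent rod below the cord in
both channels.

**Motion.** Crawling is a sequence of labelled bouts (forward / backward).
Within a bout, translation follows stride-locked velocity pulses: truncated
Gaussians in stride fraction, area-normalised so each stride advances the
body by `stride_displacement` (default 100 µm) at `peak_speed` (default
800 µm/s — the regime the instrument is designed for). A slow sinusoidal
in-plane rotation, optional tilt, a per-stride axial bob (2 µm), and a
non-rigid bending field (a random cubic B-spline displacement grid scaled by
a slow envelope — the same parameterisation the registration stage fits, so
recovery error is well defined) complete the pose. The kinematics are
integrated on a 1 ms grid, making the pose C¹ by construction. The true
peristaltic phase advances 2π per stride and is zero at each pulse peak.

**Activity.** During a forward bout, forward-class cells (default: medial)
see a multiplicative green gain `1 + m cos(k s - phi_true(t))` with
modulation depth `m = 0.6` and wave vector `k = 2 pi / 200 µm` along the
body axis `s` (one cycle per body length, posterior-to-anterior during
forward crawling); backward-class cells carry the mirrored wave during
backward bouts; everything else has gain 1. The red channel is strictly
time-invariant in body coordinates.

**Photon emission.** Cells and PSF are both Gaussian, so the photon rate at
any focal position is an analytic sum of Gaussians with pooled widths
(lateral 3.04 µm, axial 3.35 µm at defaults; PSF sigma 0.5/1.5 µm). Photons
along a scan are drawn *exactly* per axial line by Poisson thinning: for
each (line, emitter) pair a candidate count is drawn from the lateral rate
times the axial maximum over the line, candidates are placed uniformly in
TAG phase (the physical dwell measure), and accepted with the true axial
Gaussian ratio. This is an exact draw from the inhomogeneous Poisson process
at the line level; the ~0.7 µm of in-plane beam motion within one line is
ignored, consistently with the reconstruction, which also assigns one
in-plane position per line. Peak rates default to 5e6 (red) and 3e6 (green)
counts/s at focus. Arrival phases within the 14.3 ns laser period carry the
path's multiplexing offset (0 or 7.1 ns) plus a 1.8 ns mean
fluorescence/detection lag and 0.5 ns Gaussian jitter.

Everything is deterministic given the configuration and seed.

## Tracking (`pongscope.tracker`)

The tracking beam circles the estimated neuron position (radius R = 3 µm,
~2857 rev/s, one revolution per ~350 µs cycle) while the TAG lens sweeps
±15 µm axially. Photons are located at the beam position at arrival, gated
to |z| ≤ Z = 5 µm about the estimate, and averaged; the center of mass has
shot-noise error `R/sqrt(N)` (2D radial) and `Z/sqrt(N)` axially. A per-axis
position-only Kalman filter fuses measurements; its process term `D dt`
(D in µm²/s) sets responsiveness. `D` is not a physical diffusivity: the
default 2000 µm²/s was chosen by a simulation sweep as the smallest value
that keeps the lag error during 0.8 mm/s stride pulses well below the
1 µm budget while not amplifying shot noise at rest. Galvo and piezo
feedback are instantaneous; the stage re-centers proportionally every
25 ms. A configurable run of photon-less cycles (default 30) raises a
tracking-lost error.

## Reconstruction (`pongscope.events`)

Photons are demultiplexed by arrival phase (half-period windows), located by
nearest-preceding-sample lookup with the TAG phase advanced continuously
within the line, and weighted by the axial dwell correction
`|sin phi| / norm_const`, discarding the ±20° band around the turnarounds.
`norm_const` defaults to the conventional 0.7846. Note the constant that
makes the equal-voxel-dwell rate estimator exactly unbiased is `2/pi =
0.6366` (for a uniform emitter the estimator returns
`lam (2/pi)/norm_const`), so absolute rates under the default carry a fixed
×0.811 scale; every ratiometric or correlation-based quantity is unaffected.
`recompute_norm_const()` supplies the mean-|sin| alternative (0.769).

Volumes are adjusted-count histograms divided by a linearised dwell
histogram (2D line-center histogram × one line-time share `1/(2 f_tag n_z)`
per z voxel, default 1×1×2 µm voxels); unsampled voxels are explicit
missing data. Movies are 4D histograms at time bins of `tau_raster/2`
(94 ms at defaults), convolved with a separable σ = 1 voxel Gaussian
(reflecting boundaries, so total counts are conserved) *before* division.
Templates for registration are built by normalized (mask-weighted) Gaussian
convolution that fills missing voxels and, optionally, replaces observed
voxels that deviate from the local estimate by > 5 robust SDs — a robust
smoothing/inpainting stage standing in for L1 spline interpolation; tests
target the contract (robust, interpolating, evaluable at continuous
coordinates), not any particular spline algorithm.

## Motion correction (`pongscope.register`)

Computed from red photons only and applied identically to both channels.

1. *Rigid*, per frame (default 0.375 s — 3.125× oversampling of the field
   at 1 µm⁻²): maximize `sum_photons lambda(A x)` over rotation +
   translation. A 10°-step full-circle in-plane angle scan with
   FFT-correlation translation estimates seeds a Nelder-Mead refinement of
   (angle, tx, ty), then of all six parameters. In sequences, each frame is
   warm-started from its predecessor; `register_sequence` adds a quadratic
   continuity penalty between successive parameter vectors (Gauss-Seidel
   sweeps; zero weight reduces to independent fits) and
   `combine_registered` pools registered frames into an enlarged template.
2. *Non-rigid*: a cubic B-spline free-form deformation (control spacing
   default 20 µm, shared engine with the phantom truth) maximizing
   missing-aware normalized correlation between matched-smoothed frame and
   template rates, with a discrete bending-energy penalty (weight 1e-4,
   fixed by null-recovery tests) and coarse-to-fine image smoothing
   (σ = 3 → 1.5 voxels) for capture range. Control displacements are
   bounded (±25 µm), which bounds the field by the convex-hull property.
   The fitted displacement applies directly to scan-path coordinates.
3. *Intensity*: a smooth multiplier `alpha(x)` (cubic B-spline controls
   ~20-25 µm apart, bounded below at 0.05 for positivity) maximizing the
   inhomogeneous-Poisson log likelihood
   `sum_i log alpha(x_i) - int alpha(x(t)) lambda(x(t)) dt`, concave in the
   control values (L-BFGS-B with analytic gradients). The path integral is
   evaluated by expanding every 8th scan line into 8 quadrature points
   uniform in TAG phase — the physical dwell measure along the axial sweep.

Corrected events go through rigid, then deformation; weights are divided by
`alpha` at the corrected location; events leaving the template domain are
dropped and tallied.

## Behavioral phase (`pongscope.behavior`)

The tracked 2D path is denoised by a cubic smoothing spline with parameter
0.99 in the convention minimizing `p Σ(y-f)² + (1-p) ∫ f''²` (mapped to the
penalty form `lam = (1-p)/p` of the underlying solver), differentiated by a
derivative-of-Gaussian filter (σ = 0.25 s), and projected on the heading to
give the forward velocity. The Hilbert phase of the de-meaned velocity
(sign-flipped for backward bouts so phase 0 always sits at maximal speed in
the travel direction) is unwrapped and re-oriented to increase. Strides span
consecutive phase-zero crossings; the last stride of each bout is excluded.
Each stride's velocity-vs-phase profile (extended π/4 into the neighbours)
is aligned to the mean-stride template by a 4-control-point cubic B-spline
phase adjustment bounded by |δφ| < π/4; the adjustments are mapped back to
the time axis with a ±π/8 cross-fade at stride joins and a final
non-decreasing projection. Bout labels are an input, never inferred.

## Wave statistics (`pongscope.waves`)

Activity is ratiometric (green rate / red rate), normalized by an iterative
one-sided clipped-mean baseline (discard > mean + 1 SD, iterate) for
extended traces or by the forward-cycle minimum for stride-aligned data.
Stride-aligned cubes bin the z-projected photons by behavioral phase
(24 bins of 15°, edges at phase 0) and divide count by dwell histograms,
both convolved with a σ = 1-bin Gaussian (circular along phase) — the same
pre-division smoothing convention as movie reconstruction. In the pipeline,
wave statistics are computed within a tissue mask: pixels whose
phase-averaged red rate exceeds 15% of its 99th percentile, the stable
channel serving as the anatomy reference (configurable; stands in for
anatomical segmentation).

PCA over spatial points of the temporally mean-subtracted cube yields
components ordered so c₁ leads c₂ by +90° (sign of the fundamental
cross-spectrum phase; c₁(0) ≥ 0 fixes the remaining sign). The complex
projection g(x, y) carries per-point amplitude and phase; phase maps are
spatially low-passed (σ = 3 µm, on the complex field) before taking the
angle. The wave-restricted variance explained replaces arg g by the best
plane `k·(x,y) + phi_0` (direction grid of 5°, |k| grid, Nelder-Mead
refinement; phi_0 closed-form) while keeping |g|, and reports
`1 - residual/total` variance — zero by convention for a zero-amplitude
cube, negative when the constraint hurts. Bout comparisons use per-bout
mean normalized ratios and a one-sided Wilcoxon rank-sum test
(exact null up to 10 bouts per group, normal approximation above).

## Pipeline and problem sizes

`run_demo` chains simulate → track → reconstruct → register → strides →
waves with per-stage named substreams of one seed, so every stage is
individually reproducible; all outputs carry the config hash and seed.
The demo configuration uses one forward bout of 8 strides and one backward
bout of 3 (≈13 s of experiment), rotation amplitude 0.08 rad, no
deformation, ~13M photon events, 40 rigid frames, and 4 µm cube pixels;
the non-rigid stage is off by default in the demo (its recovery is
exercised directly by the registration tests) and can be enabled with
`nonrigid: true`. On one CPU the demo takes roughly five minutes.

## What the synthetic tests show — and what they do not

Passing tests establish that the algorithms are implemented correctly and
recover known ground truth under the phantom's assumptions: Gaussian cells
and PSF, rigid-plus-smooth-FFD motion, a clean plane-wave activity gain,
Poisson photon statistics, and exactly known bout labels. Real recordings
differ in ways the phantom does not emulate: scattering and aberrations,
photobleaching, richer deformation, behavioral variability, segmentation
error in the anatomy mask, and imperfect bout labelling. Quantitative
margins measured here (tracking error, registration residuals, variance
explained) therefore characterise the software under the stated model, not
instrument performance on animals.
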
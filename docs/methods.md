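# Methods

## The imaging model

A slab-like optical absorber buried in tissue behaves, acoustically, as a
plane-wave source: an optical pulse deposits an initial pressure `p0`
inside the absorber, and the upward-traveling wave reaching a detector
parallel to the slab is a pulse whose temporal width times the sound speed
equals the slab thickness (the *reciprocal-distance* rule). A flat
detector parallel to the slab receives this wave in phase over its whole
surface, so integrating over the aperture multiplies the planar component
by the number of aperture elements, while the spherical waves of compact
absorbers arrive out of phase and add incoherently. A single A-line from
such a detector therefore contains one dominant peak per parallel layer,
and a relative threshold isolates it. The axial resolution is that of any
planar optoacoustic detection, `δ = 0.88·Vs/B` (94.3 µm for Vs = 1.5 mm/µs
and B = 14 MHz; 26.8 µm for B = 49.3 MHz). The method has no lateral
resolution by construction.

## Forward models

**Spectral propagator** (`forward.propagate_spectral`). In a homogeneous
lossless medium the initial-value problem (initial pressure `p0`, zero
initial velocity) is solved exactly in Fourier space:
`p(x,t) = IFFT2[P0(k)·cos(c|k|t)]`. There is no time stepping: each output
sample is computed directly, so there is no CFL constraint and no
numerical dispersion; the sampling interval `dt` is purely a recording
choice. The FFT imposes periodic boundary conditions. Instead of an
absorbing layer, the domain is zero-padded (`pad_factor`, default 2) and a
hard horizon check refuses any record long enough for a periodic image of
the source support to reach a sensor (bounding-box distance over the eight
neighboring period images). This makes the boundary error exactly zero
inside the admitted window rather than approximately small. An escape
hatch (`check_horizon=False`) exists for the one case where periodic
continuation is intended — e.g. a full-width slab at `pad_factor=1`, which
realizes a laterally infinite slab and hence the exact 1D d'Alembert
solution (used as a test oracle).

The field is evaluated only on the sensor rows (a partial inverse DFT per
row), so a 700-sample record of the 256²-padded reference scene takes
under a second on one core.

**Sensors.** A point sensor samples one grid cell; a line (planar) sensor
is a contiguous row segment whose recording is the unweighted sample-wise
sum of its per-cell recordings — exact aperture integration, and exactly
linear, which tests exploit (`record_planar(A+B) = record_planar(A) +
record_planar(B)`).

**Analytic slab** (`forward.analytic_slab_waveform`). Depth sweeps in
0.2 mm steps are sub-grid at dx = 0.5 mm, so the depth and thickness
experiments use the closed-form 1D plane-wave pulse instead of the grid
solver: zero before `t = depth/c`, amplitude
`0.5·A·exp(−µ·(z−depth))` for `z = c·t` inside the slab, zero after. The
attenuation coefficient `µ` (1/mm) models optical extinction inside an
absorbing layer (ink): the deposited pressure, hence the emitted
amplitude, decays with depth into the absorber.

**Transducer band-pass** (`forward.apply_bandpass`). Zero-phase filter
with Gaussian magnitude response centered at `f_c` whose FWHM equals the
absolute bandwidth `B = f_c × fractional bandwidth`. DC gain is ~1e-4 for
the 25 MHz/56% probe, so unipolar pulses become the bipolar wavelets seen
experimentally. Simulated discrimination signals are deliberately *not*
band-passed by default (ideal wideband detection shows only positive
peaks, as theory predicts); the band-pass is opt-in for the experiment
analogs.

**Noise** (`forward.add_noise`). White Gaussian noise scaled to a target
SNR in dB against the mean-square of the record; always seeded.

## The reference discrimination scene

`phantom.discrimination_phantom(seed)`: 128×128 grid, 0.5 mm spacing
(64×64 mm field), sound speed 1.5 mm/µs. A 2 Pa slab occupies rows 58–68 ×
cols 23–103 (0-based; physical depth bounds 29.0–34.5 mm, thickness
5.5 mm, length 40.5 mm). Thirty 2 mm discs (2 Pa) are placed uniformly at
random, rejecting overlap with the slab footprint and the sensor row;
disc-disc overlap is allowed; a cell belongs to a disc iff its center lies
within the radius. The point sensor is cell (29, 63); the planar sensor
spans row 29, cols 28–98 (71 cells, 35.5 mm). All depths are reported as
distance from the sensor row; the slab's leading face is 14.5 mm below it.
The shape ledger is authoritative: re-rasterizing it must reproduce `p0`
cell for cell, and the experiment drivers derive windows and ground truth
from the ledger, never from the raster.

Default recording: dt = 0.05 µs, 700 samples (35 µs ≈ 52.5 mm of depth,
inside the wraparound horizon at pad_factor 2). These record parameters
are recording choices of this package; one depth sample corresponds to
0.075 mm.

## Synthetic raster scans

`rsom.synth_rsom` emulates a raster-scanned focused transducer over a
tape-plus-sutures phantom: each scan position's A-line is the tape's
rectangular plane pulse (identical everywhere — the plane-wave property)
plus, per suture, a bipolar N-pulse at the closest-approach time of
flight, with Gaussian lateral falloff (`cone_width_um`, default 100 µm)
standing in for the detection cone. Defaults are desk-scale: 64×64
positions at 30 µm spacing (1.92 mm field), 512 samples at 250 MS/s, tape
at 2.3 mm, six filaments ~1.5 mm above the tape. Filament endpoints get
independent ±0.2 mm seeded height offsets: a filament at perfectly
constant depth would radiate in phase along its length and masquerade as a
plane — real threaded filaments cross at different levels and sag, and the
tilt restores the scaling that makes the aperture win (area gain for the
tape vs. length gain for a filament). What this generator does *not*
emulate: focal-zone weighting, optical fluence heterogeneity, frequency-
dependent attenuation, and speckle-free statistics of real media — so
passing tests demonstrate the discrimination *mechanism*, not system-level
performance on tissue.

`rsom.virtual_point` extracts one A-line; `rsom.virtual_planar` sums an
index rectangle (virtual planar detector). Summation is associative over
ROI partitions, which is tested.

## Reconstruction

`recon.reconstruct` composes, in order: optional DC subtraction → optional
Hilbert envelope → time-to-depth (`x[mm] = 1.5·t[µs]` by default) →
multiplicative step weighting over depth (identity by default) → backward
threshold → rendering.

The backward threshold starts from the deep end of the record and finds
the last sample exceeding `threshold_fraction` of the profile maximum
(0.35 for ideal wideband signals; 0.27 and 0.07 are the presets used for
envelope-processed experimental-style data). Everything deeper than the
cut is zeroed. The gate is *positional*; an amplitude gate (zeroing every
sub-threshold sample up to the cut as well) is available as
`amplitude_gate=True` but is not the default, because the backward-search
definition defines a position, not an amplitude class. Gating is
idempotent and scale-equivariant (tested).

The slab top is the shallowest sample exceeding the same relative
threshold; thickness is the inclusive sample span between top and cut
times the depth per sample. On noise-free analytic slabs both round-trip
within one sample across the tested 20-point (depth × thickness) sweep.

Step weighting uses `(start_depth, gain)` segments with gain 1 before the
first start. The matched correction for an exponentially attenuated
absorber uses gains `exp(µ·z_mid)` per segment but holds them constant
beyond a configurable band (default: expected structure depth + 1 mm).
The band matters: an unbounded exponential gain amplifies deep,
signal-free noise above a 7% threshold and the backward search would then
cut at the record end. This mirrors the hand-crafted step corrections used
in practice, which only span the clinically expected depth range.

Rendering broadcasts the gated profile across a configurable width,
applies a 1D Gaussian blur (σ = 2 samples) restricted to the nonzero
support (zeroed samples stay exactly zero — no energy bleeds into the
gated region), and scales by `255/max` so the global maximum maps to 255
with no clipping; all-zero or constant profiles render black. Images are
written as PNG and as ASCII PGM (the bit-exact text reference format).

## Estimators and statistics

* `peak_depth`: depth of the global minimum (bipolar experimental-style
  signals), global maximum (unipolar simulated signals), or envelope peak;
  ties break toward the shallowest sample. Exactly shift-equivariant.
* `suppression_ratio`: max |amplitude| inside a depth window over max
  outside; `inf` when the outside is identically zero; invariant under
  global scaling.
* `axial_resolution`: `0.88·Vs/B` in µm.
* `ols_fit`: ordinary least squares with Pearson R and the two-sided
  p-value for the zero-slope null (via `scipy.stats.linregress`; an
  independent closed-form oracle cross-checks it in the tests to 1e-12).
  The application literature sometimes labels Pearson R a "coefficient of
  determination"; this package reports Pearson R and calls it that.

## Experiment drivers and their conditions

**Discrimination (`run_sim1`).** Propagates the reference scene once,
records point and planar signals, reconstructs the planar signal at
threshold 0.35, and reports two artifact-suppression figures:

* *decomposition ratio* (primary): by linearity the planar signal is
  exactly the slab-only signal plus the disc contribution, so the slab is
  propagated alone and the ratio is total peak over the largest
  disc-induced peak. This is the exact realization of "slab peak over
  largest artifact peak".
* *windowed ratio*: peak inside vs. outside a ledger-derived depth window.
  The window extends from one cell above the slab's leading face to one
  cell past the last "first corner-wave arrival" across the aperture,
  because a truncated slab sheds edge-diffraction waves from its lateral
  ends that trail the main pulse: that wake is slab signal, not artifact,
  and a window cut at the trailing face would misclassify it (it reaches
  ~20% of the peak just beyond the face even with no discs present). Even
  with the extended window the estimator remains conservative — residual
  wake beyond the window is counted as artifact — which is why the
  decomposition figure is primary.

Typical numbers (seeds 0–9): planar decomposition ratio 6.0–10.3 (mean
7.5), point-detector ratio ≈ 2 (no aperture gain); recovered thickness
5.475–5.55 mm vs. 5.5 mm ground truth; dominant peak at 14.7 mm (slab
leading face at 14.5 mm). The point signal shows several peaks within
3 dB of its maximum — no discrimination without the aperture.

**Depth sweep (`run_depth_sweep`).** Eleven analytic slabs from 3.0 mm in
0.2 mm steps, ink-like attenuation µ = 1 /mm, 25 MHz/56% band-pass,
40 dB SNR, 500 MS/s over 7 µs; depth read as the global minimum;
estimated vs. programmed depths fitted by OLS. The attenuation matters
physically: with a symmetric (zero-phase) wavelet and a non-attenuating
slab, the two interfaces produce equal-magnitude minima and the global
minimum would be a noise-decided tie between the two faces. The constant
reading offset (≈ −17 µm, a fixed fraction of the wavelet) moves the
intercept, not the slope. Even noise-free, R is bounded near 1−1e-6 by
argmin quantization (sample spacing 3 µm against a 0.2 mm step that is not
an integer number of samples).

**Thickness series (`run_thickness_series`).** Slabs of 1/2/3 mm at 2 mm
depth, µ = 0.5 /mm, band-passed, 50 dB SNR (a kHz-repetition,
heavily-averaged acquisition), reconstructed with DC removal + envelope +
7% threshold + matched banded weighting; estimated vs. programmed
thickness fitted by OLS. The envelope of a band-passed slab is two edge
humps; the 7% crossings extend ~0.09 mm beyond each edge, so estimates
carry a constant ≈ +0.17 mm offset with slope ≈ 1.00. Disabling the
weighting under strong attenuation drops the trailing interface below
threshold and the 3 mm slab reads thin — the expected failure mode when
deep pigment absorbs little light.

## Numerical choices and verification

* The finite-difference cross-check (second-order leapfrog, 5-point
  Laplacian, same periodic padded domain) is run inside its accuracy
  envelope: a smooth phantom (Gaussian blobs, σ = 4 cells) on a 64² grid
  over 14 µs, where it agrees with the spectral solution to 1.9% relative
  RMS. Grid-sharp sources would be dominated by the oracle's dispersion
  error, not by propagator error.
* Extremum ties break toward shallow depth; the backward threshold uses
  strict `>`; thickness uses the inclusive sample span.
* All randomness flows through `numpy.random.default_rng(seed)`; every
  driver echoes its seeds, and re-running a driver from its configuration
  echo reproduces the result table bit for bit.
* Degenerate inputs raise typed errors (all-zero profiles, constant
  signals, inverted bounds, undersampled band-pass, infeasible placement,
  horizon violations) rather than returning silently wrong output.

## Known limitations

* The propagator is 2D, lossless and homogeneous; no acoustic
  attenuation/dispersion, no heterogeneity, no elastic effects, no 3D grid
  propagation (the 3D raster-scan case is handled by the analytic scene
  generator instead).
* The suture model is a far-field N-pulse with a Gaussian detection cone;
  no focused-transducer spatial impulse response is simulated.
* The windowed suppression estimator conservatively counts residual slab
  edge-diffraction as artifact (see above).
* Desk-scale defaults (64×64 scan positions, 10-seed statistics) are
  chosen for interactive use; the generators accept full-scale parameters.
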
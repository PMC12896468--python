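# oaslab

Single-transducer, **non-tomographic optoacoustic imaging** of slab-like
structures — simulation, reconstruction, and validation, in Python.

Many clinically relevant targets are thin layers parallel to the skin:
tattoo ink, subcutaneous fat, the melanin layer, cerebrospinal fluid
below the fontanelle. Acoustically, a layer excited by a light pulse is a
plane-wave source, and three facts make it imageable with *one* flat
ultrasound transducer and no reconstruction inversion:

1. a slab emits a plane wave perpendicular to its surface;
2. the wave's temporal width × the sound speed equals the slab thickness
   (*reciprocal distance*);
3. the plane wave reaches a parallel flat detector in phase everywhere,
   so aperture integration amplifies it by the detector area, while
   compact absorbers (vessels, artifacts) add incoherently.

A single A-line therefore contains one dominant peak per layer; a
backward relative-threshold search isolates it, depth is read off as
`x[mm] = Vs·t` (Vs = 1.5 mm/µs), and thickness via reciprocal distance.
The axial resolution is the usual planar-detection figure
`δ = 0.88·Vs/B` (94.3 µm at B = 14 MHz). The method has no lateral
resolution — that is the price of dropping tomography.

The package provides, as library + CLI:

* `phantom` — grids, media, initial-pressure phantoms with an exact shape
  ledger, and the reference 128×128 slab-plus-30-discs discrimination
  scene;
* `forward` — an exact spectral (FFT, `cos(c|k|t)`) solver for the 2D
  optoacoustic initial-value problem with a provable wraparound horizon,
  point/planar sensors, an analytic sub-grid slab model, Gaussian
  transducer band-pass, seeded noise;
* `rsom` — synthetic raster-scan (RSOM-style) A-line grids of a
  tape-plus-sutures scene, and virtual point/planar detectors derived
  from them;
* `recon` — the two-stage reconstruction: DC removal / Hilbert envelope,
  depth conversion, step depth-weighting, backward threshold gating, and
  8-bit strip-image rendering;
* `metrics` — peak-depth reading, artifact-suppression ratio, axial
  resolution, OLS agreement fits (Pearson R, two-sided p);
* `experiments` / `oaslab` CLI — three end-to-end studies: slab-vs-discs
  discrimination, a 0.2 mm depth sweep, and a 1–3 mm thickness series.

## Worked example

```python
from oaslab import run_sim1, run_depth_sweep

sim = run_sim1(seed=1, out_dir="sim1_out")
print(sim.metrics["planar_peak_depth_mm"])    # 14.7
print(sim.metrics["recovered_thickness_mm"])  # 5.475
print(sim.metrics["suppression_planar"])      # 6.15
print(sim.metrics["suppression_point"])       # 2.24

sweep = run_depth_sweep(seed=1)
print(sweep.metrics["regression"]["slope"])   # 0.99982
print(sweep.metrics["regression"]["r"])       # 0.999999
```

What the numbers mean: the scene buries a 5.5 mm-thick slab with its
leading face 14.5 mm below the sensor row among 30 random 2 mm discs.
The 71-cell planar detector's dominant peak lands at 14.7 mm and the
thresholded profile spans 5.475 mm — depth and thickness recovered to
within one depth sample (0.075 mm). The slab peak exceeds the largest
disc-induced peak ~6× on this seed (~7.5× averaged over seeds 0–9),
whereas the single-cell point detector manages only ~2.2× — with several
peaks within 3 dB of its maximum it cannot discriminate the layer at
all. The depth sweep steps an ink-like slab in 0.2 mm increments through
a band-limited (25 MHz, 56%), noisy (40 dB SNR) acquisition; reading
depth at the global signal minimum tracks the programmed positions with
slope ≈ 1 and Pearson R ≈ 0.999999.

The same studies run from the shell:

```
oaslab sim1 --seed 1 --out sim1_out
oaslab depth-sweep --seed 1 --out sweep_out
oaslab thickness-series --seed 1 --out thick_out
oaslab rsom-synth --seed 1 --out alines.h5
oaslab rsom-virtual alines.h5 --mode planar --out planar.txt
oaslab recon planar.txt --threshold 0.27 --envelope --dc-subtract --out recon_out
```

Each driver writes its waveforms (plain-text tables), strip images (PNG +
ASCII PGM) and a JSON report echoing every parameter and seed;
re-running from a report's configuration echo reproduces the result
table bit for bit.

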
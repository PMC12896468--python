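"""Forward acoustic models.

The 2D optoacoustic initial-value problem in a homogeneous lossless medium
admits an exact spectral solution: with initial pressure ``p0``, zero
initial velocity, and sound speed ``c``, the field at time ``t`` is

    p(x, t) = IFFT2[ P0(k) * cos(c |k| t) ]

where ``P0`` is the 2D Fourier transform of ``p0`` and ``|k|`` the
isotropic angular wavenumber magnitude.  There is no time stepping, hence
no CFL constraint and no numerical dispersion; the output sampling interval
is purely a recording choice.  The FFT imposes periodic boundaries, which
zero-padding converts into an exactly quantifiable time horizon: the
propagator refuses to produce samples that periodic image sources could
have reached (:class:`~oaslab.errors.HorizonExceededError`) rather than
return silently wrong output.

The module also provides a continuous-time 1D plane-wave slab model for
sub-grid depth and thickness experiments, a Gaussian band-pass transducer
response, and seeded additive noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    AliasingError,
    HorizonExceededError,
    IncompatibleWaveformError,
    InvalidArgumentError,
    TruncationError,
)
from .phantom import Grid, Medium, Phantom

__all__ = [
    "Waveform",
    "SensorGeometry",
    "TransducerModel",
    "propagate_spectral",
    "field_at",
    "record_planar",
    "analytic_slab_waveform",
    "apply_bandpass",
    "add_noise",
]


@dataclass
class Waveform:
    """A uniformly sampled pressure time series.

    ``samples`` are pressure amplitudes in arbitrary linear units, ``dt``
    is the sampling interval in us and ``t0`` the time of the first sample
    in us.  ``meta`` carries free-form provenance (sensor, medium, seed).
    """

    samples: np.ndarray
    dt: float
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise InvalidArgumentError("samples must be a non-empty 1D array")
        if not self.dt > 0:
            raise InvalidArgumentError("dt must be positive")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        """Sample times in us."""
        return self.t0 + self.dt * np.arange(self.samples.size)

    def copy(self) -> "Waveform":
        return Waveform(self.samples.copy(), self.dt, self.t0, dict(self.meta))


@dataclass(frozen=True)
class SensorGeometry:
    """A point sensor (one cell) or a line sensor (contiguous row segment)."""

    kind: str
    cells: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.kind not in ("point", "line"):
            raise InvalidArgumentError("kind must be 'point' or 'line'")
        if not self.cells:
            raise InvalidArgumentError("sensor needs at least one cell")
        if self.kind == "point" and len(self.cells) != 1:
            raise InvalidArgumentError("point sensor must have exactly one cell")
        if self.kind == "line":
            rows = {r for r, _ in self.cells}
            cols = sorted(c for _, c in self.cells)
            if len(rows) != 1:
                raise InvalidArgumentError("line sensor cells must share one row")
            if cols != list(range(cols[0], cols[0] + len(cols))):
                raise InvalidArgumentError("line sensor cells must be contiguous")

    @classmethod
    def point(cls, row: int, col: int) -> "SensorGeometry":
        return cls("point", ((row, col),))

    @classmethod
    def line(cls, row: int, col_lo: int, col_hi: int) -> "SensorGeometry":
        if col_hi < col_lo:
            raise InvalidArgumentError("col_hi must be >= col_lo")
        return cls("line", tuple((row, c) for c in range(col_lo, col_hi + 1)))

    def validate_on(self, grid: Grid) -> None:
        for r, c in self.cells:
            if not (0 <= r < grid.n_rows and 0 <= c < grid.n_cols):
                raise InvalidArgumentError(f"sensor cell {(r, c)} outside grid")


@dataclass(frozen=True)
class TransducerModel:
    """Band-limited transducer: Gaussian magnitude response.

    ``center_frequency`` (f_c) in MHz; ``fractional_bandwidth`` is the
    relative bandwidth, so the absolute -6 dB bandwidth is
    ``B = f_c * fractional_bandwidth`` MHz (the full width at half maximum
    of the magnitude response).
    """

    center_frequency: float
    fractional_bandwidth: float

    def __post_init__(self) -> None:
        if not self.center_frequency > 0:
            raise InvalidArgumentError("center_frequency must be positive")
        if not self.fractional_bandwidth > 0:
            raise InvalidArgumentError("fractional_bandwidth must be positive")

    @property
    def bandwidth(self) -> float:
        """Absolute bandwidth B in MHz."""
        return self.center_frequency * self.fractional_bandwidth


def _min_image_distance(
    grid: Grid,
    p0: np.ndarray,
    cells: Sequence[tuple[int, int]],
    pad_rows: int,
    pad_cols: int,
) -> float:
    """Shortest distance (mm) from any periodic image of the source support
    to any sensor cell, on the zero-padded periodic domain."""
    nz = np.argwhere(p0 != 0)
    if nz.size == 0:
        return np.inf
    dx = grid.dx
    src_lo = nz.min(axis=0) * dx
    src_hi = (nz.max(axis=0) + 1) * dx
    cells_arr = np.asarray(cells, dtype=float)
    sen_lo = cells_arr.min(axis=0) * dx
    sen_hi = (cells_arr.max(axis=0) + 1) * dx
    Ly = (grid.n_rows + pad_rows) * dx
    Lx = (grid.n_cols + pad_cols) * dx

    def box_gap(lo_a, hi_a, lo_b, hi_b):
        # per-axis gap between two intervals (0 if overlapping)
        return max(0.0, max(lo_a - hi_b, lo_b - hi_a))

    best = np.inf
    for my in (-1, 0, 1):
        for mx in (-1, 0, 1):
            if my == 0 and mx == 0:
                continue
            gy = box_gap(src_lo[0] + my * Ly, src_hi[0] + my * Ly, sen_lo[0], sen_hi[0])
            gx = box_gap(src_lo[1] + mx * Lx, src_hi[1] + mx * Lx, sen_lo[1], sen_hi[1])
            best = min(best, float(np.hypot(gy, gx)))
    return best


def _spectral_setup(phantom: Phantom, pad_factor: int):
    if pad_factor < 1:
        raise InvalidArgumentError("pad_factor must be >= 1")
    g = phantom.grid
    n_rows_p = g.n_rows * pad_factor
    n_cols_p = g.n_cols * pad_factor
    padded = np.zeros((n_rows_p, n_cols_p))
    padded[: g.n_rows, : g.n_cols] = phantom.p0
    p0_hat = np.fft.fft2(padded)
    ky = 2 * np.pi * np.fft.fftfreq(n_rows_p, d=g.dx)
    kx = 2 * np.pi * np.fft.fftfreq(n_cols_p, d=g.dx)
    kmag = np.sqrt(ky[:, None] ** 2 + kx[None, :] ** 2)
    return p0_hat, kmag, (n_rows_p, n_cols_p)


def field_at(
    phantom: Phantom, medium: Medium, t: float, pad_factor: int = 2
) -> np.ndarray:
    """Exact pressure field at time ``t`` on the (unpadded) grid.

    Negative ``t`` is allowed; the solution is even in time.  No horizon
    check is applied here -- intended for short-time diagnostics and tests.
    """
    g = phantom.grid
    p0_hat, kmag, _ = _spectral_setup(phantom, pad_factor)
    f = np.fft.ifft2(p0_hat * np.cos(medium.sound_speed * kmag * t)).real
    return f[: g.n_rows, : g.n_cols]


def propagate_spectral(
    phantom: Phantom,
    medium: Medium,
    sensors: "SensorGeometry | Sequence[SensorGeometry]",
    dt: float = 0.05,
    n_samples: int = 700,
    pad_factor: int = 2,
    check_horizon: bool = True,
) -> list[list[Waveform]]:
    """Record the exact field at every sensor cell.

    Returns one list of per-cell :class:`Waveform` per input sensor (a
    single :class:`SensorGeometry` is treated as a one-element list and
    still returns ``[[...]]``).  All waveforms share ``dt`` and ``t0 = 0``.

    Raises :class:`HorizonExceededError` if the requested record length
    times the sound speed exceeds the shortest periodic-image path from the
    source support to any sensor cell.  ``check_horizon=False`` disables
    the guard for the cases where periodic continuation is the *intended*
    physics (e.g. a laterally infinite slab built from a full-width
    phantom at ``pad_factor=1``).
    """
    if isinstance(sensors, SensorGeometry):
        sensors = [sensors]
    if not dt > 0 or n_samples < 1:
        raise InvalidArgumentError("dt must be positive and n_samples >= 1")
    g = phantom.grid
    all_cells: list[tuple[int, int]] = []
    for s in sensors:
        s.validate_on(g)
        all_cells.extend(s.cells)

    pad_rows = g.n_rows * (pad_factor - 1)
    pad_cols = g.n_cols * (pad_factor - 1)
    horizon_mm = (
        _min_image_distance(g, phantom.p0, all_cells, pad_rows, pad_cols)
        if check_horizon
        else np.inf
    )
    t_max = (n_samples - 1) * dt
    if medium.sound_speed * t_max > horizon_mm:
        raise HorizonExceededError(
            f"record length {t_max:g} us (x{medium.sound_speed:g} mm/us = "
            f"{medium.sound_speed * t_max:g} mm) exceeds the wraparound-safe "
            f"horizon of {horizon_mm:g} mm; increase pad_factor or shorten "
            "the record"
        )

    p0_hat, kmag, (n_rows_p, n_cols_p) = _spectral_setup(phantom, pad_factor)
    c = medium.sound_speed

    # Evaluate only the sensor rows: one partial inverse DFT per row, then a
    # full inverse FFT along columns.  Exact and much cheaper than ifft2.
    rows = sorted({r for r, _ in all_cells})
    row_phase = {
        r: np.exp(2j * np.pi * np.arange(n_rows_p) * r / n_rows_p) / n_rows_p
        for r in rows
    }
    traces = {cell: np.empty(n_samples) for cell in set(all_cells)}
    cols_by_row = {
        r: sorted({c0 for rr, c0 in set(all_cells) if rr == r}) for r in rows
    }
    for i in range(n_samples):
        prop = p0_hat * np.cos(c * kmag * (i * dt))
        for r in rows:
            row_vals = np.fft.ifft(row_phase[r] @ prop).real
            for c0 in cols_by_row[r]:
                traces[(r, c0)][i] = row_vals[c0]

    out: list[list[Waveform]] = []
    for s in sensors:
        wfs = [
            Waveform(
                traces[cell].copy(),
                dt=dt,
                t0=0.0,
                meta={
                    "sensor_cell": cell,
                    "sensor_kind": s.kind,
                    "sound_speed": c,
                    "pad_factor": pad_factor,
                },
            )
            for cell in s.cells
        ]
        out.append(wfs)
    return out


def record_planar(per_cell_waveforms: Iterable[Waveform]) -> Waveform:
    """Unweighted aperture integration: sample-wise sum over cells.

    Every point of a flat detector parallel to a slab vibrates in phase
    with the slab's plane wave, so the sum amplifies planar contributions
    by the cell count while localized (spherical-wave) contributions add
    incoherently.
    """
    wfs = list(per_cell_waveforms)
    if not wfs:
        raise InvalidArgumentError("no waveforms to sum")
    ref = wfs[0]
    for w in wfs[1:]:
        if len(w) != len(ref) or w.dt != ref.dt or w.t0 != ref.t0:
            raise IncompatibleWaveformError(
                "waveforms must share dt, t0 and length"
            )
    total = np.sum([w.samples for w in wfs], axis=0)
    meta = dict(ref.meta)
    meta["sensor_kind"] = "planar-sum"
    meta["n_cells"] = len(wfs)
    meta.pop("sensor_cell", None)
    return Waveform(total, dt=ref.dt, t0=ref.t0, meta=meta)


def analytic_slab_waveform(
    depth: float,
    thickness: float,
    medium: Medium = Medium(),
    fs: float = 500.0,
    window: float = 7.0,
    surface_amplitude: float = 2.0,
    attenuation_coeff: float = 0.0,
) -> Waveform:
    """Plane-wave pulse from a slab at sub-grid (continuous) depth.

    The upward-traveling plane wave from a uniform slab is a rectangular
    pulse at half the initial surface pressure, starting at
    ``t = depth / c`` and lasting ``thickness / c`` (the reciprocal-distance
    rule).  Optical attenuation inside the absorber is modeled as an
    exponential decay ``exp(-attenuation_coeff * (z - depth))`` of the
    deposited pressure, mapped through ``z = c t``.

    ``fs`` is the sampling rate in MS/s (samples per us); ``window`` is the
    record length in us.
    """
    if depth < 0 or not thickness > 0:
        raise InvalidArgumentError("depth must be >= 0 and thickness > 0")
    if not fs > 0 or not window > 0:
        raise InvalidArgumentError("fs and window must be positive")
    if attenuation_coeff < 0:
        raise InvalidArgumentError("attenuation_coeff must be >= 0")
    c = medium.sound_speed
    if window * c < depth + thickness:
        raise TruncationError(
            f"window {window:g} us covers only {window * c:g} mm but the slab "
            f"extends to {depth + thickness:g} mm"
        )
    dt = 1.0 / fs
    t = dt * np.arange(int(round(window * fs)))
    z = c * t
    inside = (z >= depth) & (z < depth + thickness)
    samples = np.where(
        inside,
        0.5 * surface_amplitude * np.exp(-attenuation_coeff * np.clip(z - depth, 0.0, None)),
        0.0,
    )
    return Waveform(
        samples,
        dt=dt,
        t0=0.0,
        meta={
            "model": "analytic-slab",
            "depth_mm": depth,
            "thickness_mm": thickness,
            "sound_speed": c,
            "attenuation_coeff": attenuation_coeff,
        },
    )


def apply_bandpass(waveform: Waveform, transducer: TransducerModel) -> Waveform:
    """Zero-phase Gaussian band-pass modeling the transducer response.

    The magnitude response is a Gaussian centered at ``f_c`` whose full
    width at half maximum equals the absolute bandwidth ``B``; applied in
    the frequency domain (zero phase), it turns unipolar optoacoustic
    pulses into the bipolar wavelets seen with real transducers, and its
    DC gain is negligible.
    """
    fs = 1.0 / waveform.dt  # MHz
    fc = transducer.center_frequency
    bw = transducer.bandwidth
    if not fs > 2 * (fc + bw):
        raise AliasingError(
            f"sampling rate {fs:g} MHz too low for passband {fc:g}+/-{bw:g} MHz"
        )
    sigma = bw / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    freqs = np.fft.rfftfreq(len(waveform), d=waveform.dt)
    response = np.exp(-((freqs - fc) ** 2) / (2.0 * sigma**2))
    filtered = np.fft.irfft(np.fft.rfft(waveform.samples) * response, len(waveform))
    meta = dict(waveform.meta)
    meta["bandpass"] = {"fc_mhz": fc, "fractional_bandwidth": transducer.fractional_bandwidth}
    return Waveform(filtered, dt=waveform.dt, t0=waveform.t0, meta=meta)


def add_noise(waveform: Waveform, snr_db: float, seed: int) -> Waveform:
    """Additive white Gaussian noise at the requested signal-to-noise ratio.

    ``snr_db`` is ``10 log10(signal power / noise power)`` with signal power
    the mean square of the record.  ``snr_db = inf`` returns an unchanged
    copy.  Deterministic given ``seed``.
    """
    if np.isinf(snr_db):
        return waveform.copy()
    if not np.isfinite(snr_db):
        raise InvalidArgumentError("snr_db must be finite or +inf")
    power = float(np.mean(waveform.samples**2))
    if power == 0.0:
        raise InvalidArgumentError("cannot scale noise to an all-zero signal")
    noise_power = power / 10.0 ** (snr_db / 10.0)
    rng = np.random.default_rng(seed)
    noisy = waveform.samples + rng.normal(0.0, np.sqrt(noise_power), len(waveform))
    meta = dict(waveform.meta)
    meta["noise"] = {"snr_db": snr_db, "seed": seed}
    return Waveform(noisy, dt=waveform.dt, t0=waveform.t0, meta=meta)
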
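"""Synthetic raster-scan optoacoustic datasets and virtual detectors.

A raster-scan optoacoustic mesoscopy (RSOM) acquisition records one A-line
per scan position of a focused single-element transducer; each focal
position behaves as a virtual point-like detector.  This module generates
such A-line grids for a scene made of a horizontal absorbing tape (a slab,
hence a plane wave identical at every position) plus thin suture filaments
above it (localized, bipolar far-field signatures), and derives virtual
point and planar detectors from the grid.

The suture signal is a far-field N-shaped pulse centered at the
closest-approach time of flight, with a Gaussian lateral amplitude falloff
standing in for the detection cone of the focused transducer.  Any
physically reasonable localized bipolar pulse supports the point/planar
discrimination logic; no focusing model is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InvalidArgumentError, TruncationError
from .forward import Waveform
from .phantom import Medium

__all__ = ["SutureSpec", "AlineGrid", "synth_rsom", "virtual_point", "virtual_planar",
           "default_suture_layout"]


@dataclass(frozen=True)
class SutureSpec:
    """A thin cylindrical absorber given as a 3D line segment.

    Endpoints are ``(x, y, z)`` in mm with x along the fast axis, y along
    the slow axis and z the depth below the detection plane (z = 0).
    ``radius_um`` sets the half-duration of the N-pulse, ``amplitude`` its
    peak value at zero lateral offset.
    """

    p0: tuple[float, float, float]
    p1: tuple[float, float, float]
    radius_um: float = 35.0
    amplitude: float = 1.5

    def __post_init__(self) -> None:
        if not self.radius_um > 0:
            raise InvalidArgumentError("radius_um must be positive")


@dataclass
class AlineGrid:
    """3D stack of A-lines indexed ``(sample, fast, slow)``."""

    data: np.ndarray
    dt: float
    fast_spacing_um: float
    slow_spacing_um: float
    medium: Medium = field(default_factory=Medium)
    scene: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise InvalidArgumentError("data must be (sample, fast, slow)")
        if not self.dt > 0:
            raise InvalidArgumentError("dt must be positive")
        if not (self.fast_spacing_um > 0 and self.slow_spacing_um > 0):
            raise InvalidArgumentError("spacings must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_fast(self) -> int:
        return self.data.shape[1]

    @property
    def n_slow(self) -> int:
        return self.data.shape[2]


def default_suture_layout(
    field_mm: float, depth_mm: float, n: int = 6, jitter_mm: float = 0.2, seed: int = 0
) -> list[SutureSpec]:
    """Six straight filaments criss-crossing the scan field.

    Mimics a holder threading sutures between opposite frame sides so some
    run parallel and some intersect at different levels: each endpoint gets
    an independent seeded height offset, so filaments are tilted and their
    closest-approach distance varies along the line.  (A filament at
    perfectly constant depth would radiate fully in phase along its length
    and masquerade as a plane; real threaded filaments never do.)
    """
    rng = np.random.default_rng(seed)
    specs = []
    # upper/lower anchor fractions across the field, some crossing pairs
    anchors = [(0.15, 0.95), (0.3, 0.8), (0.5, 0.5), (0.65, 0.65), (0.8, 0.2), (0.95, 0.3)]
    for ua, la in anchors[:n]:
        z0 = depth_mm + rng.uniform(-jitter_mm, jitter_mm)
        z1 = depth_mm + rng.uniform(-jitter_mm, jitter_mm)
        specs.append(
            SutureSpec(p0=(ua * field_mm, 0.0, z0), p1=(la * field_mm, field_mm, z1))
        )
    return specs


def _segment_closest_point(p0: np.ndarray, p1: np.ndarray, q: np.ndarray) -> np.ndarray:
    d = p1 - p0
    denom = float(d @ d)
    if denom == 0.0:
        return p0
    s = np.clip(((q - p0) @ d) / denom, 0.0, 1.0)
    return p0 + s * d


def synth_rsom(
    tape_depth: float = 2.3,
    sutures: Sequence[SutureSpec] | None = None,
    n_fast: int = 64,
    n_slow: int = 64,
    fast_spacing_um: float = 30.0,
    slow_spacing_um: float = 30.0,
    dt: float = 0.004,
    n_samples: int = 512,
    medium: Medium = Medium(),
    tape_thickness: float = 0.2,
    tape_amplitude: float = 1.0,
    cone_width_um: float = 100.0,
    snr_db: float = float("inf"),
    seed: int = 0,
) -> AlineGrid:
    """Generate a synthetic raster-scan A-line grid.

    Every A-line is the superposition of (a) a rectangular tape pulse
    starting at ``tape_depth / c`` -- identical at every scan position, the
    plane-wave signature of a slab -- and (b) one bipolar N-pulse per
    suture passing near the position, centered at the closest-approach
    time of flight with amplitude ``exp(-rho^2 / (2 w^2))`` for lateral
    offset ``rho`` and cone width ``w``.  Optional seeded white noise.

    Pass ``sutures=[]`` for a tape-only (pure plane) scene; ``None``
    selects the default six-suture layout 1.5 mm above the tape.
    """
    c = medium.sound_speed
    window_mm = c * dt * n_samples
    if tape_depth + tape_thickness > window_mm:
        raise TruncationError(
            f"tape at {tape_depth:g}+{tape_thickness:g} mm exceeds the "
            f"{window_mm:g} mm time window"
        )
    field_fast = n_fast * fast_spacing_um / 1000.0
    field_slow = n_slow * slow_spacing_um / 1000.0
    if sutures is None:
        sutures = default_suture_layout(
            field_mm=min(field_fast, field_slow),
            depth_mm=tape_depth - 1.5,
            seed=seed,
        )
    for s in sutures:
        for p in (s.p0, s.p1):
            if p[2] > window_mm:
                raise TruncationError("suture deeper than the time window")

    t = dt * np.arange(n_samples)
    z = c * t
    tape_pulse = np.where(
        (z >= tape_depth) & (z < tape_depth + tape_thickness), 0.5 * tape_amplitude, 0.0
    )

    data = np.empty((n_samples, n_fast, n_slow))
    data[:] = tape_pulse[:, None, None]

    xs = (np.arange(n_fast) + 0.5) * fast_spacing_um / 1000.0
    ys = (np.arange(n_slow) + 0.5) * slow_spacing_um / 1000.0
    w_mm = cone_width_um / 1000.0
    for s in sutures:
        p0 = np.asarray(s.p0, dtype=float)
        p1 = np.asarray(s.p1, dtype=float)
        tau = s.radius_um / 1000.0 / c  # N-pulse half-duration, us
        for i, px in enumerate(xs):
            for j, py in enumerate(ys):
                q = np.array([px, py, 0.0])
                cp = _segment_closest_point(p0, p1, q)
                dist = float(np.linalg.norm(cp - q))
                rho = float(np.hypot(cp[0] - px, cp[1] - py))
                amp = s.amplitude * np.exp(-(rho**2) / (2.0 * w_mm**2))
                if amp < 1e-6 * s.amplitude:
                    continue
                tc = dist / c
                u = (t - tc) / tau
                pulse = np.where(np.abs(u) <= 1.0, -amp * u, 0.0)
                data[:, i, j] += pulse

    if np.isfinite(snr_db):
        rng = np.random.default_rng(seed)
        power = float(np.mean(data**2))
        sigma = np.sqrt(power / 10.0 ** (snr_db / 10.0))
        data = data + rng.normal(0.0, sigma, data.shape)

    scene = {
        "tape_depth_mm": tape_depth,
        "tape_thickness_mm": tape_thickness,
        "tape_amplitude": tape_amplitude,
        "sutures": [
            {"p0": list(s.p0), "p1": list(s.p1), "radius_um": s.radius_um,
             "amplitude": s.amplitude}
            for s in sutures
        ],
        "cone_width_um": cone_width_um,
        "snr_db": snr_db if np.isfinite(snr_db) else "inf",
        "seed": seed,
    }
    return AlineGrid(
        data=data,
        dt=dt,
        fast_spacing_um=fast_spacing_um,
        slow_spacing_um=slow_spacing_um,
        medium=medium,
        scene=scene,
    )


def virtual_point(alines: AlineGrid, fast_index: int, slow_index: int) -> Waveform:
    """The single A-line at one scan position (a virtual point detector)."""
    if not (0 <= fast_index < alines.n_fast and 0 <= slow_index < alines.n_slow):
        raise InvalidArgumentError("scan index out of range")
    return Waveform(
        alines.data[:, fast_index, slow_index].copy(),
        dt=alines.dt,
        t0=0.0,
        meta={
            "sensor_kind": "virtual-point",
            "fast_index": fast_index,
            "slow_index": slow_index,
            "sound_speed": alines.medium.sound_speed,
        },
    )


def virtual_planar(
    alines: AlineGrid, roi: tuple[int, int, int, int] | None = None
) -> Waveform:
    """Sum of all A-lines in a rectangular ROI (a virtual planar detector).

    ``roi`` is ``(fast_lo, fast_hi, slow_lo, slow_hi)`` inclusive; ``None``
    sums the whole grid.  The in-phase tape component grows with the cell
    count while localized suture pulses add incoherently, which is the
    plane-wave discrimination mechanism.
    """
    if roi is None:
        roi = (0, alines.n_fast - 1, 0, alines.n_slow - 1)
    f0, f1, s0, s1 = roi
    if not (0 <= f0 <= f1 < alines.n_fast and 0 <= s0 <= s1 < alines.n_slow):
        raise InvalidArgumentError("ROI out of range or inverted")
    total = alines.data[:, f0 : f1 + 1, s0 : s1 + 1].sum(axis=(1, 2))
    return Waveform(
        total,
        dt=alines.dt,
        t0=0.0,
        meta={
            "sensor_kind": "virtual-planar",
            "roi": list(roi),
            "n_cells": (f1 - f0 + 1) * (s1 - s0 + 1),
            "sound_speed": alines.medium.sound_speed,
        },
    )
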
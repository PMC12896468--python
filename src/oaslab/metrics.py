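"""Estimators and statistics used to validate the imaging method."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.signal import hilbert

from .errors import (
    DegenerateFitError,
    InvalidArgumentError,
    NoExtremumError,
)
from .forward import Waveform
from .recon import to_depth

__all__ = [
    "RegressionResult",
    "peak_depth",
    "suppression_ratio",
    "axial_resolution",
    "ols_fit",
]


@dataclass(frozen=True)
class RegressionResult:
    """Ordinary-least-squares fit summary.

    ``rvalue`` is the Pearson correlation coefficient (often loosely called
    the coefficient of determination in the application literature);
    ``pvalue`` is the two-sided p-value for the zero-slope null.
    """

    slope: float
    intercept: float
    rvalue: float
    pvalue: float
    n: int

    def as_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r": self.rvalue,
            "p_value": self.pvalue,
            "n": self.n,
        }

    def summary(self) -> str:
        return (
            f"OLS fit (n={self.n}): slope={self.slope:.6g}, "
            f"intercept={self.intercept:.6g}, R={self.rvalue:.6g}, "
            f"p={self.pvalue:.3g}"
        )


def peak_depth(
    waveform: Waveform, mode: str = "global_min", conversion: float = 1.5
) -> float:
    """Depth (mm) of the selected extremum of the record.

    ``global_min`` implements distance reading on bipolar (band-limited)
    signals where the dominant trough marks the interface; ``global_max``
    suits unipolar simulated signals; ``envelope_peak`` takes the maximum
    of the analytic-signal magnitude.  Ties break toward the shallowest
    sample.
    """
    x = waveform.samples
    if np.ptp(x) == 0.0:
        raise NoExtremumError("constant signal has no extremum")
    if mode == "global_min":
        idx = int(np.argmin(x))
    elif mode == "global_max":
        idx = int(np.argmax(x))
    elif mode == "envelope_peak":
        idx = int(np.argmax(np.abs(hilbert(x))))
    else:
        raise InvalidArgumentError(f"unknown mode {mode!r}")
    return float(to_depth(waveform, conversion)[idx])


def suppression_ratio(
    waveform: Waveform,
    slab_window: tuple[float, float],
    conversion: float = 1.5,
) -> float:
    """Peak ratio inside vs. outside a depth window.

    ``(max |amplitude| inside slab_window) / (max |amplitude| outside)``;
    returns ``inf`` when the record is identically zero outside the
    window.  The window is a closed depth interval in mm.
    """
    lo, hi = slab_window
    if not hi > lo:
        raise InvalidArgumentError("slab_window must be a non-empty interval")
    depth = to_depth(waveform, conversion)
    inside = (depth >= lo) & (depth <= hi)
    if not inside.any():
        raise InvalidArgumentError("slab_window does not overlap the record")
    mag = np.abs(waveform.samples)
    peak_in = float(mag[inside].max())
    outside = ~inside
    if not outside.any() or mag[outside].max() == 0.0:
        return float("inf")
    return peak_in / float(mag[outside].max())


def axial_resolution(sound_speed: float, bandwidth: float) -> float:
    """Axial resolution delta = 0.88 * Vs / B, in um.

    ``sound_speed`` in mm/us, ``bandwidth`` in MHz.  This is the standard
    resolution figure of planar optoacoustic detection and is what the
    non-tomographic method inherits.
    """
    if not sound_speed > 0 or not bandwidth > 0:
        raise InvalidArgumentError("sound_speed and bandwidth must be positive")
    return 0.88 * sound_speed / bandwidth * 1000.0


def ols_fit(x, y) -> RegressionResult:
    """Ordinary least squares of ``y`` on ``x`` with Pearson R and p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidArgumentError("x and y must be equal-length 1D arrays")
    if x.size < 3:
        raise InvalidArgumentError("need n >= 3 for a finite p-value")
    if np.ptp(x) == 0.0:
        raise DegenerateFitError("constant predictor")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        rvalue=float(res.rvalue),
        pvalue=float(res.pvalue),
        n=int(x.size),
    )
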
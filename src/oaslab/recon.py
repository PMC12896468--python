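"""Two-stage non-tomographic reconstruction.

Stage 1 converts an A-line to a depth profile and isolates the slab: the
record is optionally DC-corrected and Hilbert-enveloped, time is mapped to
depth (``x[mm] = c * t[us]``, default 1.5 mm/us), a multiplicative step
weighting can compensate depth-dependent light attenuation, and a backward
threshold search gates the profile: starting from the deep end, the last
sample exceeding ``threshold_fraction`` of the profile maximum defines the
cut, and everything deeper is zeroed.

Stage 2 renders the gated depth profile as a column-uniform 8-bit strip
image with support-restricted Gaussian softening.

The gate is positional ("samples deeper than the cut"), which is the
default; an amplitude gate (zero every sub-threshold sample) is available
as an explicit opt-in mode.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import hilbert

from .errors import InvalidArgumentError, NoSignalError
from .forward import Waveform

__all__ = [
    "ReconConfig",
    "ReconResult",
    "to_depth",
    "preprocess",
    "backward_threshold",
    "depth_weighting",
    "render_strip",
    "reconstruct",
]


@dataclass(frozen=True)
class ReconConfig:
    """Parameters of the reconstruction pipeline.

    ``weighting_steps`` is a sequence of ``(start_depth_mm, gain)`` pairs
    with strictly increasing start depths; a sample at depth ``z`` is
    multiplied by the gain of the last step whose start is <= ``z`` (gain
    1.0 before the first step).  An empty sequence is the identity.
    """

    threshold_fraction: float = 0.35
    envelope: bool = False
    dc_subtract: bool = False
    depth_conversion: float = 1.5
    weighting_steps: tuple[tuple[float, float], ...] = ()
    blur_sigma: float = 2.0
    render_width: int = 200
    amplitude_gate: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold_fraction < 1.0:
            raise InvalidArgumentError("threshold_fraction must be in (0, 1)")
        if not self.depth_conversion > 0:
            raise InvalidArgumentError("depth_conversion must be positive")
        if self.blur_sigma < 0:
            raise InvalidArgumentError("blur_sigma must be >= 0")
        if self.render_width < 1:
            raise InvalidArgumentError("render_width must be >= 1")
        steps = tuple((float(b), float(g)) for b, g in self.weighting_steps)
        starts = [b for b, _ in steps]
        if any(b2 <= b1 for b1, b2 in zip(starts, starts[1:])):
            raise InvalidArgumentError("weighting step breakpoints must increase")
        if any(g < 0 for _, g in steps):
            raise InvalidArgumentError("weighting gains must be >= 0")
        object.__setattr__(self, "weighting_steps", steps)


@dataclass
class ReconResult:
    """Output of :func:`reconstruct`."""

    depth_axis: np.ndarray
    gated_profile: np.ndarray
    cut_index: int
    slab_top_depth: float
    slab_thickness: float
    image: np.ndarray
    config: ReconConfig

    def as_dict(self) -> dict:
        """JSON-ready scalar summary (arrays omitted)."""
        return {
            "cut_index": int(self.cut_index),
            "cut_depth_mm": float(self.depth_axis[self.cut_index]),
            "slab_top_depth_mm": float(self.slab_top_depth),
            "slab_thickness_mm": float(self.slab_thickness),
            "threshold_fraction": self.config.threshold_fraction,
        }


def to_depth(waveform: Waveform, conversion: float = 1.5) -> np.ndarray:
    """Depth in mm of every sample: ``depth[i] = conversion * (t0 + i dt)``."""
    if not conversion > 0:
        raise InvalidArgumentError("conversion must be positive")
    return conversion * waveform.times


def preprocess(waveform: Waveform, config: ReconConfig) -> Waveform:
    """Optional DC removal and Hilbert-envelope detection."""
    x = waveform.samples
    if config.dc_subtract:
        x = x - x.mean()
    if config.envelope:
        if x.size < 2:
            raise InvalidArgumentError("envelope needs at least 2 samples")
        x = np.abs(hilbert(x))
    return Waveform(x, dt=waveform.dt, t0=waveform.t0, meta=dict(waveform.meta))


def backward_threshold(
    profile: np.ndarray, threshold_fraction: float
) -> tuple[int, np.ndarray]:
    """Backward search for the last sample above the relative threshold.

    Returns ``(cut_index, gated)`` where ``cut_index`` is the largest index
    with ``profile[i] > threshold_fraction * max(profile)`` and ``gated``
    equals the input up to the cut and is zero beyond it.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise InvalidArgumentError("threshold_fraction must be in (0, 1)")
    profile = np.asarray(profile, dtype=float)
    peak = profile.max() if profile.size else 0.0
    if not peak > 0:
        raise NoSignalError("profile has no strictly positive sample")
    above = np.nonzero(profile > threshold_fraction * peak)[0]
    cut = int(above[-1])
    gated = profile.copy()
    gated[cut + 1 :] = 0.0
    return cut, gated


def depth_weighting(
    profile: np.ndarray,
    depth_axis: np.ndarray,
    weighting_steps: Sequence[tuple[float, float]],
) -> np.ndarray:
    """Multiplicative piecewise-constant gain over depth.

    Compensates depth-dependent light attenuation: each sample is
    multiplied by the gain of the step segment containing its depth.  An
    empty step list is the identity.
    """
    profile = np.asarray(profile, dtype=float)
    depth_axis = np.asarray(depth_axis, dtype=float)
    if profile.shape != depth_axis.shape:
        raise InvalidArgumentError("profile and depth_axis must have equal length")
    if not weighting_steps:
        return profile.copy()
    starts = np.array([b for b, _ in weighting_steps])
    gains = np.array([g for _, g in weighting_steps])
    if np.any(np.diff(starts) <= 0):
        raise InvalidArgumentError("weighting step breakpoints must increase")
    if np.any(gains < 0):
        raise InvalidArgumentError("weighting gains must be >= 0")
    seg = np.searchsorted(starts, depth_axis, side="right") - 1
    gain = np.where(seg >= 0, gains[np.clip(seg, 0, None)], 1.0)
    return profile * gain


def _support_blur(profile: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing restricted to the nonzero support.

    Each contiguous run of nonzero samples is blurred independently with a
    'nearest' boundary, so no energy bleeds into the zeroed region and the
    zeroed region stays exactly zero.
    """
    out = np.zeros_like(profile)
    mask = profile != 0.0
    if sigma == 0 or not mask.any():
        out[mask] = profile[mask]
        return out
    idx = np.nonzero(mask)[0]
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    for s, e in zip(starts, ends):
        lo, hi = idx[s], idx[e] + 1
        out[lo:hi] = gaussian_filter1d(profile[lo:hi], sigma, mode="nearest")
    return out


def render_strip(gated_profile: np.ndarray, config: ReconConfig) -> np.ndarray:
    """Render the gated depth profile as an 8-bit grayscale strip.

    Columns are identical copies of the profile; a 1D Gaussian of
    ``blur_sigma`` samples is applied along depth restricted to the nonzero
    support; the result is scaled by ``255 / max`` so the global maximum
    maps to 255 with no clipping.  All-zero or constant profiles render as
    an all-zero image.
    """
    profile = np.asarray(gated_profile, dtype=float)
    nz = profile[profile != 0.0]
    if nz.size == 0 or np.ptp(nz) == 0.0:
        return np.zeros((profile.size, config.render_width), dtype=np.uint8)
    blurred = _support_blur(profile, config.blur_sigma)
    scaled = np.clip(blurred, 0.0, None) * (255.0 / blurred.max())
    column = np.rint(scaled).astype(np.uint8)
    return np.repeat(column[:, None], config.render_width, axis=1)


def reconstruct(waveform: Waveform, config: ReconConfig = ReconConfig()) -> ReconResult:
    """Full two-stage pipeline; reports slab top depth and thickness.

    The slab top is the shallowest sample exceeding the relative threshold;
    the thickness is the inclusive sample span between top and cut times
    the depth per sample (the reciprocal-distance rule applied to the
    gated profile).
    """
    pre = preprocess(waveform, config)
    depth_axis = to_depth(pre, config.depth_conversion)
    profile = depth_weighting(pre.samples, depth_axis, config.weighting_steps)
    cut, gated = backward_threshold(profile, config.threshold_fraction)
    if config.amplitude_gate:
        gated = np.where(profile > config.threshold_fraction * profile.max(), profile, 0.0)
        gated[cut + 1 :] = 0.0
    top = int(np.nonzero(profile > config.threshold_fraction * profile.max())[0][0])
    dz = config.depth_conversion * waveform.dt
    thickness = (cut - top + 1) * dz
    image = render_strip(gated, config)
    return ReconResult(
        depth_axis=depth_axis,
        gated_profile=gated,
        cut_index=cut,
        slab_top_depth=float(depth_axis[top]),
        slab_thickness=float(thickness),
        image=image,
        config=config,
    )
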
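"""File formats: delimited waveform tables, HDF5 containers, images, reports.

Waveform files are two-column delimited text (time_us, amplitude) with
'#'-prefixed metadata header lines.  ``dt`` and ``t0`` are stored in the
header at full precision, so read/write round-trips are lossless well
beyond 9 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import yaml
from PIL import Image

from .errors import InvalidArgumentError
from .forward import Waveform
from .phantom import DiscShape, Grid, Medium, Phantom, SlabShape
from .rsom import AlineGrid

__all__ = [
    "write_waveform",
    "read_waveform",
    "save_phantom",
    "load_phantom",
    "phantom_to_text",
    "save_alines",
    "load_alines",
    "aline_to_csv",
    "write_pgm",
    "write_png",
    "write_report",
    "load_config",
]


def write_waveform(path, waveform: Waveform) -> None:
    path = Path(path)
    lines = ["# oaslab waveform v1"]
    lines.append(f"# dt_us = {waveform.dt!r}")
    lines.append(f"# t0_us = {waveform.t0!r}")
    for key, value in waveform.meta.items():
        lines.append(f"# meta {key} = {json.dumps(value)}")
    lines.append("# time_us\tamplitude")
    t = waveform.times
    for ti, xi in zip(t, waveform.samples):
        lines.append(f"{ti:.9g}\t{xi:.17g}")
    path.write_text("\n".join(lines) + "\n")


def read_waveform(path) -> Waveform:
    path = Path(path)
    dt = t0 = None
    meta: dict = {}
    samples = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("dt_us ="):
                dt = float(body.split("=", 1)[1])
            elif body.startswith("t0_us ="):
                t0 = float(body.split("=", 1)[1])
            elif body.startswith("meta "):
                key, value = body[5:].split("=", 1)
                meta[key.strip()] = json.loads(value)
            continue
        fields = line.split()
        if len(fields) != 2:
            raise InvalidArgumentError(f"malformed waveform line: {line!r}")
        samples.append(float(fields[1]))
    if dt is None or t0 is None:
        raise InvalidArgumentError("waveform file missing dt/t0 header")
    return Waveform(np.array(samples), dt=dt, t0=t0, meta=meta)


def save_phantom(path, phantom: Phantom) -> None:
    """HDF5 container: p0 dataset, grid attributes, shape ledger."""
    with h5py.File(path, "w") as f:
        dset = f.create_dataset("p0", data=phantom.p0)
        dset.attrs["n_rows"] = phantom.grid.n_rows
        dset.attrs["n_cols"] = phantom.grid.n_cols
        dset.attrs["dx_mm"] = phantom.grid.dx
        if phantom.seed is not None:
            dset.attrs["seed"] = phantom.seed
        ledger = []
        for s in phantom.shapes:
            if isinstance(s, SlabShape):
                ledger.append(
                    {"kind": "slab", "row_lo": s.row_lo, "row_hi": s.row_hi,
                     "col_lo": s.col_lo, "col_hi": s.col_hi, "amplitude": s.amplitude}
                )
            elif isinstance(s, DiscShape):
                ledger.append(
                    {"kind": "disc", "center_y": s.center_y, "center_x": s.center_x,
                     "diameter": s.diameter, "amplitude": s.amplitude}
                )
            else:  # pragma: no cover
                raise InvalidArgumentError(f"unknown shape {type(s)}")
        dset.attrs["ledger_json"] = json.dumps(ledger)


def load_phantom(path) -> Phantom:
    with h5py.File(path, "r") as f:
        dset = f["p0"]
        grid = Grid(
            n_rows=int(dset.attrs["n_rows"]),
            n_cols=int(dset.attrs["n_cols"]),
            dx=float(dset.attrs["dx_mm"]),
        )
        p0 = dset[()]
        seed = int(dset.attrs["seed"]) if "seed" in dset.attrs else None
        shapes = []
        for entry in json.loads(dset.attrs["ledger_json"]):
            kind = entry.pop("kind")
            if kind == "slab":
                shapes.append(SlabShape(**entry))
            else:
                shapes.append(DiscShape(**entry))
    return Phantom(grid=grid, p0=p0, shapes=tuple(shapes), seed=seed)


def phantom_to_text(path, phantom: Phantom) -> None:
    """Delimited text matrix of p0 for quick inspection."""
    header = (
        f"oaslab phantom {phantom.grid.n_rows}x{phantom.grid.n_cols} "
        f"dx={phantom.grid.dx} mm"
    )
    np.savetxt(path, phantom.p0, fmt="%.9g", delimiter="\t", header=header)


def save_alines(path, alines: AlineGrid) -> None:
    with h5py.File(path, "w") as f:
        dset = f.create_dataset("alines", data=alines.data)
        dset.attrs["dt_us"] = alines.dt
        dset.attrs["fast_spacing_um"] = alines.fast_spacing_um
        dset.attrs["slow_spacing_um"] = alines.slow_spacing_um
        dset.attrs["sound_speed"] = alines.medium.sound_speed
        dset.attrs["density"] = alines.medium.density
        dset.attrs["scene_json"] = json.dumps(alines.scene)


def load_alines(path) -> AlineGrid:
    with h5py.File(path, "r") as f:
        dset = f["alines"]
        return AlineGrid(
            data=dset[()],
            dt=float(dset.attrs["dt_us"]),
            fast_spacing_um=float(dset.attrs["fast_spacing_um"]),
            slow_spacing_um=float(dset.attrs["slow_spacing_um"]),
            medium=Medium(
                sound_speed=float(dset.attrs["sound_speed"]),
                density=float(dset.attrs["density"]),
            ),
            scene=json.loads(dset.attrs["scene_json"]),
        )


def aline_to_csv(path, alines: AlineGrid, fast_index: int, slow_index: int) -> None:
    t = alines.dt * np.arange(alines.n_samples)
    data = np.column_stack([t, alines.data[:, fast_index, slow_index]])
    np.savetxt(path, data, fmt="%.9g", delimiter=",", header="time_us,amplitude")


def write_pgm(path, image: np.ndarray) -> None:
    """ASCII (P2) PGM: the bit-exact plain-text reference image format."""
    image = np.asarray(image)
    if image.dtype != np.uint8 or image.ndim != 2:
        raise InvalidArgumentError("image must be a 2D uint8 array")
    rows = [" ".join(str(v) for v in row) for row in image]
    header = f"P2\n{image.shape[1]} {image.shape[0]}\n255\n"
    Path(path).write_text(header + "\n".join(rows) + "\n")


def write_png(path, image: np.ndarray) -> None:
    image = np.asarray(image)
    if image.dtype != np.uint8 or image.ndim != 2:
        raise InvalidArgumentError("image must be a 2D uint8 array")
    Image.fromarray(image, mode="L").save(path)


def write_report(path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def load_config(path) -> dict:
    """YAML experiment configuration."""
    with open(path) as f:
        cfg = yaml.safe_load(f)
    return cfg or {}
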
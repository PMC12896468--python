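import numpy as np
import pytest

from oaslab import (
    Medium,
    SensorGeometry,
    build_grid,
    discrimination_phantom,
    new_phantom,
    propagate_spectral,
    record_planar,
    run_sim1,
)
from oaslab.phantom import PLANAR_SENSOR_COLS, POINT_SENSOR_COL, SENSOR_ROW


@pytest.fixture(scope="session")
def medium():
    return Medium()


@pytest.fixture(scope="session")
def sim1_report():
    """The reference discrimination run (seed 0), shared across tests."""
    return run_sim1(seed=0)


@pytest.fixture(scope="session")
def sim1_signals(medium):
    """Point and planar waveforms of the reference scene (seed 0)."""
    phantom = discrimination_phantom(0)
    line = SensorGeometry.line(SENSOR_ROW, *PLANAR_SENSOR_COLS)
    (cells,) = propagate_spectral(phantom, medium, line)
    planar = record_planar(cells)
    point = cells[POINT_SENSOR_COL - PLANAR_SENSOR_COLS[0]]
    return {"phantom": phantom, "cells": cells, "planar": planar, "point": point}


def fdtd_point_trace(phantom, medium, cell, dt, n_samples, pad_factor=2, fdt=0.05):
    """Independent second-order finite-difference solution at one cell.

    Leapfrog in time, 5-point Laplacian in space, on the same zero-padded
    periodic domain as the spectral propagator; the zero-initial-velocity
    start uses the standard half-step Taylor correction.
    """
    g = phantom.grid
    n_pad = (g.n_rows * pad_factor, g.n_cols * pad_factor)
    u = np.zeros(n_pad)
    u[: g.n_rows, : g.n_cols] = phantom.p0
    steps_per = max(1, round(dt / fdt))
    fdt = dt / steps_per
    lam = (medium.sound_speed * fdt / g.dx) ** 2

    def lap(w):
        return (
            np.roll(w, 1, 0) + np.roll(w, -1, 0) + np.roll(w, 1, 1) + np.roll(w, -1, 1)
            - 4 * w
        )

    u_prev = u.copy()
    u = u + 0.5 * lam * lap(u)
    trace = np.empty(n_samples)
    trace[0] = u_prev[cell]
    step = 1
    for i in range(1, n_samples):
        while step < i * steps_per:
            u_prev, u = u, 2 * u - u_prev + lam * lap(u)
            step += 1
        trace[i] = u[cell]
    return trace


@pytest.fixture(scope="session")
def oracle_comparison(medium):
    """Spectral vs. finite-difference point traces on a smooth 64^2 scene.

    The FD oracle is second-order, so its accuracy envelope requires a
    smooth initial pressure (Gaussian blobs, sigma = 4 cells) and a
    moderate propagation distance; within that envelope the two solvers
    must agree closely.
    """
    n = 64
    grid = build_grid(n, n, 0.5)
    rr, cc = np.mgrid[0:n, 0:n]
    p0 = 2.0 * np.exp(-(((rr - 46) ** 2 + (cc - 32) ** 2) / (2 * 4.0**2)))
    p0 += 1.0 * np.exp(-(((rr - 40) ** 2 + (cc - 45) ** 2) / (2 * 4.0**2)))
    phantom = new_phantom(grid)
    phantom = type(phantom)(grid=grid, p0=p0)
    cell = (32, 32)
    dt, n_samples = 0.05, 280
    (wfs,) = propagate_spectral(
        phantom, medium, SensorGeometry.point(*cell), dt=dt, n_samples=n_samples
    )
    fd = fdtd_point_trace(phantom, medium, cell, dt, n_samples)
    return wfs[0].samples, fd
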
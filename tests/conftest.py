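"""Shared fixtures: phantoms at two scales and helper builders."""

from __future__ import annotations

import numpy as np
import pytest

from lungcbir.phantom import PhantomSpec, generate_lung_phantom
from lungcbir.volume import CTVolume


def small_phantom_spec(**overrides) -> PhantomSpec:
    """A fast, reduced-size phantom for unit tests (a few seconds to build)."""
    defaults = dict(
        spacing_mm=0.7,
        lung_semi_axes_mm=((24.0, 26.0, 32.0), (24.0, 26.0, 32.0)),
        emphysema_fraction=0.05,
        diameter_range_mm=(2.0, 12.0),
        airway_length_mm=24.0,
        vessels_per_lung=10,
        oversize_vessels_per_lung=1,
        seed=3,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def small_phantom():
    spec = small_phantom_spec()
    volume, masks, truth = generate_lung_phantom(spec)
    return spec, volume, masks, truth


@pytest.fixture(scope="session")
def default_phantom():
    """The full-size phantom at its study-condition defaults (seed 1)."""
    spec = PhantomSpec(seed=1)
    volume, masks, truth = generate_lung_phantom(spec)
    return spec, volume, masks, truth


@pytest.fixture(scope="session")
def dslope_phantom():
    """The emphysema-only exponent-recovery phantom (seed 1)."""
    from lungcbir.phantom import emphysema_recovery_spec

    spec = emphysema_recovery_spec(seed=1)
    volume, masks, truth = generate_lung_phantom(spec)
    return spec, volume, masks, truth


def make_annulus_volume(
    r_in: float,
    wall: float,
    spacing: float = 0.5,
    size_mm: float = 26.0,
    lumen_hu: float = -1000.0,
    wall_hu: float = 0.0,
    parenchyma_hu: float = -850.0,
    supersample: int = 4,
) -> tuple[CTVolume, tuple[float, float, float]]:
    """An axis-aligned tube with partial-volume (CT-like) edge blur.

    Returns the volume and the tube-centre coordinates in mm.
    """
    n = int(size_mm / spacing)
    c = n * spacing / 2
    off = ((np.arange(supersample) + 0.5) / supersample - 0.5) * spacing
    x = (np.arange(n) + 0.5) * spacing - c
    f_lumen = np.zeros((n, n))
    f_wall = np.zeros((n, n))
    for ox in off:
        for oy in off:
            xx, yy = np.meshgrid(x + ox, x + oy, indexing="ij")
            rho = np.hypot(xx, yy)
            f_lumen += rho <= r_in
            f_wall += (rho > r_in) & (rho <= r_in + wall)
    f_lumen /= supersample**2
    f_wall /= supersample**2
    plane = (
        f_lumen * lumen_hu
        + f_wall * wall_hu
        + (1 - f_lumen - f_wall) * parenchyma_hu
    )
    nz = int(10.0 / spacing)
    volume = np.repeat(plane[:, :, None], nz, axis=2)
    return CTVolume(volume, (spacing,) * 3), (c, c, nz * spacing / 2)
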
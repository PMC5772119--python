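"""Shared fixtures: rasterized reference shapes and small synthetic slides."""

from __future__ import annotations

import numpy as np
import pytest

import sparticle as sp


def rasterize_disk(radius: float, pad: int = 4) -> np.ndarray:
    """Boolean mask of a disk of the given radius (pixel centres within
    radius of the geometric centre)."""
    n = int(np.ceil(radius)) + pad
    yy, xx = np.mgrid[-n:n + 1, -n:n + 1]
    return np.hypot(yy, xx) <= radius


def rasterize_ellipse(a: float, b: float, pad: int = 4) -> np.ndarray:
    """Boolean mask of an axis-aligned ellipse with semi-axes a (x) and b (y)."""
    nx, ny = int(np.ceil(a)) + pad, int(np.ceil(b)) + pad
    yy, xx = np.mgrid[-ny:ny + 1, -nx:nx + 1]
    return (xx / a) ** 2 + (yy / b) ** 2 <= 1.0


def add_disk(mask: np.ndarray, center: tuple[float, float], radius: float) -> None:
    yy, xx = np.mgrid[:mask.shape[0], :mask.shape[1]]
    mask |= np.hypot(yy - center[0], xx - center[1]) <= radius


def disk_with_hyphae(radius: float, n_hyphae: int, length: float,
                     thickness: float = 2.0) -> np.ndarray:
    """Disk plus straight radial spokes — the canonical 'pellet with
    protruding hyphae' geometry used in perimeter-sensitivity checks."""
    n = int(np.ceil(radius + length)) + 4
    yy, xx = np.mgrid[-n:n + 1, -n:n + 1]
    mask = np.hypot(yy, xx) <= radius
    for k in range(n_hyphae):
        ang = 2 * np.pi * k / n_hyphae + 0.3
        u = np.array([np.sin(ang), np.cos(ang)])
        t = np.arange(radius, radius + length, 0.5)
        for ti in t:
            cy, cx = ti * u
            mask |= np.hypot(yy - cy, xx - cx) <= thickness / 2.0
    return mask


@pytest.fixture(scope="session")
def disk50() -> np.ndarray:
    return rasterize_disk(50)


@pytest.fixture(scope="session")
def ring_pellet():
    """Noise-free single-pellet slide: core radius 100 px, bright ring
    centred 20 px inside the edge, no hyphae."""
    p = sp.PelletSpec(center=(256, 256), core_radius_um=100 * 0.78,
                      ring_depth_fraction=0.2, n_hyphae=0, hypha_length_um=0.0)
    spec = sp.SynthSpec(shape=(512, 512), noise_sd=0.0, pellets=(p,), seed=11)
    img, truth = sp.generate_image(spec)
    return img, truth


@pytest.fixture(scope="session")
def small_slide():
    """Small noisy slide: three pellets, one debris speck; no bubble/fiber."""
    pellets = tuple(
        sp.PelletSpec(center=c, core_radius_um=r * 0.78,
                      n_hyphae=6, hypha_length_um=12.0)
        for c, r in (((120, 120), 40), ((120, 380), 55), ((380, 250), 30))
    )
    debris = (sp.ArtifactSpec(kind="debris", center=(380, 450),
                              debris_area_px=100.0, intensity=30.0),)
    spec = sp.SynthSpec(shape=(512, 512), pellets=pellets, artifacts=debris,
                        seed=42)
    img, truth = sp.generate_image(spec)
    return spec, img, truth
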
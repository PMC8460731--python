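"""Shared fixtures: small meshes, section images, and a reduced phantom.

The full default phantom pipeline is expensive, so it runs once per
session (the acceptance tests share it); unit tests use small inputs.
"""
from __future__ import annotations

import numpy as np
import pytest
import trimesh

from mrhist.geometry import Image2D, TriangleMesh


def random_mesh(rng: np.random.Generator, n_vertices: int = 12,
                n_faces: int = 16, scale: float = 2.0,
                offset: float = 0.0) -> TriangleMesh:
    """Random triangle soup (degenerate faces allowed) for oracle tests."""
    verts = rng.normal(scale=scale, size=(n_vertices, 3)) + offset
    faces = rng.integers(0, n_vertices, size=(n_faces, 3))
    return TriangleMesh(verts, faces, degenerate_ok=True)


@pytest.fixture(scope="session")
def ellipsoid_mesh() -> TriangleMesh:
    """Closed ~500-face ellipsoid at millimeter scale."""
    ico = trimesh.creation.icosphere(subdivisions=2, radius=1.0)
    verts = ico.vertices * np.array([6.0, 4.0, 3.0])
    return TriangleMesh(verts, ico.faces)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def binary_disk_image(n: int = 64, spacing: float = 0.5,
                      rx: float = 10.0, ry: float = 7.0) -> Image2D:
    x, y = np.meshgrid(np.arange(n) * spacing, np.arange(n) * spacing,
                       indexing="ij")
    c = n * spacing / 2
    disk = (((x - c) / rx) ** 2 + ((y - c) / ry) ** 2 < 1).astype(float)
    return Image2D(disk, [spacing, spacing], [0.0, 0.0])


@pytest.fixture(scope="session")
def disk_image() -> Image2D:
    return binary_disk_image()


@pytest.fixture(scope="session")
def small_phantom():
    """Reduced simulated study: 3 blocks, small in-plane extent.

    Used by unit tests that need a coherent multi-stage dataset without
    paying for the full default phantom.
    """
    from mrhist.phantom import PhantomSpec, simulate_full

    spec = PhantomSpec(
        volume_size_mm=(18.0, 18.0, 14.0),
        tissue_radii_mm=(6.5, 6.0, 4.5),
        lesion_center_mm=(0.5, -0.5, 0.0),
        lesion_radii_mm=(2.8, 2.5, 2.2),
        tumor_radii_mm=(4.0, 3.7, 3.2),
        seed=7,
    )
    return spec, *simulate_full(spec)


@pytest.fixture(scope="session")
def default_phantom_run():
    """The full default-condition phantom pipeline, run once per session."""
    from mrhist.phantom import PhantomSpec, simulate_full
    from mrhist.pipeline import run_phantom_pipeline

    spec = PhantomSpec(seed=1)
    phantom, exvivo, blocks = simulate_full(spec)
    result = run_phantom_pipeline(phantom, exvivo, blocks, mode="full3d")
    return spec, phantom, exvivo, blocks, result
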
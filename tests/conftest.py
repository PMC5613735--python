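"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math
from collections import deque

import numpy as np
import pytest

from histovol import StackSpec, generate_stack
from histovol.synthetic import MisalignmentSpec
from histovol.volume import Label


@pytest.fixture(scope="session")
def default_stack():
    """The full-size default synthetic stack (256x256x24, seed 42)."""
    spec = StackSpec()
    sections, truth = generate_stack(spec)
    return spec, sections, truth


@pytest.fixture(scope="session")
def small_stack():
    """A fast desk-size stack for unit tests (64x64x6, no damage)."""
    spec = StackSpec(
        n_slices=6,
        width=64,
        height=64,
        damaged_slices=(),
        seed=7,
        misalignment=MisalignmentSpec(max_rotation_deg=3.0, max_translation_px=4.0),
    )
    spec = _shrink_organ(spec)
    sections, truth = generate_stack(spec)
    return spec, sections, truth


def _shrink_organ(spec: StackSpec) -> StackSpec:
    from dataclasses import replace

    from histovol.synthetic import ClusterSpec, OrganSpec, SpeckleSpec

    return replace(
        spec,
        organ=OrganSpec(center=(32.0, 32.0), semi_axes=(20.0, 17.0), drift=(2.0, -1.0)),
        clusters=ClusterSpec(per_slice=6, radius_range=(2.0, 4.0)),
        speckle=SpeckleSpec(per_slice=4, radius_range=(1.0, 2.0)),
    )


# --------------------------------------------------------------------------
# independent oracles (kept free of the implementation paths they check)


def grid_search_rigid(moving: np.ndarray, fixed: np.ndarray, step: float = 1e-3):
    """Brute-force rigid fit: scan theta, solve the optimal translation per
    theta in closed form (centroid difference), return the best (theta, t,
    rms).  Independent of the analytic estimator it benchmarks."""
    thetas = np.arange(-math.pi, math.pi, step)
    mc = moving.mean(axis=0)
    fc = fixed.mean(axis=0)
    m0 = moving - mc
    f0 = fixed - fc
    cos, sin = np.cos(thetas), np.sin(thetas)
    # rotated moving clouds for every theta: (T, N, 2)
    rx = cos[:, None] * m0[:, 0] - sin[:, None] * m0[:, 1]
    ry = sin[:, None] * m0[:, 0] + cos[:, None] * m0[:, 1]
    sq = (rx - f0[:, 0]) ** 2 + (ry - f0[:, 1]) ** 2
    rms = np.sqrt(sq.mean(axis=1))
    best = int(np.argmin(rms))
    theta = float(thetas[best])
    r = np.array([[cos[best], -sin[best]], [sin[best], cos[best]]])
    t = fc - r @ mc
    return theta, t, float(rms[best])


_NEIGHBOURS_6 = [
    (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
]
_NEIGHBOURS_26 = [
    (dy, dx, dz)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dy, dx, dz) != (0, 0, 0)
]


def bfs_component(mask: np.ndarray, seed_yxz: tuple[int, int, int], connectivity: int):
    """Plain breadth-first search of the connected True-component containing
    the seed, for 6- or 26-connectivity.  Returns a boolean mask."""
    offsets = _NEIGHBOURS_6 if connectivity == 6 else _NEIGHBOURS_26
    ny, nx, nz = mask.shape
    visited = np.zeros_like(mask, dtype=bool)
    if not mask[seed_yxz]:
        return visited
    queue = deque([seed_yxz])
    visited[seed_yxz] = True
    while queue:
        y, x, z = queue.popleft()
        for dy, dx, dz in offsets:
            yy, xx, zz = y + dy, x + dx, z + dz
            if 0 <= yy < ny and 0 <= xx < nx and 0 <= zz < nz:
                if mask[yy, xx, zz] and not visited[yy, xx, zz]:
                    visited[yy, xx, zz] = True
                    queue.append((yy, xx, zz))
    return visited


def random_label_volume(rng: np.random.Generator, shape=(20, 20, 10), p_tissue=0.35):
    """A random label grid: Bernoulli tissue with a random positive subset."""
    tissue = rng.random(shape) < p_tissue
    labels = np.where(tissue, int(Label.NEGATIVE), int(Label.BACKGROUND)).astype(np.uint8)
    positive = tissue & (rng.random(shape) < 0.3)
    labels[positive] = int(Label.POSITIVE)
    return labels
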
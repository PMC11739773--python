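"""Shared fixtures: canonical geometries and velocity models.

Everything is generated programmatically; heavyweight meshes are
module-scoped so each is built once per session.
"""

import numpy as np
import pytest

from reentry_scout import (
    ScarSpec,
    VelocityModel,
    assign_fibers,
    build_disc,
    build_slab,
)


@pytest.fixture(scope="session")
def iso_vel():
    """Isotropic 0.5 mm/ms in healthy tissue (analytic-oracle setting)."""
    return VelocityModel(healthy=(0.5, 0.5), bz=(0.25, 0.25))


@pytest.fixture(scope="session")
def aniso_vel():
    return VelocityModel(healthy=(0.6, 0.3), bz=(0.25, 0.125))


def _with_fibers(model, alpha=0.0):
    assign_fibers(model, alpha, alpha)
    return model


@pytest.fixture(scope="session")
def slab_homog():
    """40 x 40 mm homogeneous 2D slab, 0.5 mm edges."""
    return _with_fibers(build_slab(40, 40, 0, 0.5))


@pytest.fixture(scope="session")
def disc_core():
    """Disc r = 11 mm with a central non-conducting core r = 9 mm: the
    canonical annular reentry geometry (conducting ring 9..11 mm)."""
    scar = ScarSpec(core_regions=[("ellipsoid", (0, 0, 0), (9.0, 9.0, 1e9))])
    return _with_fibers(build_disc(11.0, 0.5, scar))


@pytest.fixture(scope="session")
def central_core_slab():
    scar = ScarSpec(core_regions=[("box", (20, 20, 0), (10, 10, 0))])
    return _with_fibers(build_slab(40, 40, 0, 1.0, scar))


@pytest.fixture(scope="session")
def single_channel_slab():
    """Left-anchored core with one border-zone channel through it."""
    scar = ScarSpec(
        core_regions=[("box", (8, 20, 0), (18.5, 10, 0))],
        channels=[(np.array([[8.0, 10.0], [8.0, 30.0]]), 3.0)],
    )
    return _with_fibers(build_slab(40, 40, 0, 1.0, scar))


@pytest.fixture(scope="session")
def two_channel_slab():
    """Two wall-anchored cores, one channel each: two disjoint circuits."""
    scar = ScarSpec(
        core_regions=[
            ("box", (9, 20, 0), (20, 10, 0)),
            ("box", (31, 20, 0), (20, 10, 0)),
        ],
        channels=[
            (np.array([[9.0, 10.0], [9.0, 30.0]]), 3.0),
            (np.array([[31.0, 10.0], [31.0, 30.0]]), 3.0),
        ],
    )
    return _with_fibers(build_slab(40, 40, 0, 1.0, scar))


@pytest.fixture(scope="session")
def plane_block():
    """20 x 20 x 10 mm block, core above z = 5: planar interface 4 cm^2."""
    scar = ScarSpec(core_regions=[("box", (10, 10, 7.5), (24, 24, 5))])
    return _with_fibers(build_slab(20, 20, 10, 1.0, scar))


@pytest.fixture(scope="session")
def sphere_block():
    """24 mm cube with a spherical core r = 10 mm, 0.75 mm edges."""
    scar = ScarSpec(core_regions=[("ellipsoid", (12, 12, 12), (10, 10, 10))])
    return _with_fibers(build_slab(24, 24, 24, 0.75, scar))


def nearest_node(model, xyz):
    return int(np.argmin(np.linalg.norm(model.nodes - np.asarray(xyz, float), axis=1)))


def grid_geodesic_oracle(size_mm, h, v, src_xy, blocked_fn):
    """Independent geodesic-distance oracle on a refined grid graph.

    Dijkstra over a structured grid with axis, diagonal and knight moves
    (16-neighbourhood), so the direction-set metrication error is ~1%.
    `blocked_fn(pts) -> bool mask` marks non-conducting points; an edge is
    traversable when its endpoints and midpoint are all conducting.
    Returns a callable xy -> first-arrival time (ms).
    """
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import dijkstra

    n = int(round(size_mm / h)) + 1
    xs = np.arange(n) * h
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel()])
    ok = ~blocked_fn(pts)
    idx = np.arange(n * n).reshape(n, n)
    moves = [(1, 0), (0, 1), (1, 1), (1, -1), (2, 1), (1, 2), (2, -1), (1, -2)]
    rows, cols, w = [], [], []
    for dx, dy in moves:
        x0 = slice(max(0, -dx), n - max(0, dx))
        y0 = slice(max(0, -dy), n - max(0, dy))
        x1 = slice(max(0, dx), n + min(0, dx) or None)
        y1 = slice(max(0, dy), n + min(0, dy) or None)
        a = idx[x0, y0].ravel()
        b = idx[x1, y1].ravel()
        mid = 0.5 * (pts[a] + pts[b])
        good = ok[a] & ok[b] & ~blocked_fn(mid)
        rows.append(a[good])
        cols.append(b[good])
        w.append(np.full(good.sum(), np.hypot(dx, dy) * h / v))
    g = coo_matrix(
        (np.concatenate(w), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n * n, n * n),
    )
    src = int(np.argmin(np.linalg.norm(pts - np.asarray(src_xy, float), axis=1)))
    dist = dijkstra(g + g.T, directed=False, indices=src)

    def lookup(xy):
        i = int(np.argmin(np.linalg.norm(pts - np.asarray(xy, float), axis=1)))
        return float(dist[i])

    return lookup
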
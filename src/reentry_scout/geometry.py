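"""Synthetic ventricular geometry: slabs, discs, annuli, an idealized LV.

All builders are deterministic given their arguments.  Scar anatomy is
painted onto the mesh from a :class:`~reentry_scout.model.ScarSpec`:
elements whose centroid falls inside a core region become CORE, elements
within the border-zone rim width become BZ, and channel polylines relabel
CORE back to BZ to carve conducting corridors.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np

from .model import BZ, CORE, HEALTHY, PacingSiteSet, ScarSpec, VentricularModel

# Kuhn decomposition of the unit cube into 6 tetrahedra sharing the main
# diagonal (0,0,0)-(1,1,1); conforming across a translated structured grid.
_KUHN = [
    (0, 1, 3, 7), (0, 1, 5, 7), (0, 2, 3, 7),
    (0, 2, 6, 7), (0, 4, 5, 7), (0, 4, 6, 7),
]


def _label_from_scar(model: VentricularModel, scar: Optional[ScarSpec]) -> None:
    if scar is None or not scar.core_regions:
        return
    c = model.centroids()
    d = scar.core_distance(c)
    tissue = np.full(model.n_elements, HEALTHY, dtype=np.int64)
    tissue[d <= scar.bz_rim_width] = BZ
    tissue[d <= 0.0] = CORE
    if scar.channels:
        ch = scar.channel_mask(c)
        tissue[ch & (tissue == CORE)] = BZ
    if (tissue == CORE).sum() == 0:
        warnings.warn("scar core regions fall outside the mesh; clipped away")
    model.tissue = tissue


def build_slab(
    width_mm: float,
    height_mm: float,
    depth_mm: float = 0.0,
    edge_len_mm: float = 1.0,
    scar: Optional[ScarSpec] = None,
) -> VentricularModel:
    """Rectangular slab: triangle mesh if depth is 0, tetrahedral otherwise.

    The slab occupies [0, width] x [0, height] (x [0, depth]); structured
    grid with target edge length `edge_len_mm`.
    """
    if edge_len_mm <= 0 or width_mm <= 0 or height_mm <= 0 or depth_mm < 0:
        raise ValueError("degenerate slab dimensions")
    nx = max(1, round(width_mm / edge_len_mm))
    ny = max(1, round(height_mm / edge_len_mm))
    xs = np.linspace(0.0, width_mm, nx + 1)
    ys = np.linspace(0.0, height_mm, ny + 1)
    if depth_mm == 0.0:
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        nodes = np.column_stack([X.ravel(), Y.ravel(), np.zeros(X.size)])
        nid = np.arange((nx + 1) * (ny + 1)).reshape(nx + 1, ny + 1)
        a = nid[:-1, :-1].ravel()
        b = nid[1:, :-1].ravel()
        c = nid[1:, 1:].ravel()
        d = nid[:-1, 1:].ravel()
        elements = np.concatenate(
            [np.column_stack([a, b, c]), np.column_stack([a, c, d])]
        )
        model = VentricularModel(
            nodes, elements, np.zeros(len(elements), dtype=np.int64), kind="slab2d"
        )
        model.transmural = np.zeros(model.n_nodes)
    else:
        nz = max(1, round(depth_mm / edge_len_mm))
        zs = np.linspace(0.0, depth_mm, nz + 1)
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        nid = np.arange(nodes.shape[0]).reshape(nx + 1, ny + 1, nz + 1)
        corners = [
            nid[:-1, :-1, :-1], nid[1:, :-1, :-1], nid[:-1, 1:, :-1], nid[1:, 1:, :-1],
            nid[:-1, :-1, 1:], nid[1:, :-1, 1:], nid[:-1, 1:, 1:], nid[1:, 1:, 1:],
        ]
        corner_arr = np.stack([c.ravel() for c in corners], axis=1)
        elements = np.concatenate([corner_arr[:, list(t)] for t in _KUHN])
        model = VentricularModel(
            nodes, elements, np.zeros(len(elements), dtype=np.int64), kind="slab3d"
        )
        model.transmural = nodes[:, 2] / depth_mm
    _label_from_scar(model, scar)
    return model


def _polar_mesh(r_in: float, r_out: float, edge_len_mm: float, kind: str):
    """Structured polar triangle mesh between two radii (annulus or disc ring)."""
    n_theta = max(8, int(np.ceil(2 * np.pi * r_out / edge_len_mm)))
    n_r = max(1, round((r_out - r_in) / edge_len_mm))
    rs = np.linspace(r_in, r_out, n_r + 1)
    thetas = np.arange(n_theta) * (2 * np.pi / n_theta)
    R, T = np.meshgrid(rs, thetas, indexing="ij")
    nodes = np.column_stack(
        [(R * np.cos(T)).ravel(), (R * np.sin(T)).ravel(), np.zeros(R.size)]
    )
    nid = np.arange(nodes.shape[0]).reshape(n_r + 1, n_theta)
    tris = []
    for i in range(n_r):
        a = nid[i]
        b = nid[i + 1]
        a1 = np.roll(a, -1)
        b1 = np.roll(b, -1)
        tris.append(np.column_stack([a, b, b1]))
        tris.append(np.column_stack([a, b1, a1]))
    elements = np.concatenate(tris)
    model = VentricularModel(
        nodes, elements, np.zeros(len(elements), dtype=np.int64), kind=kind
    )
    model.transmural = np.zeros(model.n_nodes)
    return model


def build_annulus(
    r_inner_mm: float,
    r_outer_mm: float,
    edge_len_mm: float = 0.5,
    scar: Optional[ScarSpec] = None,
) -> VentricularModel:
    """2D annulus (ring) — the canonical single-loop reentry geometry."""
    if not 0 < r_inner_mm < r_outer_mm:
        raise ValueError("need 0 < r_inner < r_outer")
    model = _polar_mesh(r_inner_mm, r_outer_mm, edge_len_mm, "annulus")
    _label_from_scar(model, scar)
    return model


def build_disc(
    radius_mm: float,
    edge_len_mm: float = 0.5,
    scar: Optional[ScarSpec] = None,
) -> VentricularModel:
    """2D disc with a central vertex fan inside a structured polar ring."""
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    r0 = max(edge_len_mm, radius_mm / max(2, round(radius_mm / edge_len_mm)))
    model = _polar_mesh(r0, radius_mm, edge_len_mm, "disc")
    n_theta = max(8, int(np.ceil(2 * np.pi * radius_mm / edge_len_mm)))
    center = len(model.nodes)
    nodes = np.vstack([model.nodes, [[0.0, 0.0, 0.0]]])
    inner = np.arange(n_theta)  # first ring in construction order
    fan = np.column_stack([np.full(n_theta, center), inner, np.roll(inner, -1)])
    elements = np.vstack([model.elements, fan])
    out = VentricularModel(
        nodes, elements, np.zeros(len(elements), dtype=np.int64), kind="disc"
    )
    out.transmural = np.zeros(out.n_nodes)
    _label_from_scar(out, scar)
    return out


def build_ellipsoid_lv(
    long_axis_mm: float,
    short_axis_mm: float,
    wall_thickness_mm: float,
    edge_len_mm: float = 2.0,
    scar: Optional[ScarSpec] = None,
    base_z_frac: float = 0.25,
) -> VentricularModel:
    """Truncated-ellipsoid LV shell (apex at z = -long axis, base plane above).

    The epicardial surface is the ellipsoid with semi-axes
    (short, short, long); the endocardium is offset inward by the wall
    thickness.  The shell is truncated by the plane z = base_z_frac * long
    axis.  Endo and epi node sets are stored for transmural coordinates.
    """
    a_epi, b_epi = long_axis_mm, short_axis_mm
    w = wall_thickness_mm
    if not 0 < w < short_axis_mm:
        raise ValueError("wall thickness must be positive and < short axis")
    a_endo, b_endo = a_epi - w, b_epi - w
    z0 = base_z_frac * a_epi
    if z0 >= a_endo:
        raise ValueError("base plane truncates above the endocardial apex")

    n_s = max(2, round(w / edge_len_mm))
    arc = a_epi * (np.pi - np.arccos(z0 / a_epi))
    n_phi = max(6, int(np.ceil(arc / edge_len_mm)))
    n_theta = max(12, int(np.ceil(2 * np.pi * b_epi / edge_len_mm)))

    layers_a = np.linspace(a_endo, a_epi, n_s + 1)
    layers_b = np.linspace(b_endo, b_epi, n_s + 1)

    nodes = []
    ring_id = np.empty((n_s + 1, n_phi, n_theta), dtype=np.int64)
    apex_id = np.empty(n_s + 1, dtype=np.int64)
    thetas = np.arange(n_theta) * (2 * np.pi / n_theta)
    for s in range(n_s + 1):
        a_s, b_s = layers_a[s], layers_b[s]
        phi_base = np.arccos(np.clip(z0 / a_s, -1.0, 1.0))
        phis = phi_base + (np.pi - phi_base) * np.arange(n_phi) / n_phi
        for j, phi in enumerate(phis):
            r = b_s * np.sin(phi)
            z = a_s * np.cos(phi)
            ring_id[s, j] = len(nodes) + np.arange(n_theta)
            nodes.extend(
                np.column_stack(
                    [r * np.cos(thetas), r * np.sin(thetas), np.full(n_theta, z)]
                )
            )
        apex_id[s] = len(nodes)
        nodes.append(np.array([0.0, 0.0, -a_s]))
    nodes = np.asarray(nodes)

    tets = []
    for s in range(n_s):
        for j in range(n_phi):
            k = np.arange(n_theta)
            k1 = (k + 1) % n_theta
            if j < n_phi - 1:
                c = [
                    ring_id[s, j, k], ring_id[s, j, k1],
                    ring_id[s, j + 1, k], ring_id[s, j + 1, k1],
                    ring_id[s + 1, j, k], ring_id[s + 1, j, k1],
                    ring_id[s + 1, j + 1, k], ring_id[s + 1, j + 1, k1],
                ]
            else:  # collapse the next ring onto the apex node
                ap0 = np.full(n_theta, apex_id[s])
                ap1 = np.full(n_theta, apex_id[s + 1])
                c = [
                    ring_id[s, j, k], ring_id[s, j, k1], ap0, ap0,
                    ring_id[s + 1, j, k], ring_id[s + 1, j, k1], ap1, ap1,
                ]
            corner = np.stack(c, axis=1)
            for t in _KUHN:
                tet = corner[:, list(t)]
                # drop tets collapsed by the apex identification
                distinct = (
                    (tet[:, 0] != tet[:, 1]) & (tet[:, 0] != tet[:, 2])
                    & (tet[:, 0] != tet[:, 3]) & (tet[:, 1] != tet[:, 2])
                    & (tet[:, 1] != tet[:, 3]) & (tet[:, 2] != tet[:, 3])
                )
                tets.append(tet[distinct])
    elements = np.concatenate(tets)

    model = VentricularModel(
        nodes, elements, np.zeros(len(elements), dtype=np.int64), kind="lv"
    )
    tm = np.empty(model.n_nodes)
    for s in range(n_s + 1):
        tm[ring_id[s].ravel()] = s / n_s
        tm[apex_id[s]] = s / n_s
    model.transmural = tm
    model.node_sets["endo"] = np.append(ring_id[0].ravel(), apex_id[0])
    model.node_sets["epi"] = np.append(ring_id[-1].ravel(), apex_id[-1])
    model.validate()
    _label_from_scar(model, scar)
    return model


# ----------------------------------------------------------------------
# fibers


def element_gradients(model: VentricularModel, nodal: np.ndarray) -> np.ndarray:
    """Per-element gradient of a nodal scalar field (linear shape functions)."""
    x = model.nodes[model.elements]
    f = nodal[model.elements]
    if model.dim == 2:
        # in-plane gradient of linear interpolant on each triangle
        e1 = x[:, 1] - x[:, 0]
        e2 = x[:, 2] - x[:, 0]
        g11 = np.einsum("ij,ij->i", e1, e1)
        g12 = np.einsum("ij,ij->i", e1, e2)
        g22 = np.einsum("ij,ij->i", e2, e2)
        det = g11 * g22 - g12 * g12
        df1 = f[:, 1] - f[:, 0]
        df2 = f[:, 2] - f[:, 0]
        a = (g22 * df1 - g12 * df2) / det
        b = (g11 * df2 - g12 * df1) / det
        return a[:, None] * e1 + b[:, None] * e2
    A = np.stack([x[:, 1] - x[:, 0], x[:, 2] - x[:, 0], x[:, 3] - x[:, 0]], axis=1)
    rhs = np.stack([f[:, 1] - f[:, 0], f[:, 2] - f[:, 0], f[:, 3] - f[:, 0]], axis=1)
    return np.linalg.solve(A, rhs[..., None])[..., 0]


def assign_fibers(
    model: VentricularModel,
    alpha_endo_deg: float = 60.0,
    alpha_epi_deg: float = -60.0,
) -> np.ndarray:
    """Rule-based fiber field: in-plane helix angle rotating linearly
    across the wall from `alpha_endo_deg` (endocardium, transmural 0) to
    `alpha_epi_deg` (epicardium, transmural 1).

    Slabs use the sheet plane (x, y) with the angle measured from +x; the
    idealized LV uses the local (circumferential, longitudinal) frame.  2D
    models have transmural coordinate 0 everywhere and get the constant
    endocardial angle.  The fiber field is stored on the model and
    returned.
    """
    if model.transmural is None:
        if model.kind == "lv":
            raise ValueError("LV model without endo/epi transmural coordinate")
        model.transmural = np.zeros(model.n_nodes)
    tm_el = model.transmural[model.elements].mean(axis=1)
    alpha = np.deg2rad(alpha_endo_deg + (alpha_epi_deg - alpha_endo_deg) * tm_el)

    if model.kind == "lv":
        grad = element_gradients(model, model.transmural)
        nrm = np.linalg.norm(grad, axis=1, keepdims=True)
        nrm[nrm == 0] = 1.0
        n_hat = grad / nrm
        zhat = np.array([0.0, 0.0, 1.0])
        e_c = np.cross(np.broadcast_to(zhat, n_hat.shape), n_hat)
        bad = np.linalg.norm(e_c, axis=1) < 1e-8
        e_c[bad] = np.array([1.0, 0.0, 0.0])  # apex: frame degenerates
        e_c /= np.linalg.norm(e_c, axis=1, keepdims=True)
        e_l = np.cross(n_hat, e_c)
        e_l /= np.linalg.norm(e_l, axis=1, keepdims=True)
        fibers = np.cos(alpha)[:, None] * e_c + np.sin(alpha)[:, None] * e_l
    else:
        fibers = np.column_stack(
            [np.cos(alpha), np.sin(alpha), np.zeros(len(alpha))]
        )
    fibers /= np.linalg.norm(fibers, axis=1, keepdims=True)
    model.fibers = fibers
    return fibers


# ----------------------------------------------------------------------
# AHA segments and pacing sites


def _aha_segment_ids(model: VentricularModel, apex_cap_frac: float = 0.15) -> np.ndarray:
    c = model.centroids()
    z = c[:, 2]
    ell = (z - z.min()) / (z.max() - z.min())  # 0 apex .. 1 base
    theta = np.mod(np.arctan2(c[:, 1], c[:, 0]), 2 * np.pi)  # anterior = +x
    seg = np.empty(model.n_elements, dtype=np.int64)
    basal = ell >= 2 / 3
    mid = (ell >= 1 / 3) & ~basal
    apical = (ell >= apex_cap_frac) & ~basal & ~mid
    cap = ~(basal | mid | apical)
    seg[basal] = 1 + (theta[basal] // (np.pi / 3)).astype(int)
    seg[mid] = 7 + (theta[mid] // (np.pi / 3)).astype(int)
    seg[apical] = 13 + (theta[apical] // (np.pi / 2)).astype(int)
    seg[cap] = 17
    return seg


def assign_aha_and_pacing(model: VentricularModel, n_sites: int = 17):
    """AHA-style segmentation plus one pacing node per segment.

    LV models get the standard 17-segment division (basal/mid/apical thirds
    along the long axis, 6/6/4 equal-angle sectors plus the apex cap).
    Slab/disc models get `n_sites` surrogate sites uniformly spaced around
    the mesh boundary.  Each site is the conducting node nearest the
    segment centroid; a segment that is entirely scar core is skipped with
    a warning.
    """
    node_ok = model.node_tissue() != CORE

    if model.kind == "lv":
        seg = _aha_segment_ids(model)
        model.aha = seg
        meas = model.measures()
        cents = model.centroids()
        sites, segments = [], []
        for s in range(1, 18):
            m = seg == s
            if not m.any():
                continue
            cond = m & (model.tissue != CORE)
            if not cond.any():
                warnings.warn(f"AHA segment {s} is entirely scar core; site omitted")
                continue
            w = meas[cond]
            target = (cents[cond] * w[:, None]).sum(axis=0) / w.sum()
            cand = np.flatnonzero(node_ok)
            site = cand[np.argmin(np.linalg.norm(model.nodes[cand] - target, axis=1))]
            if site in sites:  # tiny segment collapsing onto a neighbour's node
                order = np.argsort(np.linalg.norm(model.nodes[cand] - target, axis=1))
                site = next(int(cand[i]) for i in order if cand[i] not in sites)
            sites.append(int(site))
            segments.append(s)
        return seg, PacingSiteSet(sites, segments)

    # surrogate segmentation: uniform boundary sites
    fn, fe = model.facets()
    boundary_nodes = np.unique(fn[fe[:, 1] < 0])
    center = model.nodes.mean(axis=0)
    rel = model.nodes[boundary_nodes] - center
    ang = np.arctan2(rel[:, 1], rel[:, 0])
    sites = []
    cand_ok = node_ok[boundary_nodes]
    for i in range(n_sites):
        target = -np.pi + 2 * np.pi * i / n_sites
        d = np.abs(np.angle(np.exp(1j * (ang - target))))
        d[~cand_ok] = np.inf
        order = np.argsort(d)
        site = next(
            int(boundary_nodes[j]) for j in order if boundary_nodes[j] not in sites
        )
        sites.append(site)
    seg = np.zeros(model.n_elements, dtype=np.int64)
    model.aha = None
    return seg, PacingSiteSet(sites, list(range(1, n_sites + 1)))
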
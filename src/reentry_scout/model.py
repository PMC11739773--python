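"""Ventricular model container: mesh + tissue labels + fibers.

Coordinates are millimetres, times milliseconds, velocities mm/ms
(numerically equal to m/s).  Elements are simplices: triangles for 2D
models (surface slabs, discs, annuli), tetrahedra for 3D models.  Tissue
labels live on elements; an interface facet's status is defined by its two
incident elements.  Scar core is electrically non-conducting everywhere
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

# Tissue label codes (element-wise).
HEALTHY = 0
BZ = 1
CORE = 2

TISSUE_NAMES = {HEALTHY: "healthy", BZ: "bz", CORE: "core"}


@dataclass
class VentricularModel:
    """Simplicial mesh with per-element tissue labels and fiber vectors.

    Attributes
    ----------
    nodes : (n_nodes, 3) float array, mm.  2D models live in the z=0 plane.
    elements : (n_elem, 3|4) int array of node indices (triangles or tets).
    tissue : (n_elem,) int array with values HEALTHY / BZ / CORE.
    fibers : (n_elem, 3) float array of unit fiber vectors.
    aha : optional (n_elem,) int array of AHA-style segment ids (1..17).
    transmural : optional (n_nodes,) float array, 0 at endocardium, 1 at
        epicardium (0 everywhere on 2D models).
    kind : free-form geometry tag ("slab2d", "slab3d", "disc", "annulus",
        "lv", ...), used by fiber and pacing heuristics.
    node_sets : named node-index sets, e.g. {"endo": ..., "epi": ...}.
    """

    nodes: np.ndarray
    elements: np.ndarray
    tissue: np.ndarray
    fibers: Optional[np.ndarray] = None
    aha: Optional[np.ndarray] = None
    transmural: Optional[np.ndarray] = None
    kind: str = "generic"
    node_sets: dict = field(default_factory=dict)

    # -- cached derived structures -------------------------------------
    _facets: Optional[tuple] = field(default=None, repr=False, compare=False)
    _edges: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(np.asarray(self.nodes, dtype=float))
        if self.nodes.shape[1] == 2:  # lift planar meshes into z=0
            self.nodes = np.column_stack([self.nodes, np.zeros(len(self.nodes))])
        self.elements = np.ascontiguousarray(np.asarray(self.elements, dtype=np.int64))
        self.tissue = np.asarray(self.tissue, dtype=np.int64)
        if self.elements.ndim != 2 or self.elements.shape[1] not in (3, 4):
            raise ValueError("elements must be (n, 3) triangles or (n, 4) tetrahedra")
        if self.tissue.shape[0] != self.elements.shape[0]:
            raise ValueError("tissue labels must cover all elements")
        if self.elements.size and self.elements.max() >= len(self.nodes):
            raise ValueError("element refers to a nonexistent node")
        if self.fibers is not None:
            self.fibers = np.asarray(self.fibers, dtype=float)

    # ------------------------------------------------------------------
    @property
    def dim(self) -> int:
        """Topological dimension: 2 for triangle meshes, 3 for tets."""
        return self.elements.shape[1] - 1

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def measures(self) -> np.ndarray:
        """Element measures: areas (mm^2) for triangles, volumes (mm^3) for tets."""
        x = self.nodes[self.elements]
        if self.dim == 2:
            a = x[:, 1] - x[:, 0]
            b = x[:, 2] - x[:, 0]
            return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)
        a = x[:, 1] - x[:, 0]
        b = x[:, 2] - x[:, 0]
        c = x[:, 3] - x[:, 0]
        return np.abs(np.einsum("ij,ij->i", np.cross(a, b), c)) / 6.0

    # -- facets ---------------------------------------------------------
    def facets(self):
        """All element facets, deduplicated.

        Returns
        -------
        facet_nodes : (n_facets, dim) int array of sorted node indices
            (edges of triangles, triangular faces of tets).
        facet_elems : (n_facets, 2) int array of incident elements,
            -1 in the second slot for boundary facets.
        """
        if self._facets is not None:
            return self._facets
        d = self.dim
        if d == 2:
            local = [(0, 1), (1, 2), (2, 0)]
        else:
            local = [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]
        per = len(local)
        fn = np.concatenate([self.elements[:, idx] for idx in local], axis=0)
        fn = np.sort(fn, axis=1)
        fe = np.tile(np.arange(self.n_elements), per)
        order = np.lexsort(fn.T[::-1])
        fn, fe = fn[order], fe[order]
        uniq, first, counts = np.unique(fn, axis=0, return_index=True, return_counts=True)
        if counts.max(initial=0) > 2:
            raise ValueError("non-conforming mesh: facet shared by >2 elements")
        elems = np.full((len(uniq), 2), -1, dtype=np.int64)
        elems[:, 0] = fe[first]
        two = counts == 2
        elems[two, 1] = fe[first[two] + 1]
        self._facets = (uniq, elems)
        return self._facets

    def facet_measures(self, facet_nodes: np.ndarray) -> np.ndarray:
        """Lengths (mm) of edge facets or areas (mm^2) of triangle facets."""
        x = self.nodes[facet_nodes]
        if facet_nodes.shape[1] == 2:
            return np.linalg.norm(x[:, 1] - x[:, 0], axis=1)
        return 0.5 * np.linalg.norm(
            np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0]), axis=1
        )

    # -- edges ----------------------------------------------------------
    def edges(self) -> np.ndarray:
        """Unique mesh edges as a sorted (n_edges, 2) int array."""
        if self._edges is not None:
            return self._edges
        d = self.dim
        if d == 2:
            pairs = [(0, 1), (1, 2), (2, 0)]
        else:
            pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        e = np.concatenate([self.elements[:, p] for p in pairs], axis=0)
        e = np.sort(e, axis=1)
        self._edges = np.unique(e, axis=0)
        return self._edges

    def element_components(self, mask: np.ndarray) -> np.ndarray:
        """Connected components of the element subset `mask` under facet adjacency.

        Returns per-element component id (-1 outside the mask).
        """
        fn, fe = self.facets()
        internal = fe[:, 1] >= 0
        a, b = fe[internal, 0], fe[internal, 1]
        keep = mask[a] & mask[b]
        a, b = a[keep], b[keep]
        n = self.n_elements
        g = coo_matrix((np.ones(len(a)), (a, b)), shape=(n, n))
        ncomp, lab = connected_components(g + g.T, directed=False)
        out = np.full(n, -1, dtype=np.int64)
        ids = {}
        for i in np.flatnonzero(mask):
            out[i] = ids.setdefault(lab[i], len(ids))
        return out

    def conducting_elements(self) -> np.ndarray:
        return self.tissue != CORE

    def node_tissue(self) -> np.ndarray:
        """Per-node minimum tissue label over incident elements.

        A node is conducting iff it belongs to at least one non-CORE element.
        """
        out = np.full(self.n_nodes, CORE, dtype=np.int64)
        for k in range(self.elements.shape[1]):
            np.minimum.at(out, self.elements[:, k], self.tissue)
        # nodes not referenced by any element stay CORE (non-conducting)
        return out

    def validate(self) -> None:
        """Check the structural invariants; raise ValueError on violation."""
        if not np.isfinite(self.nodes).all():
            raise ValueError("non-finite node coordinates")
        if not np.isin(self.tissue, [HEALTHY, BZ, CORE]).all():
            raise ValueError("unknown tissue label")
        if (self.measures() <= 0).any():
            raise ValueError("degenerate or inverted element")
        if self.fibers is not None:
            norms = np.linalg.norm(self.fibers, axis=1)
            if np.abs(norms - 1.0).max(initial=0) > 1e-6:
                raise ValueError("fiber vectors must be unit length")
        self.facets()  # raises on non-conforming connectivity


@dataclass
class ScarSpec:
    """Parametric scar description used by the synthetic geometry builders.

    core_regions : list of shapes, each either
        ("box", (cx, cy, cz), (sx, sy, sz))  — axis-aligned box, full side
        lengths in mm, or
        ("ellipsoid", (cx, cy, cz), (rx, ry, rz)) — semi-axes in mm.
    bz_rim_width : border-zone rim thickness around each core region, mm.
    channels : list of (polyline, width_mm); elements whose centroid lies
        within width/2 of the polyline are relabelled CORE -> BZ, carving a
        conducting corridor through the core.
    """

    core_regions: list = field(default_factory=list)
    bz_rim_width: float = 0.0
    channels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.bz_rim_width < 0:
            raise ValueError("bz_rim_width must be >= 0")
        for _, w in self.channels:
            if w <= 0:
                raise ValueError("channel width must be > 0")

    # signed-ish distance to the union of core regions (negative inside)
    def core_distance(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        d = np.full(len(pts), np.inf)
        for shape in self.core_regions:
            d = np.minimum(d, _shape_distance(shape, pts))
        return d

    def channel_mask(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        m = np.zeros(len(pts), dtype=bool)
        for path, width in self.channels:
            m |= _polyline_distance(np.asarray(path, dtype=float), pts) <= width / 2.0
        return m


def _shape_distance(shape, pts: np.ndarray) -> np.ndarray:
    """Distance to a parametric shape (negative inside, 0 on the boundary)."""
    name, center, size = shape
    c = np.zeros(3)
    c[: len(center)] = center
    q = pts - c
    if name == "box":
        h = np.zeros(3)
        h[: len(size)] = np.asarray(size, dtype=float) / 2.0
        h[h == 0] = np.inf  # a zero extent means "don't constrain this axis"
        d = np.abs(q) - np.where(np.isinf(h), np.inf, h)
        d = np.where(np.isinf(h), -np.inf, d)
        outside = np.linalg.norm(np.maximum(d, 0.0), axis=1)
        inside = np.minimum(d.max(axis=1), 0.0)
        return outside + inside
    if name == "ellipsoid":
        r = np.ones(3)
        r[: len(size)] = size
        rho = np.linalg.norm(q / r, axis=1)
        # approximate metric distance: exact for spheres, adequate for rims
        return (rho - 1.0) * r.min()
    raise ValueError(f"unknown shape {name!r}")


def _polyline_distance(path: np.ndarray, pts: np.ndarray) -> np.ndarray:
    if path.shape[1] == 2:
        path = np.column_stack([path, np.zeros(len(path))])
    d = np.full(len(pts), np.inf)
    for p0, p1 in zip(path[:-1], path[1:]):
        seg = p1 - p0
        L2 = seg @ seg
        if L2 == 0:
            d = np.minimum(d, np.linalg.norm(pts - p0, axis=1))
            continue
        t = np.clip((pts - p0) @ seg / L2, 0.0, 1.0)
        proj = p0 + t[:, None] * seg
        d = np.minimum(d, np.linalg.norm(pts - proj, axis=1))
    if len(path) == 1:
        d = np.minimum(d, np.linalg.norm(pts - path[0], axis=1))
    return d


@dataclass
class PacingSiteSet:
    """Pacing node indices, one per AHA (or surrogate) segment."""

    sites: list
    segments: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.sites)) != len(self.sites):
            raise ValueError("pacing sites must be distinct")

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)
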
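"""Anisotropic eikonal activation-time solver on labeled simplicial meshes.

The wavefront obeys a transversely isotropic speed law about the local
fiber direction f: a planar front with unit normal d travels at

    v(d) = sqrt(v_f^2 (f.d)^2 + v_t^2 (1 - (f.d)^2))

which is the quadratic form sqrt(d^T M d) with M = v_t^2 I +
(v_f^2 - v_t^2) f f^T.  The first-arrival time from a point source is the
geodesic distance in the dual (slowness) metric N = M^{-1}: the travel
time along a straight segment e is sqrt(e^T N e).  On- and cross-fiber the
two coincide (|e|/v_f and |e|/v_t); off-axis the ray (group) time
sqrt(e^T N e) is the physically correct arrival time and is what both
solver modes use.

Two solvers are provided:

* ``mode="fim"`` — an active-list fast-iterative scheme with element-wise
  two-point (triangle) local updates; characteristics may cross element
  interiors, so it converges to the true viscosity solution under
  refinement.
* ``mode="dijkstra"`` — shortest paths restricted to mesh edges with the
  same per-edge metric; an upper bound on the FIM solution, useful as an
  independent oracle.

Scar core is non-conducting and is removed from the update stencils
outright rather than given a small velocity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra

from .model import BZ, CORE, HEALTHY, VentricularModel

INF = np.inf


@dataclass(frozen=True)
class VelocityModel:
    """Per-tissue (along-fiber, cross-fiber) conduction velocities, mm/ms.

    Defaults are literature-typical surrogates: healthy myocardium
    (0.6, 0.3), border zone slowed to (0.25, 0.125); core never conducts.
    """

    healthy: tuple = (0.6, 0.3)
    bz: tuple = (0.25, 0.125)

    def __post_init__(self):
        for vf, vt in (self.healthy, self.bz):
            if not 0 < vt <= vf:
                raise ValueError("need 0 < v_transverse <= v_fiber")

    def pairs_for(self, tissue: np.ndarray) -> np.ndarray:
        """(n, 2) array of (v_f, v_t); NaN rows for CORE."""
        out = np.full((len(tissue), 2), np.nan)
        out[tissue == HEALTHY] = self.healthy
        out[tissue == BZ] = self.bz
        return out

    def scaled(self, k: float) -> "VelocityModel":
        return VelocityModel(
            tuple(k * v for v in self.healthy), tuple(k * v for v in self.bz)
        )


def directional_speed(fiber, direction, velocity_pair) -> float:
    """Planar-front speed along a unit direction: sqrt(d^T M d)."""
    f = np.asarray(fiber, dtype=float)
    d = np.asarray(direction, dtype=float)
    nd = np.linalg.norm(d)
    if nd == 0:
        raise ValueError("zero-length direction")
    d = d / nd
    f = f / np.linalg.norm(f)
    vf, vt = velocity_pair
    c2 = float(np.dot(f, d)) ** 2
    return float(np.sqrt(vf * vf * c2 + vt * vt * (1.0 - c2)))


@dataclass
class ActivationMap:
    """Per-node first-arrival times with a steepest-descent predecessor tree.

    ``times`` is +inf on unreached and core-only nodes; ``pred`` holds the
    conducting neighbour with the smallest arrival time strictly below the
    node's own (-1 at sources and unreached nodes), so every predecessor
    chain descends monotonically to a source.
    """

    times: np.ndarray
    sources: np.ndarray
    pred: np.ndarray

    def path_to_source(self, node: int) -> list:
        path = [int(node)]
        seen = {int(node)}
        while self.pred[path[-1]] >= 0:
            nxt = int(self.pred[path[-1]])
            if nxt in seen:  # numerical tie loop guard
                break
            path.append(nxt)
            seen.add(nxt)
        return path


# ----------------------------------------------------------------------
# per-element dual metrics and edge travel times


def element_metrics(model: VentricularModel, velocity: VelocityModel) -> np.ndarray:
    """(n_elem, 3, 3) dual metric N = M^{-1} per element; NaN for CORE."""
    if model.fibers is None:
        raise ValueError("model has no fiber field; call assign_fibers first")
    vp = velocity.pairs_for(model.tissue)
    vf2 = vp[:, 0] ** 2
    vt2 = vp[:, 1] ** 2
    f = model.fibers
    ff = np.einsum("ni,nj->nij", f, f)
    eye = np.eye(3)
    return (1.0 / vt2)[:, None, None] * eye + (1.0 / vf2 - 1.0 / vt2)[
        :, None, None
    ] * ff


def edge_travel_times(
    model: VentricularModel,
    velocity: VelocityModel,
    edges: np.ndarray,
) -> np.ndarray:
    """Group-velocity travel time (ms) along each mesh edge.

    Each edge uses the mean fiber direction of its incident conducting
    elements and the slower of their tissues; +inf if every incident
    element is core or either endpoint is core-only.
    """
    edges = np.atleast_2d(np.asarray(edges, dtype=np.int64))
    key_all, inc = _edge_incidence(model)
    vf_all, vt_all = _speeds_for(inc, velocity)
    keys = edges.min(axis=1) * model.n_nodes + edges.max(axis=1)
    pos = _searchsorted_exact(key_all, keys)

    tau = np.full(len(edges), INF)
    node_ok = model.node_tissue() != CORE
    ok = node_ok[edges[:, 0]] & node_ok[edges[:, 1]] & (pos >= 0)
    if not ok.any():
        return tau

    e_vec = model.nodes[edges[:, 1]] - model.nodes[edges[:, 0]]
    mean_fib = inc["fiber_sum"][pos[ok]]
    nrm = np.linalg.norm(mean_fib, axis=1, keepdims=True)
    nrm[nrm == 0] = 1.0
    fhat = mean_fib / nrm
    vf = vf_all[pos[ok]]
    vt = vt_all[pos[ok]]
    e = e_vec[ok]
    proj = np.einsum("ij,ij->i", e, fhat)
    par2 = proj**2
    perp2 = np.einsum("ij,ij->i", e, e) - par2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.sqrt(par2 / vf**2 + np.maximum(perp2, 0.0) / vt**2)
    tau[ok] = np.where(np.isfinite(t), t, INF)
    return tau


def edge_travel_time(model, velocity, edge) -> float:
    """Scalar convenience wrapper around :func:`edge_travel_times`."""
    return float(edge_travel_times(model, velocity, np.asarray([edge]))[0])


def _searchsorted_exact(sorted_keys: np.ndarray, keys: np.ndarray) -> np.ndarray:
    pos = np.searchsorted(sorted_keys, keys)
    pos = np.clip(pos, 0, len(sorted_keys) - 1)
    bad = sorted_keys[pos] != keys
    pos[bad] = -1
    return pos


_EDGE_CACHE: dict = {}


def _edge_incidence(model: VentricularModel):
    """Sorted edge keys + per-edge aggregates over incident conducting elements."""
    cache_key = id(model)
    hit = _EDGE_CACHE.get(cache_key)
    if hit is not None and hit[0] is model:
        return hit[1], hit[2]
    d = model.dim
    pairs = (
        [(0, 1), (1, 2), (2, 0)]
        if d == 2
        else [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    )
    e = np.concatenate([model.elements[:, p] for p in pairs], axis=0)
    eid = np.tile(np.arange(model.n_elements), len(pairs))
    keys = e.min(axis=1).astype(np.int64) * model.n_nodes + e.max(axis=1)
    order = np.argsort(keys, kind="stable")
    keys, eid = keys[order], eid[order]
    uk, start = np.unique(keys, return_index=True)
    # aggregate conducting incident elements per unique edge
    cond = model.tissue[eid] != CORE
    fib = np.zeros((model.n_elements, 3)) if model.fibers is None else model.fibers
    vp = np.full((model.n_elements, 2), np.nan)
    vp[model.tissue == HEALTHY] = (1.0, 1.0)  # placeholders, replaced below
    grp = np.searchsorted(uk, keys)
    n = len(uk)
    fiber_sum = np.zeros((n, 3))
    for k in range(3):
        np.add.at(fiber_sum[:, k], grp[cond], fib[eid[cond], k])
    # BZ is slower than HEALTHY for any sane VelocityModel, so track the
    # slowest conducting tissue label; speeds are resolved per query
    worst = np.full(n, -1, dtype=np.int64)  # -1 none conducting, 0 healthy, 1 bz
    t_el = np.where(model.tissue == BZ, 1, np.where(model.tissue == HEALTHY, 0, -10))
    np.maximum.at(worst, grp, t_el[eid])
    inc = {"fiber_sum": fiber_sum, "worst": worst}
    _EDGE_CACHE.clear()
    _EDGE_CACHE[cache_key] = (model, uk, inc)
    return uk, inc


def _speeds_for(inc: dict, velocity: VelocityModel):
    worst = inc["worst"]
    vf = np.where(
        worst == 1, velocity.bz[0], np.where(worst == 0, velocity.healthy[0], np.nan)
    )
    vt = np.where(
        worst == 1, velocity.bz[1], np.where(worst == 0, velocity.healthy[1], np.nan)
    )
    return vf, vt


# ----------------------------------------------------------------------
# FIM solver


class _Stencil:
    """Precomputed two-point update triples (a, b -> c) with metric dot
    products alpha = w^T N w, beta = w^T N d, gamma = d^T N d where
    w = x_a - x_b and d = x_c - x_b."""

    def __init__(self, model: VentricularModel, velocity: VelocityModel,
                 blocked: Optional[set] = None):
        N = element_metrics(model, velocity)
        cond = model.tissue != CORE
        els = model.elements[cond]
        Nc = N[cond]
        x = model.nodes
        if model.dim == 2:
            combos = [(1, 2, 0), (0, 2, 1), (0, 1, 2)]
        else:
            combos = []
            for c_loc in range(4):
                face = [k for k in range(4) if k != c_loc]
                combos += [
                    (face[0], face[1], c_loc),
                    (face[0], face[2], c_loc),
                    (face[1], face[2], c_loc),
                ]
        ia, ib, ic, al, be, ga = [], [], [], [], [], []
        for la, lb, lc in combos:
            a = els[:, la]
            b = els[:, lb]
            c = els[:, lc]
            w = x[a] - x[b]
            dv = x[c] - x[b]
            al.append(np.einsum("ni,nij,nj->n", w, Nc, w))
            be.append(np.einsum("ni,nij,nj->n", w, Nc, dv))
            ga.append(np.einsum("ni,nij,nj->n", dv, Nc, dv))
            ia.append(a)
            ib.append(b)
            ic.append(c)
        self.ia = np.concatenate(ia)
        self.ib = np.concatenate(ib)
        self.ic = np.concatenate(ic)
        self.alpha = np.concatenate(al)
        self.beta = np.concatenate(be)
        self.gamma = np.concatenate(ga)

        if blocked:
            n = model.n_nodes
            bk = {min(p, q) * n + max(p, q) for p, q in blocked}
            def kk(u, v):
                return np.minimum(u, v).astype(np.int64) * n + np.maximum(u, v)
            drop = (
                np.isin(kk(self.ia, self.ib), list(bk))
                | np.isin(kk(self.ia, self.ic), list(bk))
                | np.isin(kk(self.ib, self.ic), list(bk))
            )
            keep = ~drop
            for name in ("ia", "ib", "ic", "alpha", "beta", "gamma"):
                setattr(self, name, getattr(self, name)[keep])

        # CSR mapping: node -> triples it feeds (appears as a or b)
        n_nodes = model.n_nodes
        feed_nodes = np.concatenate([self.ia, self.ib])
        feed_triples = np.tile(np.arange(len(self.ia)), 2)
        order = np.argsort(feed_nodes, kind="stable")
        self._feed_sorted = feed_triples[order]
        self._feed_ptr = np.searchsorted(
            feed_nodes[order], np.arange(n_nodes + 1)
        )
        self.n_nodes = n_nodes

    def triples_fed_by(self, nodes: np.ndarray) -> np.ndarray:
        chunks = [
            self._feed_sorted[self._feed_ptr[v]: self._feed_ptr[v + 1]]
            for v in nodes
        ]
        if not chunks:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate(chunks))

    def update_values(self, t_idx: np.ndarray, T: np.ndarray) -> np.ndarray:
        """Candidate arrival times at ic for the given triple subset."""
        Ta = T[self.ia[t_idx]]
        Tb = T[self.ib[t_idx]]
        al = self.alpha[t_idx]
        be = self.beta[t_idx]
        ga = self.gamma[t_idx]
        with np.errstate(invalid="ignore", divide="ignore"):
            # endpoint candidates (lambda = 0 from b, lambda = 1 from a)
            v0 = Tb + np.sqrt(ga)
            v1 = Ta + np.sqrt(np.maximum(ga - 2 * be + al, 0.0))
            best = np.minimum(
                np.where(np.isfinite(Tb), v0, INF),
                np.where(np.isfinite(Ta), v1, INF),
            )
            # interior stationary points (both endpoints finite)
            u = Ta - Tb
            fin = np.isfinite(Ta) & np.isfinite(Tb)
            A = al * (al - u * u)
            B = -2 * be * (al - u * u)
            C = be * be - u * u * ga
            disc = B * B - 4 * A * C
            valid = fin & (disc >= 0) & (np.abs(A) > 1e-300)
            sq = np.sqrt(np.where(valid, disc, 0.0))
            for sign in (1.0, -1.0):
                lam = np.where(valid, (-B + sign * sq) / (2 * A), np.nan)
                good = valid & (lam > 0.0) & (lam < 1.0)
                q = ga - 2 * lam * be + lam * lam * al
                good &= q > 0
                # unsquared stationarity: sign(beta - lam*alpha) == sign(u)
                good &= (be - lam * al) * u >= 0
                f = Tb + lam * u + np.sqrt(np.where(good, q, 1.0))
                best = np.minimum(best, np.where(good, f, INF))
        return best


_STENCIL_CACHE: dict = {}


def _get_stencil(model, velocity, blocked_key, blocked):
    key = (id(model), velocity, blocked_key)
    hit = _STENCIL_CACHE.get(key)
    if hit is not None and hit[0] is model:
        return hit[1]
    st = _Stencil(model, velocity, blocked)
    if len(_STENCIL_CACHE) > 32:
        _STENCIL_CACHE.clear()
    _STENCIL_CACHE[key] = (model, st)
    return st


def solve(
    model: VentricularModel,
    velocity: VelocityModel,
    sources: Sequence[int],
    onset_times: Optional[Sequence[float]] = None,
    blocked_edges: Optional[Iterable] = None,
    mode: str = "fim",
    tol: float = 1e-3,
) -> ActivationMap:
    """First-arrival activation map from one or more pacing sources.

    Parameters
    ----------
    sources : node indices; must be conducting.
    onset_times : per-source onset (ms), default all 0.
    blocked_edges : node-index pairs treated as non-traversable (the
        unidirectional-block line in reentry simulations).
    mode : "fim" (element-wise local solver) or "dijkstra" (edge-restricted
        upper-bound oracle).
    tol : convergence/stopping tolerance in ms for the FIM sweeps.
    """
    sources = np.atleast_1d(np.asarray(sources, dtype=np.int64))
    if onset_times is None:
        onsets = np.zeros(len(sources))
    else:
        onsets = np.asarray(onset_times, dtype=float)
    node_ok = model.node_tissue() != CORE
    if not node_ok[sources].all():
        raise ValueError("pacing source lies in non-conducting core")
    if not node_ok.any():
        raise ValueError("empty conducting domain")
    blocked = None
    blocked_key = None
    if blocked_edges is not None:
        blocked = {tuple(sorted(map(int, e))) for e in blocked_edges}
        blocked_key = frozenset(blocked)

    if mode == "dijkstra":
        T = _solve_dijkstra(model, velocity, sources, onsets, blocked)
    elif mode == "fim":
        T = _solve_fim(model, velocity, sources, onsets, blocked, blocked_key, tol)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    T[~node_ok] = INF
    pred = _descent_predecessors(model, T, sources, blocked)
    return ActivationMap(times=T, sources=sources, pred=pred)


def _source_ball_init(model, velocity, sources, onsets, T):
    """Exact local initialization around point sources.

    First-order local solvers lose accuracy at the point-source rarefaction
    fan; seeding the two-ring neighbourhood with the exact local-metric
    time removes the dominant error.  Only used without block lines, and
    only through conducting mesh edges, so it cannot leak across core.
    """
    N = element_metrics(model, velocity)
    cond = model.tissue != CORE
    edges = model.edges()
    node_ok = model.node_tissue() != CORE
    e_ok = edges[node_ok[edges[:, 0]] & node_ok[edges[:, 1]]]
    nbr = {}
    for a, b in e_ok:
        nbr.setdefault(int(a), []).append(int(b))
        nbr.setdefault(int(b), []).append(int(a))
    # per-node tissue uniformity: init only inside a single-tissue region
    lo = np.full(model.n_nodes, 99, dtype=np.int64)
    hi = np.full(model.n_nodes, -1, dtype=np.int64)
    inc_N = np.zeros((model.n_nodes, 3, 3))
    inc_n = np.zeros(model.n_nodes)
    for k in range(model.elements.shape[1]):
        idx = model.elements[:, k]
        np.minimum.at(lo, idx[cond], model.tissue[cond])
        np.maximum.at(hi, idx[cond], model.tissue[cond])
        np.add.at(inc_N, idx[cond], N[cond])
        np.add.at(inc_n, idx[cond], 1.0)
    uniform = lo == hi

    lens = np.linalg.norm(
        model.nodes[e_ok[:, 0]] - model.nodes[e_ok[:, 1]], axis=1
    )
    h = float(lens.mean()) if len(lens) else 1.0
    r_init = max(2.0, 2.5 * h)  # mm; fixed so the seeded patch refines away
    max_hops = int(np.ceil(r_init / max(h, 1e-9))) + 2

    for s, t0 in zip(sources, onsets):
        s = int(s)
        if inc_n[s] == 0 or not uniform[s]:
            continue
        Ns = inc_N[s] / inc_n[s]
        lab = lo[s]
        frontier = {s}
        seen = {s}
        for _ in range(max_hops):
            nxt = set()
            for v in frontier:
                for w in nbr.get(v, []):
                    if w not in seen:
                        seen.add(w)
                        nxt.add(w)
            frontier = nxt
            if not frontier:
                break
        seen.discard(s)
        for v in seen:
            if not (uniform[v] and lo[v] == lab):
                continue
            e = model.nodes[v] - model.nodes[s]
            if e @ e > r_init * r_init:
                continue
            T[v] = min(T[v], t0 + np.sqrt(e @ Ns @ e))


def _solve_fim(model, velocity, sources, onsets, blocked, blocked_key, tol):
    st = _get_stencil(model, velocity, blocked_key, blocked)
    T = np.full(model.n_nodes, INF)
    T[sources] = onsets
    if not blocked and len(sources) <= 32:
        _source_ball_init(model, velocity, sources, onsets, T)
    active = np.flatnonzero(np.isfinite(T))
    guard = 0
    max_iter = 20 * (model.n_nodes + 100)
    while len(active):
        guard += 1
        if guard > max_iter:
            raise RuntimeError("eikonal iteration failed to converge")
        t_idx = st.triples_fed_by(active)
        if len(t_idx) == 0:
            break
        vals = st.update_values(t_idx, T)
        targets = st.ic[t_idx]
        prop = np.full(model.n_nodes, INF)
        np.minimum.at(prop, targets, vals)
        cand = np.flatnonzero(prop < T - tol)
        T[cand] = prop[cand]
        active = cand
    return T


def _conducting_edge_graph(model, velocity, blocked):
    edges = model.edges()
    tau = edge_travel_times(model, velocity, edges)
    ok = np.isfinite(tau)
    if blocked:
        n = model.n_nodes
        bk = np.fromiter(
            (min(p, q) * n + max(p, q) for p, q in blocked), dtype=np.int64,
            count=len(blocked),
        )
        keys = edges[:, 0] * n + edges[:, 1]
        ok &= ~np.isin(keys, bk)
    e = edges[ok]
    w = tau[ok]
    n = model.n_nodes
    g = coo_matrix((w, (e[:, 0], e[:, 1])), shape=(n, n))
    return (g + g.T).tocsr()


def _solve_dijkstra(model, velocity, sources, onsets, blocked):
    g = _conducting_edge_graph(model, velocity, blocked)
    dist = _csgraph_dijkstra(g, directed=False, indices=sources)
    dist = np.atleast_2d(dist)
    return (dist + onsets[:, None]).min(axis=0)


def _descent_predecessors(model, T, sources, blocked):
    """pred[v] = conducting neighbour of v with minimal T strictly below T[v]."""
    edges = model.edges()
    if blocked:
        n = model.n_nodes
        bk = np.fromiter(
            (min(p, q) * n + max(p, q) for p, q in blocked), dtype=np.int64,
            count=len(blocked),
        )
        keys = edges[:, 0] * n + edges[:, 1]
        edges = edges[~np.isin(keys, bk)]
    frm = np.concatenate([edges[:, 0], edges[:, 1]])
    to = np.concatenate([edges[:, 1], edges[:, 0]])
    ok = np.isfinite(T[frm]) & (T[frm] < T[to])
    frm, to = frm[ok], to[ok]
    pred = np.full(model.n_nodes, -1, dtype=np.int64)
    if len(to):
        order = np.lexsort((frm, T[frm], to))
        to_s, frm_s = to[order], frm[order]
        first = np.ones(len(to_s), dtype=bool)
        first[1:] = to_s[1:] != to_s[:-1]
        pred[to_s[first]] = frm_s[first]
    pred[sources] = -1
    return pred
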
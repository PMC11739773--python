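"""Virtual induction of reentry: isthmus detection, unidirectional block,
round-trip times, and per-model vulnerability metrics.

The engine paces the model at each site, detects where the paced wavefront
splits around scar and collides with itself (the discrete signature of an
electrically isolated isthmus), then simulates unidirectional block across
each collision line and re-solves the eikonal problem to measure the
round-trip time (RTT) — the time for the front to travel the long way
around the circuit and re-cross the recovered line of block, the
computational analogue of the VT cycle length.  Circuits faster than a
cutoff (default 50 ms) are discarded, and duplicates induced from
different pacing sites are merged by correlating cyclically aligned
reentry activation maps.

Per model this yields four vulnerability metrics: total induced VTs,
unique VTs, and the mean and maximum RTT over unique circuits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .eikonal import ActivationMap, VelocityModel, edge_travel_times, solve
from .model import CORE, VentricularModel

#: RTT cutoff, ms: only circuits slower than this are taken forward.
RTT_MIN_MS = 50.0

#: Correlation threshold above which two reentry maps are duplicates.
RHO_DUP = 0.9


@dataclass
class Isthmus:
    """A wavefront-collision cluster bounding a scar-related circuit."""

    pacing_site: int
    collision_edges: np.ndarray  # (k, 2) node pairs
    side_a: np.ndarray
    side_b: np.ndarray
    loop_nodes: np.ndarray
    encloses_scar: bool


@dataclass
class Circuit:
    """One viable reentrant pathway (an isthmus traversed in one direction)."""

    isthmus: Isthmus
    direction: str  # "a_to_b" | "b_to_a"
    rtt_ms: float
    reentry_map: np.ndarray
    pacing_site: int
    loop_mask: Optional[np.ndarray] = None  # nodes near the circuit's loop


@dataclass
class VitaMetrics:
    total_vts: int
    unique_vts: int
    mean_rtt_ms: float
    max_rtt_ms: float
    no_circuits: bool = False

    def as_dict(self) -> dict:
        return {
            "total_vts": self.total_vts,
            "unique_vts": self.unique_vts,
            "mean_rtt_ms": self.mean_rtt_ms,
            "max_rtt_ms": self.max_rtt_ms,
        }


# ----------------------------------------------------------------------
# wavefront-split detection


def detect_splits(
    model: VentricularModel,
    activation: ActivationMap,
    velocity: VelocityModel,
    d_scar: Optional[float] = None,
) -> List[Isthmus]:
    """Find wavefront-collision clusters whose circuit encloses scar core.

    A conducting edge (a, b) is a collision edge when the discrete front
    directions at both endpoints (node minus its steepest-descent
    predecessor) point into the edge from opposite sides and the arrival
    times differ by less than the edge travel time — two branches of the
    same paced front meeting head-on.  Edges are clustered by shared
    nodes; each cluster's two descent paths to the source close a loop,
    and the cluster is kept only if that loop encloses (2D) or abuts (3D)
    core tissue, i.e. the isthmus is scar-related.
    """
    T = activation.times
    pred = activation.pred
    edges = model.edges()
    node_ok = model.node_tissue() != CORE
    ok = (
        node_ok[edges[:, 0]]
        & node_ok[edges[:, 1]]
        & np.isfinite(T[edges[:, 0]])
        & np.isfinite(T[edges[:, 1]])
        & (pred[edges[:, 0]] >= 0)
        & (pred[edges[:, 1]] >= 0)
    )
    cand = edges[ok]
    if len(cand) == 0:
        return []
    ga = model.nodes[cand[:, 0]] - model.nodes[pred[cand[:, 0]]]
    gb = model.nodes[cand[:, 1]] - model.nodes[pred[cand[:, 1]]]
    eab = model.nodes[cand[:, 1]] - model.nodes[cand[:, 0]]
    ia = np.einsum("ij,ij->i", ga, eab)
    ib = np.einsum("ij,ij->i", gb, -eab)
    # head-on seeds: both discrete front directions point into the edge
    # (90-degree cones) and oppose each other
    into = (ia > 1e-9) & (ib > 1e-9)
    opposed = np.einsum("ij,ij->i", ga, gb) < 0
    tau = edge_travel_times(model, velocity, cand)
    dt = np.abs(T[cand[:, 0]] - T[cand[:, 1]])
    close = dt < tau
    seed_mask = into & close & opposed
    # crease extensions: where the branches have already merged, the later
    # branch's front runs parallel to the crease (zero into-edge
    # component) while the other still points across it; a smooth oblique
    # front instead gives strictly opposite signs, so it never matches
    shear = ((ia > 1e-9) & (ib >= -1e-9)) | ((ib > 1e-9) & (ia >= -1e-9))
    ext_mask = shear & close & ~seed_mask
    if not seed_mask.any():
        return []

    mean_h = float(
        np.linalg.norm(
            model.nodes[edges[:, 0]] - model.nodes[edges[:, 1]], axis=1
        ).mean()
    )
    if d_scar is None:
        d_scar = 2.0 * mean_h
    r_link = 3.0 * mean_h

    from scipy.spatial import cKDTree

    mid = 0.5 * (model.nodes[cand[:, 0]] + model.nodes[cand[:, 1]])
    seeds = np.flatnonzero(seed_mask)
    exts = np.flatnonzero(ext_mask)

    # cluster seed edges by midpoint proximity: the discrete collision
    # locus drifts across mesh columns and may skip rows where the fronts
    # meet exactly at a node, so node-sharing alone would fragment it
    stree = cKDTree(mid[seeds])
    pairs = stree.query_pairs(r_link, output_type="ndarray")
    g = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
        shape=(len(seeds), len(seeds)),
    )
    _, seed_lab = connected_components(g + g.T, directed=False)

    # grow each cluster along connected crease (extension) edges so the
    # line of block terminates on scar or on the mesh boundary instead of
    # leaving a free end the circulating front could slip around
    etree = cKDTree(mid[exts]) if len(exts) else None
    clusters = []
    for ci in np.unique(seed_lab):
        members = list(seeds[seed_lab == ci])
        if etree is not None:
            taken = np.zeros(len(exts), dtype=bool)
            frontier = members
            while frontier:
                hits = etree.query_ball_point(mid[frontier], r_link)
                new = set()
                for h in hits:
                    for j in h:
                        if not taken[j]:
                            taken[j] = True
                            new.add(j)
                frontier = [exts[j] for j in new]
                members.extend(frontier)
        clusters.append(np.asarray(sorted(members), dtype=np.int64))

    core_cent = model.centroids()[model.tissue == CORE]
    if len(core_cent) == 0:
        return []
    source = int(activation.sources[0])

    isthmuses = []
    for members in clusters:
        ce = cand[members]
        is_seed = seed_mask[members]
        # representative head-on edge: smallest arrival-time mismatch
        seed_edges = ce[is_seed]
        mism = np.abs(T[seed_edges[:, 0]] - T[seed_edges[:, 1]])
        rep = seed_edges[int(np.argmin(mism))]
        loop = _close_loop(
            activation.path_to_source(rep[0]), activation.path_to_source(rep[1])
        )
        if not _loop_encloses_scar(model, loop, core_cent, d_scar):
            continue
        side_a, side_b = _split_sides(model, ce, mid[members], r_link)
        if len(side_a) == 0 or len(side_b) == 0:
            continue
        # close the line: where the discrete locus jogs across a mesh
        # column, the connecting edge joins the two sides directly and must
        # be blocked too or the circulating front slips through the jog
        in_a = np.isin(edges[:, 0], side_a) & np.isin(edges[:, 1], side_b)
        in_b = np.isin(edges[:, 0], side_b) & np.isin(edges[:, 1], side_a)
        ce = np.unique(
            np.vstack([np.sort(ce, axis=1), edges[in_a | in_b]]), axis=0
        )
        isthmuses.append(
            Isthmus(
                pacing_site=source,
                collision_edges=ce,
                side_a=side_a,
                side_b=side_b,
                loop_nodes=np.asarray(loop, dtype=np.int64),
                encloses_scar=True,
            )
        )
    return isthmuses


def _close_loop(path_a, path_b):
    """Join the two descent paths into a loop, trimming the shared tail."""
    sa, sb = list(path_a), list(path_b)
    while len(sa) > 1 and len(sb) > 1 and sa[-1] == sb[-1] and sa[-2] == sb[-2]:
        sa.pop()
        sb.pop()
    return sa[::-1] + sb  # source-ish end .. a .. b .. source-ish end


def _loop_encloses_scar(model, loop, core_cent, d_scar) -> bool:
    pts = model.nodes[np.asarray(loop)]
    if model.dim == 2:
        if len(loop) < 3:
            return False
        from shapely.geometry import Point, Polygon

        poly = Polygon(pts[:, :2])
        if not poly.is_valid:
            poly = poly.buffer(0)
        if poly.is_empty:
            return False
        return any(poly.contains(Point(c[0], c[1])) for c in core_cent)
    # 3D: the loop must pass close to core tissue
    from scipy.spatial import cKDTree

    return bool(cKDTree(core_cent).query(pts, k=1)[0].min() <= d_scar)


def _split_sides(model, coll_edges: np.ndarray, mids: np.ndarray, r_link: float):
    """Partition collision-cluster nodes into the two sides of the line.

    Edge crossing directions are oriented consistently by propagating a
    sign over the midpoint-proximity graph (the line may bend, so no single
    reference direction works); each endpoint then votes for the side its
    edge assigns it, and majority resolves nodes shared by several edges
    of a zig-zag discrete locus."""
    from scipy.spatial import cKDTree

    m = len(coll_edges)
    u = model.nodes[coll_edges[:, 1]] - model.nodes[coll_edges[:, 0]]
    tree = cKDTree(mids)
    nbrs = tree.query_ball_point(mids, r_link)
    sign = np.zeros(m, dtype=np.int8)
    for start in range(m):
        if sign[start]:
            continue
        sign[start] = 1
        stack = [start]
        while stack:
            i = stack.pop()
            for j in nbrs[i]:
                if sign[j] == 0:
                    d = float(u[i] @ u[j])
                    sign[j] = sign[i] if d >= 0 else -sign[i]
                    stack.append(j)
    votes: dict = {}
    for (a, b), s in zip(coll_edges, sign):
        a, b = int(a), int(b)
        votes[a] = votes.get(a, 0) - int(s)
        votes[b] = votes.get(b, 0) + int(s)
    side_a = np.array(sorted(v for v, s in votes.items() if s < 0), dtype=np.int64)
    side_b = np.array(sorted(v for v, s in votes.items() if s > 0), dtype=np.int64)
    return side_a, side_b


# ----------------------------------------------------------------------
# round-trip time under unidirectional block


def compute_rtt(
    model: VentricularModel,
    velocity: VelocityModel,
    isthmus: Isthmus,
    direction: str = "a_to_b",
) -> Optional[Circuit]:
    """Simulate unidirectional block across the isthmus and measure RTT.

    All collision edges are blocked; the near side of the front is paced at
    t = 0 and the eikonal problem re-solved.  The RTT is the earliest time
    the circulating front can re-cross the (by then recovered) line of
    block: min over collision edges of the far-side arrival plus the edge
    crossing time.  Returns None when the far side is unreachable under
    block (a fully blocked, non-inducible circuit).
    """
    if direction == "a_to_b":
        src, far = isthmus.side_a, isthmus.side_b
    elif direction == "b_to_a":
        src, far = isthmus.side_b, isthmus.side_a
    else:
        raise ValueError("direction must be 'a_to_b' or 'b_to_a'")
    blocked = [tuple(e) for e in isthmus.collision_edges]
    amap = solve(model, velocity, src, blocked_edges=blocked)
    T = amap.times
    tau = edge_travel_times(model, velocity, isthmus.collision_edges)
    src_set = set(int(s) for s in src)
    far_set = set(int(s) for s in far)
    rtts = []
    for (a, b), t_e in zip(isthmus.collision_edges, tau):
        a, b = int(a), int(b)
        # only edges that actually span the line of block close the loop
        if a in src_set and b in far_set:
            far_node = b
        elif b in src_set and a in far_set:
            far_node = a
        else:
            continue
        if np.isfinite(T[far_node]) and np.isfinite(t_e):
            rtts.append(T[far_node] + t_e)
    if not rtts:
        return None
    from scipy.spatial import cKDTree

    el = model.edges()
    mean_h = float(
        np.linalg.norm(model.nodes[el[:, 0]] - model.nodes[el[:, 1]], axis=1).mean()
    )
    loop_pts = model.nodes[isthmus.loop_nodes]
    d_loop = cKDTree(loop_pts).query(model.nodes, k=1)[0]
    return Circuit(
        isthmus=isthmus,
        direction=direction,
        rtt_ms=float(min(rtts)),
        reentry_map=T,
        pacing_site=isthmus.pacing_site,
        loop_mask=d_loop <= 3.0 * mean_h,
    )


def filter_circuits(circuits: Sequence[Circuit], rtt_min_ms: float = RTT_MIN_MS):
    """Keep circuits with RTT strictly above the cutoff; order preserved."""
    if rtt_min_ms < 0:
        raise ValueError("rtt_min_ms must be >= 0")
    return [c for c in circuits if c.rtt_ms > rtt_min_ms]


# ----------------------------------------------------------------------
# duplicate filtering


def _cyclic_similarity(ci: Circuit, cj: Circuit, n_shift: int = 64) -> float:
    """Max Pearson correlation between cyclically aligned reentry maps.

    Both maps are wrapped modulo their own RTT into loop phase before
    comparison — two inductions of the same circuit differ by a constant
    phase offset (where along the loop the block line sat), which the
    shift search absorbs, while opposite traversal directions
    anti-correlate under every shift.  The comparison is restricted to
    nodes near either circuit's loop: the circuit's identity lives in the
    timing around its pathway, and the smooth far field would otherwise
    make unrelated circuits in the same model look alike."""
    mask = np.isfinite(ci.reentry_map) & np.isfinite(cj.reentry_map)
    if ci.loop_mask is not None and cj.loop_mask is not None:
        mask &= ci.loop_mask | cj.loop_mask
    if mask.sum() < 10:
        return -1.0
    if ci.rtt_ms <= 0 or cj.rtt_ms <= 0:
        return -1.0
    x = np.mod(ci.reentry_map[mask], ci.rtt_ms)
    yj = cj.reentry_map[mask]
    rtt = cj.rtt_ms
    best = -1.0
    xs = x - x.mean()
    xn = np.linalg.norm(xs)
    if xn == 0:
        return -1.0
    for s in np.arange(0.0, rtt + 1e-9, rtt / n_shift):
        y = np.mod(yj + s, rtt)
        ys = y - y.mean()
        yn = np.linalg.norm(ys)
        if yn == 0:
            continue
        best = max(best, float(xs @ ys) / (xn * yn))
    return best


def deduplicate(
    circuits: Sequence[Circuit],
    rho_dup: float = RHO_DUP,
    n_shift: int = 64,
) -> List[Circuit]:
    """Merge duplicate circuits (same reentrant pathway induced repeatedly).

    Pairs whose cyclically aligned reentry maps correlate at or above
    `rho_dup` are merged by union-find; the representative of each group is
    its lowest-RTT member (ties: first encountered).  Circuits with fewer
    than 10 finite map nodes are kept as their own group.
    """
    if not 0 < rho_dup <= 1:
        raise ValueError("rho_dup must be in (0, 1]")
    n = len(circuits)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    for i in range(n):
        for j in range(i + 1, n):
            sim = max(
                _cyclic_similarity(circuits[i], circuits[j], n_shift),
                _cyclic_similarity(circuits[j], circuits[i], n_shift),
            )
            if sim >= rho_dup:
                union(i, j)

    groups: dict = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    uniques = []
    for root in sorted(groups):
        members = groups[root]
        best = min(members, key=lambda k: (circuits[k].rtt_ms, k))
        uniques.append(circuits[best])
    return uniques


# ----------------------------------------------------------------------
# full per-model run


def run_vita(
    model: VentricularModel,
    velocity: VelocityModel,
    pacing_sites,
    rtt_min_ms: float = RTT_MIN_MS,
    rho_dup: float = RHO_DUP,
    rtt_max_ms: Optional[float] = None,
):
    """Pace every site, induce and filter circuits, and summarize.

    Returns (VitaMetrics, all filtered circuits, unique circuits).  Total
    VTs are counted after the RTT filter but before deduplication;
    deduplication is applied across all circuits, including same-site
    duplicates.
    """
    all_circuits: List[Circuit] = []
    for site in pacing_sites:
        amap = solve(model, velocity, [int(site)])
        for isth in detect_splits(model, amap, velocity):
            for direction in ("a_to_b", "b_to_a"):
                c = compute_rtt(model, velocity, isth, direction)
                if c is not None:
                    all_circuits.append(c)
    kept = filter_circuits(all_circuits, rtt_min_ms)
    if rtt_max_ms is not None:
        kept = [c for c in kept if c.rtt_ms <= rtt_max_ms]
    uniques = deduplicate(kept, rho_dup)
    if not uniques:
        metrics = VitaMetrics(0, 0, 0.0, 0.0, no_circuits=True)
    else:
        rtts = np.array([c.rtt_ms for c in uniques])
        metrics = VitaMetrics(
            total_vts=len(kept),
            unique_vts=len(uniques),
            mean_rtt_ms=float(rtts.mean()),
            max_rtt_ms=float(rtts.max()),
        )
    return metrics, kept, uniques
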
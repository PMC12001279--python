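"""Fold-network extraction and the two-component pattern metric.

A deformed epidermis surface is turned into a planar graph of fold valleys:
vertices whose minimum principal curvature is most negative (concave creases
under the outward-normal sign convention) are selected by quantile, projected
to the ventral view, rasterized, thinned to a unit-width skeleton and
converted to a graph. After simplification the graph decomposes into
*domains* (cycles — interior faces of the planar embedding) and *incomplete*
(dead-end) edges. The metric vector is

    c1 = sum of cycle perimeters / toepad length
    c2 = sum of incomplete edge lengths / toepad length

and samples are compared by Euclidean distance after per-component
inter-sample standardization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import trimesh
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.morphology import skeletonize

from morphofold.mesh import EPIDERMIS, LayeredTetMesh

__all__ = [
    "CurvatureField",
    "FoldNetwork",
    "MetricVector",
    "Normalizer",
    "min_principal_curvature",
    "extract_fold_mask",
    "skeletonize_fold_mask",
    "network_from_raster_mask",
    "simplify_network",
    "compute_metrics",
    "fit_normalizer",
    "normalize",
    "network_distance",
    "layer_thickness",
    "epidermis_surface",
    "extract_fold_network",
]


# ---------------------------------------------------------------------------
# curvature


@dataclass
class CurvatureField:
    """Per-vertex principal curvatures, outward-normal sign convention.

    A unit sphere with outward normals has ``kappa_min = +1``; fold valleys
    (concave creases) have ``kappa_min < 0``.
    """

    kappa_min: np.ndarray
    kappa_max: np.ndarray


def _check_manifold(surface: trimesh.Trimesh) -> None:
    edges = np.sort(surface.edges, axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    if np.any(counts > 2):
        raise ValueError("surface is non-manifold (edge shared by > 2 faces)")


def min_principal_curvature(surface: trimesh.Trimesh) -> CurvatureField:
    """Discrete principal curvatures by local quadric fitting.

    For each vertex a quadric height function is least-squares fitted over
    the two-ring neighbourhood in the tangent frame of the (outward) vertex
    normal; principal curvatures are the eigenvalues of the negated quadric
    Hessian, so convex regions are positive and creases negative.
    """
    _check_manifold(surface)
    V = np.asarray(surface.vertices, dtype=float)
    normals = np.asarray(surface.vertex_normals, dtype=float)
    one_ring = surface.vertex_neighbors
    n = len(V)
    kmin = np.zeros(n)
    kmax = np.zeros(n)
    for i in range(n):
        nbrs = set(one_ring[i])
        for j in list(nbrs):
            nbrs.update(one_ring[j])
        nbrs.discard(i)
        nbrs = np.fromiter(nbrs, dtype=int)
        nrm = normals[i]
        # tangent frame
        a = np.array([1.0, 0.0, 0.0]) if abs(nrm[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        e1 = np.cross(nrm, a)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(nrm, e1)
        d = V[nbrs] - V[i]
        u = d @ e1
        v = d @ e2
        h = d @ nrm
        A = np.column_stack([u, v, 0.5 * u * u, u * v, 0.5 * v * v])
        coef, *_ = np.linalg.lstsq(A, h, rcond=None)
        # second fundamental form w.r.t. the outward normal, negated sign
        II = np.array([[coef[2], coef[3]], [coef[3], coef[4]]])
        w = np.linalg.eigvalsh(-II)
        kmin[i] = w[0]
        kmax[i] = w[1]
    return CurvatureField(kappa_min=kmin, kappa_max=kmax)


def extract_fold_mask(curv: CurvatureField, quantile: float) -> np.ndarray:
    """Vertices in fold valleys: kappa_min below its q-quantile and below zero.

    The zero cap uses a small scale-relative tolerance so numerically flat
    surfaces yield an empty mask.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    k = curv.kappa_min
    thr = np.quantile(k, quantile)
    eps = 1e-6 * max(np.abs(k).max(initial=0.0), 1e-30)
    return (k <= thr) & (k < -eps)


# ---------------------------------------------------------------------------
# fold network container


@dataclass
class MetricVector:
    """Two-component fold-pattern metric (dimensionless)."""

    c1: float  # normalized total cycle perimeter
    c2: float  # normalized total incomplete-edge length

    def as_array(self) -> np.ndarray:
        return np.array([self.c1, self.c2], dtype=float)


@dataclass
class Normalizer:
    """Per-component inter-sample mean and standard deviation."""

    mean: np.ndarray
    sd: np.ndarray


def _polyline_length(pl: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(pl, axis=0), axis=1).sum())


def oriented_polyline(G: nx.Graph, u, v) -> np.ndarray:
    """Edge polyline oriented from u to v."""
    data = G.edges[u, v]
    pl = data["polyline"]
    return pl if data["start"] == u else pl[::-1]


def add_network_edge(G: nx.Graph, u, v, polyline: np.ndarray) -> None:
    """Add an edge with its polyline, subdividing to keep the graph simple.

    Self-loops and parallel edges (which arise naturally from skeletons) are
    split at interior polyline points into chains of plain edges; arc length
    is preserved exactly.
    """
    polyline = np.asarray(polyline, dtype=float)
    if len(polyline) < 2:
        return
    if u != v and not G.has_edge(u, v):
        G.add_node(u, pos=polyline[0])
        G.add_node(v, pos=polyline[-1])
        G.add_edge(u, v, polyline=polyline, start=u, length=_polyline_length(polyline))
        return
    if len(polyline) == 2:
        # degenerate parallel edge with no interior point: insert a midpoint
        mid = 0.5 * (polyline[0] + polyline[1])
        polyline = np.array([polyline[0], mid, polyline[1]])
    k = len(polyline) // 2
    w = _fresh_node(G)
    G.add_node(w, pos=polyline[k])
    add_network_edge(G, u, w, polyline[: k + 1])
    add_network_edge(G, w, v, polyline[k:])


def _fresh_node(G: nx.Graph):
    n = G.number_of_nodes()
    while G.has_node(n):
        n += 1
    return n


class FoldNetwork:
    """Planar graph of fold valleys with cycle ("domain") classification.

    ``graph`` is a simple undirected graph whose nodes carry 2D positions
    (``pos``) and whose edges carry polylines (``polyline``, ``start``,
    ``length``). Cycles are the interior faces of the planar embedding given
    by the node/polyline geometry; every edge is either a member of at least
    one cycle or an *incomplete* (dead-end / bridge) edge, never both.
    """

    def __init__(self, graph: nx.Graph, toepad_length: float):
        if toepad_length <= 0:
            raise ValueError("toepad_length must be positive")
        self.graph = graph
        self.toepad_length = float(toepad_length)
        self._cycles = None
        self._incomplete = None

    # -- classification -----------------------------------------------------

    def _classify(self):
        if self._cycles is not None:
            return
        cycles, incomplete = _classify_edges(self.graph)
        self._cycles = cycles
        self._incomplete = incomplete

    @property
    def cycles(self) -> list[dict]:
        """Interior faces: each a dict with ``edges`` (undirected pairs) and ``perimeter``."""
        self._classify()
        return self._cycles

    @property
    def incomplete_edges(self) -> list[tuple]:
        self._classify()
        return self._incomplete

    @property
    def total_cycle_perimeter(self) -> float:
        return float(sum(c["perimeter"] for c in self.cycles))

    @property
    def total_incomplete_length(self) -> float:
        return float(
            sum(self.graph.edges[u, v]["length"] for u, v in self.incomplete_edges)
        )

    @property
    def total_length(self) -> float:
        return float(sum(d["length"] for _, _, d in self.graph.edges(data=True)))


def _classify_edges(G: nx.Graph):
    """Interior faces of the planar embedding and bridge/dead-end edges.

    Directed half-edges are sorted by outgoing angle at each node; faces are
    the orbits of the standard rotation-system traversal. Faces with positive
    signed area are interior ("domains"). An edge belongs to a cycle iff it
    appears exactly once on the boundary walk of some interior face; edges
    traversed twice within every face they touch are bridges or spurs
    (incomplete).
    """
    half_next = {}
    outgoing = {}
    for u, v in G.edges():
        pl = G.edges[u, v]["polyline"]
        fwd = pl if G.edges[u, v]["start"] == u else pl[::-1]
        ang_uv = math.atan2(fwd[1][1] - fwd[0][1], fwd[1][0] - fwd[0][0])
        ang_vu = math.atan2(fwd[-2][1] - fwd[-1][1], fwd[-2][0] - fwd[-1][0])
        outgoing.setdefault(u, []).append((ang_uv, v))
        outgoing.setdefault(v, []).append((ang_vu, u))
    for node, lst in outgoing.items():
        lst.sort()
        idx = {nbr: i for i, (_, nbr) in enumerate(lst)}
        for i, (_, nbr) in enumerate(lst):
            # next half-edge after arriving at `node` from `nbr`: the
            # clockwise-next outgoing direction from the reversed half-edge
            prev = lst[(idx[nbr] - 1) % len(lst)][1]
            half_next[(nbr, node)] = (node, prev)

    faces = []
    seen = set()
    for he in list(half_next):
        if he in seen:
            continue
        orbit = []
        cur = he
        while cur not in seen:
            seen.add(cur)
            orbit.append(cur)
            cur = half_next[cur]
        faces.append(orbit)

    scale = 1.0
    pos = nx.get_node_attributes(G, "pos")
    if pos:
        arr = np.array(list(pos.values()))
        scale = max(float(np.ptp(arr, axis=0).max()), 1e-30)

    cycles = []
    cycle_edges = set()
    for orbit in faces:
        area = 0.0
        for u, v in orbit:
            pl = oriented_polyline(G, u, v)
            x, y = pl[:, 0], pl[:, 1]
            area += 0.5 * float(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1]))
        if area <= 1e-9 * scale * scale:
            continue
        counts = {}
        for u, v in orbit:
            key = (u, v) if u <= v else (v, u)
            counts[key] = counts.get(key, 0) + 1
        edges = [k for k, c in counts.items() if c == 1]
        perimeter = float(sum(G.edges[u, v]["length"] for u, v in edges))
        cycles.append({"edges": edges, "perimeter": perimeter, "area": area})
        cycle_edges.update(edges)

    incomplete = [
        (u, v) if u <= v else (v, u)
        for u, v in G.edges()
        if ((u, v) if u <= v else (v, u)) not in cycle_edges
    ]
    return cycles, incomplete


# ---------------------------------------------------------------------------
# raster skeleton -> network

_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _smooth_polyline(pl: np.ndarray, window: int = 5) -> np.ndarray:
    """Moving-average smoothing of interior points (endpoints pinned).

    Removes the raster staircase so polyline arc length approximates the
    underlying smooth curve instead of overestimating it.
    """
    if len(pl) <= 2 or window < 3:
        return pl
    out = pl.astype(float).copy()
    half = window // 2
    csum = np.cumsum(np.vstack([[0, 0], pl]), axis=0)
    n = len(pl)
    for i in range(1, n - 1):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def network_from_raster_mask(
    mask: np.ndarray,
    pixel_size: float,
    origin=(0.0, 0.0),
    toepad_length: float = None,
) -> FoldNetwork:
    """Skeletonize a 2D boolean mask and convert the skeleton to a network.

    Pixel (row, col) maps to plane position ``origin + pixel_size*(col, row)``.
    """
    if toepad_length is None:
        toepad_length = mask.shape[1] * pixel_size
    skel = skeletonize(mask)
    return _skeleton_to_network(skel, pixel_size, origin, toepad_length)


def _skeleton_to_network(skel, pixel_size, origin, toepad_length) -> FoldNetwork:
    G = nx.Graph()
    coords = np.argwhere(skel)
    if len(coords) == 0:
        return FoldNetwork(G, toepad_length)
    on = set(map(tuple, coords))

    def nbrs(p):
        return [
            (p[0] + dr, p[1] + dc) for dr, dc in _OFFSETS if (p[0] + dr, p[1] + dc) in on
        ]

    deg = {p: len(nbrs(p)) for p in on}
    junction = {p for p in on if deg[p] >= 3}
    endpoint = {p for p in on if deg[p] == 1}

    # contract 8-connected clusters of junction pixels into single nodes
    jmask = np.zeros_like(skel, dtype=bool)
    for r, c in junction:
        jmask[r, c] = True
    lab, n_clusters = ndimage.label(jmask, structure=np.ones((3, 3), dtype=int))
    cluster_of = {p: int(lab[p]) for p in junction}
    cluster_pix = {}
    for p in junction:
        cluster_pix.setdefault(cluster_of[p], []).append(p)

    def to_xy(p):
        return np.array(
            [origin[0] + pixel_size * p[1], origin[1] + pixel_size * p[0]], dtype=float
        )

    node_of_cluster = {}
    next_id = 0
    for cid, pix in sorted(cluster_pix.items()):
        node_of_cluster[cid] = next_id
        G.add_node(next_id, pos=np.mean([to_xy(p) for p in pix], axis=0))
        next_id += 1
    node_of_endpoint = {}
    for p in sorted(endpoint):
        node_of_endpoint[p] = next_id
        G.add_node(next_id, pos=to_xy(p))
        next_id += 1

    def terminal_node(p):
        if p in junction:
            return node_of_cluster[cluster_of[p]]
        return node_of_endpoint[p]

    visited = set()  # corridor pixels already traced

    def trace(start_pix, first):
        """Walk from a terminal pixel through corridor pixels; returns
        (end_pixel, corridor_path) or None if the path was already traced."""
        if first in visited:
            return None
        if first in junction or first in endpoint:
            return first, []
        path = []
        prev, cur = start_pix, first
        while True:
            if cur in junction or cur in endpoint:
                return cur, path
            visited.add(cur)
            path.append(cur)
            nxt = None
            recent = set(path[-3:]) | {prev, start_pix}
            for q in nbrs(cur):
                if q in recent:
                    continue
                if q in junction or q in endpoint or q not in visited:
                    nxt = q
                    break
            if nxt is None:
                return cur, path  # dead end (shouldn't happen for degree-2)
            prev, cur = cur, nxt

    def emit(start_pix, end_pix, corridor):
        u = terminal_node(start_pix)
        if end_pix in junction or end_pix in endpoint:
            v = terminal_node(end_pix)
            pts = [G.nodes[u]["pos"]] + [to_xy(p) for p in corridor]
            pts.append(G.nodes[v]["pos"])
        else:
            # walk died inside a corridor (raster artifact): node at the tip
            v = _fresh_node(G)
            G.add_node(v, pos=to_xy(end_pix))
            pts = [G.nodes[u]["pos"]] + [to_xy(p) for p in corridor]
        pl = _smooth_polyline(np.array(pts))
        if u == v:
            # a walk returning to its own junction cluster is a genuine loop
            # only if it encloses area; 1-pixel bumps on a cluster are noise
            x, y = pl[:, 0], pl[:, 1]
            area = 0.5 * abs(float(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1])))
            if area < 3.0 * pixel_size**2:
                return
        add_network_edge(G, u, v, pl)

    # paths out of junction clusters
    emitted_jj = set()
    for p in sorted(junction):
        for q in nbrs(p):
            if q in junction:
                if cluster_of[q] != cluster_of[p]:
                    key = frozenset((cluster_of[p], cluster_of[q]))
                    if key not in emitted_jj:
                        emitted_jj.add(key)
                        u = node_of_cluster[cluster_of[p]]
                        v = node_of_cluster[cluster_of[q]]
                        add_network_edge(
                            G, u, v, np.array([G.nodes[u]["pos"], G.nodes[v]["pos"]])
                        )
                continue
            if q in endpoint:
                if q not in visited:
                    visited.add(q)
                    emit(p, q, [])
                continue
            res = trace(p, q)
            if res is None:
                continue
            end_pix, corridor = res
            if end_pix in endpoint:
                visited.add(end_pix)
            emit(p, end_pix, corridor)

    # paths between endpoints (components without junctions)
    for p in sorted(endpoint):
        if p in visited:
            continue
        visited.add(p)
        nb = nbrs(p)
        if not nb:
            continue
        q = nb[0]
        if q in endpoint:
            if q not in visited:
                visited.add(q)
                emit(p, q, [])
            continue
        if q in junction or q in visited:
            continue
        res = trace(p, q)
        if res is None:
            continue
        end_pix, corridor = res
        if end_pix in endpoint:
            visited.add(end_pix)
        emit(p, end_pix, corridor)

    # isolated loops: remaining untraced degree-2 pixels
    remaining = sorted(
        p for p in on if p not in visited and p not in junction and p not in endpoint
    )
    remaining = [p for p in remaining if deg[p] == 2]
    loop_seen = set(visited)
    for p in remaining:
        if p in loop_seen:
            continue
        loop = [p]
        loop_seen.add(p)
        prev, cur = None, p
        while True:
            nxt = None
            for q in nbrs(cur):
                if q == prev or q in junction or q in endpoint:
                    continue
                if q == p and len(loop) > 2:
                    nxt = None
                    break
                if q not in loop_seen:
                    nxt = q
                    break
            if nxt is None:
                break
            loop.append(nxt)
            loop_seen.add(nxt)
            prev, cur = cur, nxt
        if len(loop) < 4:
            continue
        k = len(loop) // 2
        a = _fresh_node(G)
        G.add_node(a, pos=to_xy(loop[0]))
        b = _fresh_node(G)
        G.add_node(b, pos=to_xy(loop[k]))
        pl1 = _smooth_polyline(np.array([to_xy(q) for q in loop[: k + 1]]))
        pl2 = _smooth_polyline(np.array([to_xy(q) for q in loop[k:] + [loop[0]]]))
        add_network_edge(G, a, b, pl1)
        add_network_edge(G, b, a, pl2)

    return FoldNetwork(G, toepad_length)


# ---------------------------------------------------------------------------
# surface -> network pipeline


def epidermis_surface(mesh: LayeredTetMesh, positions=None) -> trimesh.Trimesh:
    """Outer epidermis surface (deformed if positions given) as a trimesh.

    Keeps boundary faces owned by epidermis elements whose orientation
    agrees with the element's reference outward normal, i.e. the free outer
    skin surface (not layer side walls or the fixed base).
    """
    from morphofold.mesh import boundary_faces

    pos = mesh.points if positions is None else np.asarray(positions, dtype=float)
    pos = getattr(positions, "positions", pos) if positions is not None else pos
    faces, owner = boundary_faces(mesh.tets)
    ref = mesh.points
    fn = np.cross(
        ref[faces[:, 1]] - ref[faces[:, 0]], ref[faces[:, 2]] - ref[faces[:, 0]]
    )
    fn /= np.maximum(np.linalg.norm(fn, axis=1, keepdims=True), 1e-30)
    keep = (mesh.layer[owner] == EPIDERMIS) & (
        np.einsum("ij,ij->i", fn, mesh.normals[owner]) > 0.3
    )
    faces = faces[keep]
    used = np.unique(faces)
    remap = -np.ones(mesh.n_nodes, dtype=int)
    remap[used] = np.arange(len(used))
    return trimesh.Trimesh(vertices=pos[used], faces=remap[faces], process=False)


def skeletonize_fold_mask(
    surface: trimesh.Trimesh,
    mask: np.ndarray,
    projection_axis: int = 2,
    pixel_size: float | None = None,
) -> FoldNetwork:
    """Project masked vertices to the viewing plane, rasterize and skeletonize.

    Returns the raw (unsimplified) fold network; ``toepad_length`` is the
    extent of the projected surface outline along its principal axis.
    """
    axes = [a for a in range(3) if a != projection_axis]
    pts2 = np.asarray(surface.vertices, dtype=float)[:, axes]
    toepad_length = _principal_extent(pts2)
    if not mask.any():
        return FoldNetwork(nx.Graph(), toepad_length)
    if pixel_size is None:
        edges = np.asarray(surface.vertices)[surface.edges_unique]
        pixel_size = 0.7 * float(
            np.median(np.linalg.norm(edges[:, 0] - edges[:, 1], axis=1))
        )
    sel = pts2[mask]
    lo = pts2.min(axis=0) - 2 * pixel_size
    hi = pts2.max(axis=0) + 2 * pixel_size
    shape = np.ceil((hi - lo) / pixel_size).astype(int) + 1
    raster = np.zeros((shape[1], shape[0]), dtype=bool)  # row=y, col=x
    cols = np.clip(((sel[:, 0] - lo[0]) / pixel_size).round().astype(int), 0, shape[0] - 1)
    rows = np.clip(((sel[:, 1] - lo[1]) / pixel_size).round().astype(int), 0, shape[1] - 1)
    raster[rows, cols] = True
    raster = ndimage.binary_closing(raster, structure=np.ones((3, 3)), iterations=2)
    raster = ndimage.binary_opening(raster, structure=np.ones((2, 2)))
    # drop specks that cannot form a meaningful fold segment
    lab, _ = ndimage.label(raster, structure=np.ones((3, 3), dtype=int))
    sizes = np.bincount(lab.ravel())
    small = sizes < 8
    small[0] = False
    raster[small[lab]] = False
    return network_from_raster_mask(
        raster, pixel_size, origin=(lo[0], lo[1]), toepad_length=toepad_length
    )


def _principal_extent(pts2: np.ndarray) -> float:
    c = pts2 - pts2.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    proj = c @ vt[0]
    return float(proj.max() - proj.min())


def simplify_network(net: FoldNetwork, spur_fraction: float = 0.02) -> FoldNetwork:
    """Merge degree-2 chains and prune short spurs; idempotent.

    Arc length of merged chains is conserved exactly (polylines are
    concatenated); spurs (leaf edges) shorter than
    ``spur_fraction * toepad_length`` are removed iteratively.
    """
    G = net.graph.copy()
    min_len = spur_fraction * net.toepad_length
    changed = True
    while changed:
        changed = False
        # merge degree-2 nodes
        for node in [n for n in G.nodes if G.degree(n) == 2]:
            if not G.has_node(node) or G.degree(node) != 2:
                continue
            u, w = list(G.neighbors(node))
            if u == w or G.has_edge(u, w):
                continue  # keep a node to avoid self/parallel edges
            pl1 = oriented_polyline(G, u, node)
            pl2 = oriented_polyline(G, node, w)
            merged = np.vstack([pl1, pl2[1:]])
            G.remove_node(node)
            G.add_edge(u, w, polyline=merged, start=u, length=_polyline_length(merged))
            changed = True
        # prune short spurs
        for node in [n for n in G.nodes if G.degree(n) == 1]:
            if not G.has_node(node) or G.degree(node) != 1:
                continue
            (nbr,) = G.neighbors(node)
            if G.edges[node, nbr]["length"] < min_len:
                G.remove_node(node)
                changed = True
    G.remove_nodes_from([n for n in G.nodes if G.degree(n) == 0])
    return FoldNetwork(G, net.toepad_length)


def extract_fold_network(
    surface: trimesh.Trimesh,
    quantile: float = 0.3,
    spur_fraction: float = 0.02,
    projection_axis: int = 2,
) -> FoldNetwork:
    """Full pipeline: curvature -> valley mask -> skeleton -> simplified network."""
    curv = min_principal_curvature(surface)
    mask = extract_fold_mask(curv, quantile)
    raw = skeletonize_fold_mask(surface, mask, projection_axis)
    return simplify_network(raw, spur_fraction)


# ---------------------------------------------------------------------------
# metrics


def compute_metrics(net: FoldNetwork) -> MetricVector:
    """Raw (un-normalized) two-component metric of a fold network."""
    if net.toepad_length <= 0:
        raise ValueError("toepad_length must be positive")
    L = net.toepad_length
    return MetricVector(
        c1=net.total_cycle_perimeter / L, c2=net.total_incomplete_length / L
    )


def fit_normalizer(samples: list[MetricVector]) -> Normalizer:
    """Inter-sample per-component mean and standard deviation."""
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to fit a normalizer")
    arr = np.array([s.as_array() for s in samples])
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        raise ValueError("zero inter-sample standard deviation")
    return Normalizer(mean=mean, sd=sd)


def normalize(v: MetricVector, norm: Normalizer) -> MetricVector:
    z = (v.as_array() - norm.mean) / norm.sd
    return MetricVector(c1=float(z[0]), c2=float(z[1]))


def network_distance(a: MetricVector, b: MetricVector, norm: Normalizer) -> float:
    """Euclidean distance between normalized metric vectors."""
    za = normalize(a, norm).as_array()
    zb = normalize(b, norm).as_array()
    return float(np.linalg.norm(za - zb))


# ---------------------------------------------------------------------------
# layer thickness


def _closest_point_on_triangles(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Vectorized closest point on triangle for paired (point, triangle) arrays."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4
    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def assign(cond, val):
        m = cond & ~done
        out[m] = val[m]
        done[m] = True

    assign((d1 <= 0) & (d2 <= 0), a)
    assign((d3 >= 0) & (d4 <= d3), b)
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)
    assign((d6 >= 0) & (d5 <= d6), c)
    with np.errstate(divide="ignore", invalid="ignore"):
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)
    denom_bc = (d4 - d3) + (d5 - d6)
    with np.errstate(divide="ignore", invalid="ignore"):
        w_bc = np.where(denom_bc != 0, (d4 - d3) / denom_bc, 0.0)
    assign(
        (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0), b + w_bc[:, None] * (c - b)
    )
    s = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(s != 0, vb / s, 0.0)
        w = np.where(s != 0, vc / s, 0.0)
    assign(np.ones(len(p), dtype=bool), a + v[:, None] * ab + w[:, None] * ac)
    return out


def layer_thickness(outer: trimesh.Trimesh, inner: trimesh.Trimesh, k: int = 8):
    """Per-vertex nearest-point distance from the outer to the inner surface.

    Candidate triangles come from a kd-tree on inner triangle centroids
    (k nearest); the exact point–triangle distance is minimized over them.
    """
    pts = np.asarray(outer.vertices, dtype=float)
    tris = np.asarray(inner.triangles, dtype=float)
    centroids = tris.mean(axis=1)
    k = min(k, len(centroids))
    tree = cKDTree(centroids)
    _, idx = tree.query(pts, k=k)
    idx = np.atleast_2d(idx.T).T if idx.ndim == 1 else idx
    best = np.full(len(pts), np.inf)
    for j in range(idx.shape[1]):
        cand = tris[idx[:, j]]
        cp = _closest_point_on_triangles(pts, cand)
        d = np.linalg.norm(pts - cp, axis=1)
        best = np.minimum(best, d)
    return best
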
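"""Network-morphology quantification of assembled monomer islands.

Pipeline: bonded pairs -> geometric bond graph -> connected components
(islands) -> planar face enumeration (polygons of 3-9 monomers) -> scalar
observables: network density (ND), border ratio, polygon distributions and
their time series.

ND is the island's bond count divided by the maximum bond count of any
honeycomb-lattice subgraph with the same number of particles
(:func:`patchnet.honeycomb.compact_reference_edges`): 1 for a maximally
compact crystalline island, low for chains and ramified structures.  Frame
summaries use the island-size-weighted mean over islands of at least
``ISLAND_THRESHOLD`` (24) particles.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import networkx as nx
import numpy as np
import pandas as pd

from . import _kernels
from .honeycomb import compact_reference_edges
from .model import Configuration, ModelParams, minimum_image

__all__ = [
    "ISLAND_THRESHOLD",
    "BondGraph",
    "Island",
    "PolygonSet",
    "build_bond_graph",
    "islands_of",
    "enumerate_faces",
    "network_density",
    "face_density",
    "border_ratio",
    "polygon_distribution",
    "analyze_frame",
    "analyze_trajectory",
    "time_series",
    "FrameReport",
    "IslandStats",
]

log = logging.getLogger(__name__)

ISLAND_THRESHOLD = 24  # minimum island size entering frame-level statistics
POLYGON_RANGE = range(3, 10)  # labelled polygon sizes, 3..9-gons
MAX_DEGREE = 3


class BondGraph(nx.Graph):
    """Geometric graph of bonded monomers (max degree 3, simple).

    Nodes carry wrapped ``x, y`` coordinates; edges carry the contributing
    patch pair (simulation source) or the centre distance (point-set
    source).  ``box_side`` is set for periodic sources, None otherwise.
    """

    box_side: Optional[float] = None


def build_bond_graph(
    source: Union[Configuration, np.ndarray, pd.DataFrame],
    params: Optional[ModelParams] = None,
    cutoff: Optional[float] = None,
) -> BondGraph:
    """Bond graph from a simulation frame or a detected-centre point set.

    From a :class:`Configuration`, bonds are exactly the state-aware
    Kern-Frenkel bonds of the generating parameters.  From a point set,
    neighbours closer than ``cutoff`` (default 1.25x the modal
    nearest-neighbour distance) are bonded; degree-4+ artefacts are pruned
    by removing the longest incident edges.
    """
    g = BondGraph()
    if isinstance(source, Configuration):
        if params is None:
            raise ValueError("params required to extract bonds from a Configuration")
        n = len(source)
        for i in range(n):
            g.add_node(i, x=float(source.pos[i, 0]), y=float(source.pos[i, 1]))
        if n:
            bonds = _kernels.list_bonds(
                source.pos[:, 0].copy(), source.pos[:, 1].copy(),
                source.orient.copy(), source.states.astype(np.int8),
                source.box_side, params.sigma, params.delta, params.theta_pw)
            for i, j, a, b in bonds:
                g.add_edge(int(i), int(j), patches=(int(a), int(b)))
        g.box_side = source.box_side
        return g

    pts = np.asarray(source[["x_nm", "y_nm"]] if isinstance(source, pd.DataFrame)
                     else source, dtype=float).reshape(-1, 2)
    for i, (px, py) in enumerate(pts):
        g.add_node(i, x=float(px), y=float(py))
    g.box_side = None
    if len(pts) < 2:
        return g
    from scipy.spatial import cKDTree

    tree = cKDTree(pts)
    if cutoff is None:
        dd, _ = tree.query(pts, k=2)
        nn = dd[:, 1]
        # modal nearest-neighbour distance (kernel density mode; robust to
        # detection jitter and to a dilute-gas tail)
        if np.ptp(nn) < 1e-9 or len(nn) < 5:
            modal = float(np.median(nn))
        else:
            from scipy.stats import gaussian_kde

            kde = gaussian_kde(nn)
            grid = np.linspace(nn.min(), nn.max(), 512)
            modal = float(grid[np.argmax(kde(grid))])
        cutoff = 1.25 * modal
    pairs = sorted(tree.query_pairs(cutoff))
    for i, j in pairs:
        g.add_edge(i, j, distance=float(np.hypot(*(pts[i] - pts[j]))))
    # prune degree-4+ artefacts: repeatedly drop the longest incident edge
    heavy = [v for v in g if g.degree(v) > MAX_DEGREE]
    while heavy:
        v = heavy.pop()
        while g.degree(v) > MAX_DEGREE:
            u = max(g.neighbors(v), key=lambda w: g.edges[v, w]["distance"])
            g.remove_edge(v, u)
        heavy = [w for w in g if g.degree(w) > MAX_DEGREE]
    return g


@dataclass
class Island:
    """Connected component of the bond graph with unwrapped coordinates."""

    nodes: list[int]
    edges: list[tuple[int, int]]
    coords: dict[int, tuple[float, float]]
    percolating: bool = False
    embed_edges: list[tuple[int, int]] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def statistics_eligible(self) -> bool:
        return self.size >= ISLAND_THRESHOLD


def islands_of(g: BondGraph) -> list[Island]:
    """Split a bond graph into islands, unwrapping periodic coordinates.

    Coordinates are made consistent per component by BFS unwrapping across
    the periodic boundary.  Edges whose unwrapped endpoint distance differs
    from the minimum-image distance (wrap-around cycles of a percolating
    cluster) are excluded from the planar embedding; the island is flagged.
    """
    out = []
    box = g.box_side
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        root = comp[0]
        coords = {root: (g.nodes[root]["x"], g.nodes[root]["y"])}
        for u, v in nx.bfs_edges(g.subgraph(comp), root):
            du = np.array([g.nodes[v]["x"] - g.nodes[u]["x"],
                           g.nodes[v]["y"] - g.nodes[u]["y"]])
            if box is not None:
                du = minimum_image(du, box)
            coords[v] = (coords[u][0] + float(du[0]), coords[u][1] + float(du[1]))
        edges = [tuple(sorted(e)) for e in g.subgraph(comp).edges]
        embed = []
        percolating = False
        for u, v in edges:
            duv = np.array([g.nodes[v]["x"] - g.nodes[u]["x"],
                            g.nodes[v]["y"] - g.nodes[u]["y"]])
            if box is not None:
                duv = minimum_image(duv, box)
            unwrapped = (coords[v][0] - coords[u][0], coords[v][1] - coords[u][1])
            if (abs(unwrapped[0] - duv[0]) > 1e-6 or abs(unwrapped[1] - duv[1]) > 1e-6):
                percolating = True
            else:
                embed.append((u, v))
        out.append(Island(nodes=comp, edges=edges, coords=coords,
                          percolating=percolating, embed_edges=embed))
    return out


@dataclass
class PolygonSet:
    """Interior faces of an island's planar embedding.

    ``faces`` are the simple vertex cycles of 3-9 monomers (the labelled
    polygons); larger or non-simple interior faces are counted as ``voids``.
    ``outer_boundary`` is the vertex walk of the discarded outer face.
    """

    faces: list[tuple[int, ...]]
    voids: int
    outer_boundary: list[int]
    n_traversal_faces: int
    void_faces: list[tuple[int, ...]] = field(default_factory=list)

    @property
    def sizes(self) -> list[int]:
        return [len(f) for f in self.faces]

    def size_counts(self) -> dict[int, int]:
        c = Counter(self.sizes)
        return {k: c.get(k, 0) for k in POLYGON_RANGE}


def _segments_cross(p1, p2, p3, p4) -> bool:
    """Proper interior crossing of two segments with no shared endpoint."""

    def orient(a, b, c):
        v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        return int(v > 1e-12) - int(v < -1e-12)

    o1 = orient(p1, p2, p3)
    o2 = orient(p1, p2, p4)
    o3 = orient(p3, p4, p1)
    o4 = orient(p3, p4, p2)
    return o1 != o2 and o3 != o4 and 0 not in (o1, o2, o3, o4)


def enumerate_faces(island: Island, max_cross_fraction: float = 0.05) -> PolygonSet:
    """Enumerate interior faces by rotation-system traversal.

    Neighbours are sorted by angle around each node and the walk follows
    next-clockwise half-edges, which traverses interior faces
    counter-clockwise; the unique clockwise (negative signed area) walk is
    the outer face and is discarded.  Crossing edges (if any) are resolved by
    deleting the longer edge of each crossing pair; more than
    ``max_cross_fraction`` of crossing edges raises, as the embedding cannot
    be trusted.
    """
    coords = island.coords
    edges = list(island.embed_edges)
    if len(edges) >= 2:
        crossing = []
        for a in range(len(edges)):
            u1, v1 = edges[a]
            for b in range(a + 1, len(edges)):
                u2, v2 = edges[b]
                if len({u1, v1, u2, v2}) < 4:
                    continue
                if _segments_cross(coords[u1], coords[v1], coords[u2], coords[v2]):
                    crossing.append((a, b))
        if crossing:
            if len(crossing) > max_cross_fraction * len(edges):
                raise ValueError(
                    f"{len(crossing)} crossing edge pairs among {len(edges)} "
                    "edges: embedding not trustworthy")
            drop = set()

            def length(e):
                (u, v) = edges[e]
                return math.hypot(coords[v][0] - coords[u][0],
                                  coords[v][1] - coords[u][1])

            for a, b in crossing:
                if a in drop or b in drop:
                    continue
                loser = a if length(a) >= length(b) else b
                drop.add(loser)
                log.info("dropped crossing edge %s", edges[loser])
            edges = [e for k, e in enumerate(edges) if k not in drop]

    if not edges:
        return PolygonSet(faces=[], voids=0,
                          outer_boundary=list(island.nodes),
                          n_traversal_faces=0, void_faces=[])

    nbrs: dict[int, list[int]] = {}
    for u, v in edges:
        nbrs.setdefault(u, []).append(v)
        nbrs.setdefault(v, []).append(u)
    for v in nbrs:
        nbrs[v].sort(key=lambda w: math.atan2(coords[w][1] - coords[v][1],
                                              coords[w][0] - coords[v][0]))
    nbr_index = {v: {w: k for k, w in enumerate(ws)} for v, ws in nbrs.items()}

    visited: set[tuple[int, int]] = set()
    walks: list[list[int]] = []
    for u0, v0 in edges:
        for he in ((u0, v0), (v0, u0)):
            if he in visited:
                continue
            walk = []
            u, v = he
            while (u, v) not in visited:
                visited.add((u, v))
                walk.append(u)
                ws = nbrs[v]
                k = nbr_index[v][u]
                u, v = v, ws[(k - 1) % len(ws)]  # next clockwise around v
            walks.append(walk)

    def signed_area(walk: Sequence[int]) -> float:
        a = 0.0
        for i in range(len(walk)):
            x1, y1 = coords[walk[i]]
            x2, y2 = coords[walk[(i + 1) % len(walk)]]
            a += x1 * y2 - x2 * y1
        return 0.5 * a

    areas = [signed_area(w) for w in walks]
    outer_idx = int(np.argmin(areas))
    faces = []
    void_faces = []
    for k, w in enumerate(walks):
        if k == outer_idx:
            continue
        simple = len(set(w)) == len(w)
        if simple and len(w) in POLYGON_RANGE:
            faces.append(tuple(w))
        else:
            void_faces.append(tuple(w))
    # isolated nodes of the island are not part of any walk but remain on
    # the outer boundary (possible after crossing-edge removal)
    in_walks = set().union(*walks) if walks else set()
    boundary = list(walks[outer_idx]) + [v for v in island.nodes if v not in in_walks]
    return PolygonSet(faces=faces, voids=len(void_faces), outer_boundary=boundary,
                      n_traversal_faces=len(walks), void_faces=void_faces)


def network_density(island: Island) -> float:
    """ND = bonds / maximally-compact-honeycomb bonds for the same size.

    Equals 1 for a maximally compact honeycomb island, decreases toward
    ``(V-1)/E_max(V)`` for trees and chains.  A single particle is trivially
    compact (ND = 1).  Capped at 1: spurious detections in image-derived
    graphs can otherwise push the edge count marginally past the reference.
    """
    if island.size == 0:
        raise ValueError("empty island")
    if island.size == 1:
        return 1.0
    return min(1.0, island.n_edges / compact_reference_edges(island.size))


def face_density(island: Island, faces: Optional[PolygonSet] = None) -> float:
    """Polygon-based compactness: labelled polygons / F_max(V).

    ``F_max(V) = E_max(V) - V + 1`` is the interior-face count of the
    maximally compact honeycomb island of the same size.  1 for ideal
    crystals, exactly 0 for chains and trees — a wider dynamic range than
    the bond-based ND for sparse assemblies, since bonds spent on branches
    close no rings.  Capped at 1.
    """
    if island.size == 0:
        raise ValueError("empty island")
    f_max = compact_reference_edges(island.size) - island.size + 1
    if f_max <= 0:
        return 0.0
    if faces is None:
        faces = enumerate_faces(island)
    return min(1.0, len(faces.faces) / f_max)


def border_ratio(island: Island, faces: Optional[PolygonSet] = None) -> float:
    """Fraction of the island's polygons having a vertex on the outer border.

    0 by convention when the island contains no polygons.
    """
    if faces is None:
        faces = enumerate_faces(island)
    if not faces.faces:
        return 0.0
    border = set(faces.outer_boundary)
    on_border = sum(1 for f in faces.faces if border.intersection(f))
    return on_border / len(faces.faces)


@dataclass
class IslandStats:
    island: Island
    nd: float
    border: float
    polygon_counts: dict[int, int]
    voids: int


@dataclass
class FrameReport:
    """Morphology observables of one frame."""

    step: int
    islands: list[IslandStats]
    area: float
    n_particles: int

    @property
    def eligible(self) -> list[IslandStats]:
        return [s for s in self.islands if s.island.statistics_eligible]

    @property
    def weighted_nd(self) -> float:
        """Island-size-weighted mean ND over statistics-eligible islands."""
        el = self.eligible
        if not el:
            return np.nan
        w = np.array([s.island.size for s in el], dtype=float)
        nd = np.array([s.nd for s in el])
        return float(np.sum(w * nd) / np.sum(w))

    @property
    def island_density(self) -> float:
        return len(self.eligible) / self.area

    @property
    def particle_density(self) -> float:
        return self.n_particles / self.area

    @property
    def largest_island(self) -> Optional[IslandStats]:
        if not self.islands:
            return None
        return max(self.islands, key=lambda s: s.island.size)

    def polygon_counts(self) -> dict[int, int]:
        tot = Counter()
        for s in self.islands:
            tot.update(s.polygon_counts)
        return {k: tot.get(k, 0) for k in POLYGON_RANGE}

    @property
    def hexagon_fraction(self) -> float:
        counts = self.polygon_counts()
        total = sum(counts.values())
        return counts[6] / total if total else 0.0


def analyze_frame(
    source: Union[Configuration, np.ndarray, pd.DataFrame],
    params: Optional[ModelParams] = None,
    cutoff: Optional[float] = None,
    area: Optional[float] = None,
    step: int = 0,
) -> FrameReport:
    """Full morphology of one frame (simulation or point set)."""
    g = build_bond_graph(source, params=params, cutoff=cutoff)
    if area is None:
        if isinstance(source, Configuration):
            area = source.box_side**2
        else:
            pts = np.asarray(source[["x_nm", "y_nm"]]
                             if isinstance(source, pd.DataFrame) else source,
                             dtype=float).reshape(-1, 2)
            if len(pts):
                span = np.ptp(pts, axis=0)
                area = float(max(span[0] * span[1], 1.0))
            else:
                area = 1.0
    stats = []
    for isl in islands_of(g):
        faces = enumerate_faces(isl)
        stats.append(IslandStats(
            island=isl,
            nd=network_density(isl),
            border=border_ratio(isl, faces),
            polygon_counts=faces.size_counts(),
            voids=faces.voids,
        ))
    if isinstance(source, Configuration):
        step = source.step_index
    return FrameReport(step=step, islands=stats, area=area,
                       n_particles=g.number_of_nodes())


def polygon_distribution(
    source: Union[Configuration, np.ndarray, pd.DataFrame],
    params: Optional[ModelParams] = None,
    cutoff: Optional[float] = None,
) -> tuple[dict[int, int], float]:
    """Polygon counts by size (3-9) and the hexagon fraction of one frame."""
    rep = analyze_frame(source, params=params, cutoff=cutoff)
    return rep.polygon_counts(), rep.hexagon_fraction


def analyze_trajectory(traj, last: Optional[int] = None) -> list[FrameReport]:
    """Morphology of each recorded frame (optionally only the last ``last``)."""
    frames = traj.frames if last is None else traj.last_frames(last)
    return [analyze_frame(fr, params=traj.params) for fr in frames]


def time_series(traj, reports: Optional[list[FrameReport]] = None) -> pd.DataFrame:
    """Island density, particle density and largest-island border fraction.

    One row per recorded frame; raw values only (any smoothing is the
    caller's concern).
    """
    if len(traj.frames) < 2:
        raise ValueError("time series needs at least 2 frames")
    if reports is None:
        reports = analyze_trajectory(traj)
    rows = []
    for rep in reports:
        big = rep.largest_island
        rows.append({
            "step": rep.step,
            "island_density": rep.island_density,
            "particle_density": rep.particle_density,
            "border_fraction_largest": big.border if big else np.nan,
            "largest_island_size": big.island.size if big else 0,
            "weighted_nd": rep.weighted_nd,
            "n_polygons": sum(rep.polygon_counts().values()),
        })
    return pd.DataFrame(rows)


def report_to_tidy(reports: list[FrameReport]) -> pd.DataFrame:
    """Tidy CSV layout: one row per island per frame plus frame summaries."""
    rows = []
    for rep in reports:
        for k, s in enumerate(rep.islands):
            rows.append({
                "step": rep.step, "kind": "island", "island": k,
                "size": s.island.size, "n_edges": s.island.n_edges,
                "nd": s.nd, "border_ratio": s.border,
                **{f"n{p}gon": c for p, c in s.polygon_counts.items()},
                "voids": s.voids, "eligible": s.island.statistics_eligible,
            })
        rows.append({
            "step": rep.step, "kind": "frame", "island": -1,
            "size": rep.n_particles, "n_edges": np.nan,
            "nd": rep.weighted_nd,
            "border_ratio": rep.largest_island.border if rep.largest_island else np.nan,
            **{f"n{p}gon": c for p, c in rep.polygon_counts().items()},
            "voids": np.nan, "eligible": np.nan,
        })
    return pd.DataFrame(rows)
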
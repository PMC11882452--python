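"""Ground-truth generators for AFM-like fields of trisymmetric monomers.

Stands in for experimental AFM data: compact honeycomb islands with planted
pentagon/heptagon defects, elongated chain assemblies, dilute monomer gas,
mixed fields, and rasterized height images with AFM-style artefacts
(additive pixel noise, per-scan-line offsets).  Every generator is
seed-deterministic and records complete ground truth (bonds, island ids,
planted polygon census) so detection and morphology pipelines can be scored
against it.

Geometry is generated in lattice units (bonded centre-to-centre distance 1)
and scaled to nanometres by ``lattice_nm`` (default 16 nm).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

__all__ = [
    "SyntheticField",
    "AFMImage",
    "make_compact_island",
    "make_elongated_island",
    "make_gas",
    "make_field",
    "rasterize",
    "DEFAULT_LATTICE_NM",
]

log = logging.getLogger(__name__)

DEFAULT_LATTICE_NM = 16.0
TWO_PI = 2.0 * math.pi


@dataclass
class SyntheticField:
    """Monomer centres plus complete ground truth.

    ``points`` are centre coordinates in nm; ``bonds`` the planted bond list;
    ``island_id`` maps each particle to its component; ``island_class`` maps
    component id to 'compact' / 'elongated' / 'gas'; ``faces`` is the planted
    polygon census (vertex index cycles).
    """

    points: np.ndarray
    orientations: np.ndarray
    bonds: list[tuple[int, int]]
    island_id: np.ndarray
    island_class: dict[int, str]
    faces: list[tuple[int, ...]] = field(default_factory=list)
    lattice_nm: float = DEFAULT_LATTICE_NM

    @property
    def n_particles(self) -> int:
        return len(self.points)

    def face_sizes(self) -> list[int]:
        return [len(f) for f in self.faces]

    def points_df(self):
        import pandas as pd

        return pd.DataFrame({
            "frame": 0,
            "x_nm": self.points[:, 0],
            "y_nm": self.points[:, 1],
        })


@dataclass
class AFMImage:
    """Synthetic raster height image (nm) with provenance."""

    height: np.ndarray
    pixel_nm: float
    field_nm: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.height = np.asarray(self.height, dtype=np.float32)
        if not np.all(np.isfinite(self.height)):
            raise ValueError("non-finite heights")

    def to_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(path, self.height.astype(np.float32),
                         metadata={"pixel_nm": self.pixel_nm})

    def to_png(self, path) -> None:
        import imageio.v3 as iio

        h = self.height
        lo, hi = float(h.min()), float(h.max())
        scale = (h - lo) / (hi - lo) if hi > lo else np.zeros_like(h)
        iio.imwrite(path, (255 * scale).astype(np.uint8))

    @staticmethod
    def from_tiff(path, pixel_nm: Optional[float] = None) -> "AFMImage":
        import tifffile

        arr = tifffile.imread(path).astype(np.float32)
        if pixel_nm is None:
            pixel_nm = 750.0 / arr.shape[0]
        return AFMImage(arr, pixel_nm, pixel_nm * arr.shape[0])


# ---------------------------------------------------------------------------
# compact honeycomb islands grown face by face

_MERGE_TOL = 0.35
_CLASH_TOL = 0.7


class _FaceBuilder:
    """Grows a planar polygon patch by attaching regular k-gons to boundary
    edges; coincident corners merge, so hexagons reproduce the exact
    honeycomb and planted 5/7-gons introduce local curvature that a spring
    relaxation later absorbs."""

    def __init__(self) -> None:
        self.pts: list[np.ndarray] = []
        self.bonds: set[tuple[int, int]] = set()
        self.faces: list[tuple[int, ...]] = []
        self.edge_faces: dict[tuple[int, int], int] = {}
        self.generation: list[int] = []  # per face

    def _find(self, p: np.ndarray) -> Optional[int]:
        for i, q in enumerate(self.pts):
            if abs(q[0] - p[0]) < _MERGE_TOL and abs(q[1] - p[1]) < _MERGE_TOL:
                if np.hypot(*(q - p)) < _MERGE_TOL:
                    return i
        return None

    def degree(self, i: int) -> int:
        return sum(1 for e in self.bonds if i in e)

    def add_face(self, verts_xy: list[np.ndarray], existing: list[Optional[int]],
                 gen: int) -> bool:
        idx: list[Optional[int]] = list(existing)
        new_positions = []
        for k, p in enumerate(verts_xy):
            if idx[k] is None:
                idx[k] = self._find(p)
            if idx[k] is None:
                new_positions.append((k, p))
        # clash check: genuinely new corners must stay clear of all points
        for _, p in new_positions:
            for q in self.pts:
                if np.hypot(*(q - p)) < _CLASH_TOL:
                    return False
        # degree check on the closed cycle
        deg_gain: dict[int, int] = {}
        kk = len(verts_xy)
        for a in range(kk):
            i, j = idx[a], idx[(a + 1) % kk]
            if i is not None and j is not None and \
                    tuple(sorted((i, j))) in self.bonds:
                continue
            for v in (i, j):
                if v is not None:
                    deg_gain[v] = deg_gain.get(v, 0) + 1
        for v, gain in deg_gain.items():
            if self.degree(v) + gain > 3:
                return False
        for k, p in new_positions:
            idx[k] = len(self.pts)
            self.pts.append(p)
        cycle = tuple(int(i) for i in idx)  # type: ignore[arg-type]
        for a in range(kk):
            e = tuple(sorted((cycle[a], cycle[(a + 1) % kk])))
            self.bonds.add(e)
            self.edge_faces[e] = self.edge_faces.get(e, 0) + 1
        self.faces.append(cycle)
        self.generation.append(gen)
        return True

    def boundary_edges(self) -> list[tuple[int, int]]:
        return [e for e, c in self.edge_faces.items() if c == 1]

    def face_centroid(self, e: tuple[int, int]) -> np.ndarray:
        """Centroid of the (single) face already adjacent to edge e."""
        u, v = e
        for f in self.faces:
            if u in f and v in f:
                return np.mean([self.pts[i] for i in f], axis=0)
        raise KeyError(e)


def _regular_polygon_on_edge(p_u: np.ndarray, p_v: np.ndarray, k: int,
                             other_centroid: np.ndarray) -> list[np.ndarray]:
    """Vertices of a regular k-gon sharing edge u->v, built on the side away
    from ``other_centroid``; returned as [u, w1, ..., w_{k-2}, v]."""
    d = p_v - p_u
    length = math.hypot(*d)
    mid = 0.5 * (p_u + p_v)
    n = np.array([-d[1], d[0]]) / length
    side = -1.0 if float(n @ (other_centroid - mid)) > 0 else 1.0
    apothem = 0.5 * length / math.tan(math.pi / k)
    radius = 0.5 * length / math.sin(math.pi / k)
    c = mid + side * apothem * n
    au = math.atan2(*(p_u - c)[::-1])
    av = math.atan2(*(p_v - c)[::-1])
    step = (av - au + math.pi) % TWO_PI - math.pi  # +-2pi/k
    pts = [p_u.copy()]
    for i in range(1, k - 1):
        a = au - step * i
        pts.append(c + radius * np.array([math.cos(a), math.sin(a)]))
    pts.append(p_v.copy())
    return pts


def _relax_positions(pts: np.ndarray, bonds: list[tuple[int, int]],
                     n_iter: int = 400) -> np.ndarray:
    """Spring relaxation toward unit bond lengths with second-neighbour
    angular bracing and soft non-bonded repulsion."""
    from scipy.optimize import minimize

    n = len(pts)
    bonds_a = np.asarray(bonds, dtype=int).reshape(-1, 2)
    nbrs: dict[int, list[int]] = {i: [] for i in range(n)}
    for i, j in bonds_a:
        nbrs[int(i)].append(int(j))
        nbrs[int(j)].append(int(i))
    second = set()
    for v, ws in nbrs.items():
        for a in range(len(ws)):
            for b in range(a + 1, len(ws)):
                second.add(tuple(sorted((ws[a], ws[b]))))
    second_a = np.asarray(sorted(second), dtype=int).reshape(-1, 2)
    bondset = {tuple(sorted(map(int, e))) for e in bonds_a}
    target2 = math.sqrt(3.0)

    def energy_grad(flat):
        p = flat.reshape(n, 2)
        g = np.zeros_like(p)
        e = 0.0
        d = p[bonds_a[:, 1]] - p[bonds_a[:, 0]]
        r = np.hypot(d[:, 0], d[:, 1])
        e += np.sum((r - 1.0) ** 2)
        f = (2 * (r - 1.0) / np.maximum(r, 1e-9))[:, None] * d
        np.add.at(g, bonds_a[:, 1], f)
        np.add.at(g, bonds_a[:, 0], -f)
        if len(second_a):
            d2 = p[second_a[:, 1]] - p[second_a[:, 0]]
            r2 = np.hypot(d2[:, 0], d2[:, 1])
            e += 0.3 * np.sum((r2 - target2) ** 2)
            f2 = (0.6 * (r2 - target2) / np.maximum(r2, 1e-9))[:, None] * d2
            np.add.at(g, second_a[:, 1], f2)
            np.add.at(g, second_a[:, 0], -f2)
        # repulsion between non-bonded pairs closer than the bond cutoff,
        # so a 1.25x-lattice distance criterion recovers exactly the
        # planted bonds
        from scipy.spatial import cKDTree

        tree = cKDTree(p)
        for i, j in tree.query_pairs(1.32):
            key = tuple(sorted((int(i), int(j))))
            if key in bondset or key in second:
                continue
            dv = p[j] - p[i]
            r_ = max(np.hypot(*dv), 1e-9)
            e += 2.0 * (1.32 - r_) ** 2
            fv = -4.0 * (1.32 - r_) / r_ * dv
            g[j] += fv
            g[i] -= fv
        return e, g.ravel()

    res = minimize(energy_grad, pts.ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": n_iter})
    return res.x.reshape(n, 2)


def _orientations_from_bonds(pts: np.ndarray, bonds: list[tuple[int, int]],
                             rng: np.random.Generator) -> np.ndarray:
    orient = rng.uniform(0.0, TWO_PI, size=len(pts))
    first: dict[int, float] = {}
    for i, j in bonds:
        d = pts[j] - pts[i]
        a = math.atan2(d[1], d[0])
        first.setdefault(i, a)
        first.setdefault(j, a + math.pi)
    for i, a in first.items():
        orient[i] = a % TWO_PI
    return orient


def make_compact_island(
    n_rings: Optional[int] = None,
    n_particles: Optional[int] = None,
    defect_rates: tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
    lattice_nm: float = DEFAULT_LATTICE_NM,
) -> SyntheticField:
    """Honeycomb island grown ring by ring with planted 5/7-gon defects.

    ``defect_rates = (p5, p7)`` are per-face insertion probabilities (each in
    [0, 0.3]).  ``n_rings=2`` with zero rates yields the 24-particle flower
    of 7 hexagons.  Infeasible defect insertions (corner clashes, degree
    overflow) are skipped and logged.  Positions of defective islands are
    spring-relaxed so bond lengths stay within ~10% of the lattice constant.
    """
    p5, p7 = defect_rates
    if not (0 <= p5 <= 0.3 and 0 <= p7 <= 0.3):
        raise ValueError("defect rates must lie in [0, 0.3]")
    if n_rings is None and n_particles is None:
        raise ValueError("give n_rings or n_particles")
    if (n_rings is not None and n_rings < 1) or \
            (n_particles is not None and n_particles < 1):
        raise ValueError("island size must be >= 1")
    rng = np.random.default_rng(seed)

    def roll_k() -> int:
        u = rng.random()
        if u < p5:
            return 5
        if u < p5 + p7:
            return 7
        return 6

    b = _FaceBuilder()
    # seed face
    k0 = roll_k()
    r0 = 0.5 / math.sin(math.pi / k0)
    seed_pts = [np.array([r0 * math.cos(TWO_PI * t / k0 + math.pi / k0),
                          r0 * math.sin(TWO_PI * t / k0 + math.pi / k0)])
                for t in range(k0)]
    b.add_face(seed_pts, [None] * k0, gen=1)

    def done() -> bool:
        return n_particles is not None and len(b.pts) >= n_particles

    target_rings = n_rings if n_rings is not None else 10_000
    gen = 1
    while gen < target_rings and not done():
        gen += 1
        edges = b.boundary_edges()
        # spiral order: by angle of edge midpoint around the island centroid
        cen = np.mean(b.pts, axis=0)
        edges.sort(key=lambda e: math.atan2(
            *(0.5 * (b.pts[e[0]] + b.pts[e[1]]) - cen)[::-1]))
        progress = False
        for e in edges:
            if done():
                break
            if b.edge_faces.get(e, 0) != 1:
                continue
            k = roll_k()
            u, v = e
            other = b.face_centroid(e)
            verts = _regular_polygon_on_edge(b.pts[u], b.pts[v], k, other)
            existing: list[Optional[int]] = [u] + [None] * (k - 2) + [v]
            if b.add_face(verts, existing, gen):
                progress = True
            elif k != 6:
                log.info("defect insertion infeasible at edge %s; skipped", e)
                if b.add_face(_regular_polygon_on_edge(b.pts[u], b.pts[v], 6, other),
                              [u] + [None] * 4 + [v], gen):
                    progress = True
        if not progress:
            break

    pts = np.array(b.pts)
    bonds = sorted(b.bonds)
    if any(len(f) != 6 for f in b.faces):
        pts = _relax_positions(pts, bonds)
    orient = _orientations_from_bonds(pts, bonds, rng)
    n = len(pts)
    # final census: the actual interior faces of the planted geometry — the
    # constructed faces plus any ring that closed around a skipped insertion
    from .morphology import Island

    from .morphology import enumerate_faces as _faces

    isl = Island(nodes=list(range(n)), edges=bonds,
                 coords={i: (float(pts[i, 0]), float(pts[i, 1]))
                         for i in range(n)},
                 embed_edges=list(bonds))
    census = list(_faces(isl).faces)
    return SyntheticField(
        points=pts * lattice_nm,
        orientations=orient,
        bonds=bonds,
        island_id=np.zeros(n, dtype=int),
        island_class={0: "compact"},
        faces=census,
        lattice_nm=lattice_nm,
    )


# ---------------------------------------------------------------------------
# elongated chain assemblies

_HEX_DIRS_A = [0.5 * math.pi + k * TWO_PI / 3 for k in range(3)]


def _honeycomb_neighbours(site: tuple[int, int, int]) -> list[tuple[int, int, int]]:
    """Neighbours on the honeycomb lattice in (i, j, sublattice) coords."""
    i, j, s = site
    if s == 0:
        return [(i, j, 1), (i - 1, j, 1), (i, j - 1, 1)]
    return [(i, j, 0), (i + 1, j, 0), (i, j + 1, 0)]


def _site_xy(site: tuple[int, int, int]) -> np.ndarray:
    i, j, s = site
    a1 = np.array([math.sqrt(3.0), 0.0])
    a2 = np.array([math.sqrt(3.0) / 2.0, 1.5])
    base = i * a1 + j * a2
    if s == 1:
        base = base + np.array([math.sqrt(3.0) / 2.0, 0.5])
    return base


def make_elongated_island(
    n_particles: int,
    branch_prob: float = 0.0,
    seed: int = 0,
    lattice_nm: float = DEFAULT_LATTICE_NM,
    max_restarts: int = 50,
) -> SyntheticField:
    """Elongated assembly: neighbour-avoiding walk on the honeycomb lattice.

    The walk never steps next to previously laid monomers (other than its
    predecessor), so the planted graph is a tree — few or no closed polygons
    — and a distance-cutoff bond graph recovers exactly the planted bonds.
    With ``branch_prob`` each laid monomer may later seed a side branch.
    """
    if n_particles < 2:
        raise ValueError("need at least 2 particles")
    if not 0 <= branch_prob <= 0.3:
        raise ValueError("branch_prob must lie in [0, 0.3]")
    rng = np.random.default_rng(seed)

    for _restart in range(max_restarts):
        start = (0, 0, 0)
        placed = {start: 0}
        order = [start]
        bonds: list[tuple[int, int]] = []
        branch_from: list[tuple[int, int, int]] = []
        cur = start

        def candidates(site):
            out = []
            for nb in _honeycomb_neighbours(site):
                if nb in placed:
                    continue
                clash = any(w in placed and w != site
                            for w in _honeycomb_neighbours(nb))
                if not clash:
                    out.append(nb)
            return out

        ok = True
        while len(order) < n_particles:
            cands = candidates(cur)
            if not cands:
                # resume from a recorded branch point, if any
                while branch_from:
                    k = rng.integers(len(branch_from))
                    site = branch_from.pop(int(k))
                    if candidates(site):
                        cur = site
                        cands = candidates(cur)
                        break
                if not cands:
                    ok = False
                    break
            nb = cands[int(rng.integers(len(cands)))]
            placed[nb] = len(order)
            bonds.append((placed[cur], placed[nb]))
            order.append(nb)
            if branch_prob > 0 and rng.random() < branch_prob:
                branch_from.append(nb)
            cur = nb
        if ok:
            break
    else:
        raise RuntimeError("could not grow elongated island; lower n or branch_prob")

    pts = np.array([_site_xy(s) for s in order])
    orient = _orientations_from_bonds(pts, bonds, rng)
    n = len(pts)
    return SyntheticField(
        points=pts * lattice_nm,
        orientations=orient,
        bonds=sorted(tuple(sorted(e)) for e in bonds),
        island_id=np.zeros(n, dtype=int),
        island_class={0: "elongated"},
        faces=[],
        lattice_nm=lattice_nm,
    )


def make_gas(
    n_particles: int,
    field_nm: float = 750.0,
    seed: int = 0,
    lattice_nm: float = DEFAULT_LATTICE_NM,
) -> SyntheticField:
    """Dilute monomer gas: isolated particles, minimum spacing 2 lattice units."""
    rng = np.random.default_rng(seed)
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < n_particles:
        cand = rng.uniform(0.1 * field_nm, 0.9 * field_nm, size=2)
        if all(np.hypot(*(cand - q)) >= 2 * lattice_nm for q in pts):
            pts.append(cand)
        attempts += 1
        if attempts > 500 * n_particles:
            raise RuntimeError("gas placement failed; enlarge the field")
    arr = np.array(pts).reshape(-1, 2)
    return SyntheticField(
        points=arr,
        orientations=rng.uniform(0, TWO_PI, size=len(arr)),
        bonds=[],
        island_id=np.arange(len(arr)),
        island_class={i: "gas" for i in range(len(arr))},
        faces=[],
        lattice_nm=lattice_nm,
    )


def make_field(
    components: list[SyntheticField],
    field_nm: float = 750.0,
    seed: int = 0,
    margin_nm: Optional[float] = None,
    max_attempts: int = 400,
) -> SyntheticField:
    """Place components in a square field with random rotations, no overlap.

    Components are rejection-placed (bounding-circle pre-check, then
    point-to-point minimum distance of ``margin_nm``, default 1.5 lattice
    constants).  Raises when the components cannot be packed.
    """
    rng = np.random.default_rng(seed)
    if not components:
        return SyntheticField(points=np.empty((0, 2)),
                              orientations=np.empty(0), bonds=[],
                              island_id=np.empty(0, dtype=int),
                              island_class={}, faces=[],
                              lattice_nm=DEFAULT_LATTICE_NM)
    lattice = components[0].lattice_nm
    if margin_nm is None:
        margin_nm = 1.5 * lattice
    all_pts: list[np.ndarray] = []
    all_orient: list[np.ndarray] = []
    bonds: list[tuple[int, int]] = []
    island_id: list[np.ndarray] = []
    island_class: dict[int, str] = {}
    faces: list[tuple[int, ...]] = []
    offset = 0
    next_island = 0
    placed_pts = np.empty((0, 2))
    for comp in components:
        pts0 = comp.points - comp.points.mean(axis=0)
        rad = float(np.max(np.hypot(pts0[:, 0], pts0[:, 1]))) if len(pts0) else 0.0
        done = False
        for _ in range(max_attempts):
            ang = rng.uniform(0, TWO_PI)
            c, s_ = math.cos(ang), math.sin(ang)
            rot = pts0 @ np.array([[c, s_], [-s_, c]])
            lo = rad + margin_nm
            if 2 * lo >= field_nm:
                break
            centre = rng.uniform(lo, field_nm - lo, size=2)
            cand = rot + centre
            if len(placed_pts):
                from scipy.spatial import cKDTree

                d, _ = cKDTree(placed_pts).query(cand, k=1)
                if np.min(d) < margin_nm:
                    continue
            all_pts.append(cand)
            all_orient.append((comp.orientations + ang) % TWO_PI)
            bonds.extend((i + offset, j + offset) for i, j in comp.bonds)
            remap = {}
            for old, cls in comp.island_class.items():
                remap[old] = next_island
                island_class[next_island] = cls
                next_island += 1
            island_id.append(np.array([remap[int(k)] for k in comp.island_id]))
            faces.extend(tuple(v + offset for v in f) for f in comp.faces)
            offset += len(cand)
            placed_pts = np.vstack([placed_pts, cand]) if len(placed_pts) else cand
            done = True
            break
        if not done:
            raise RuntimeError(
                "could not place all components; use a larger field")
    return SyntheticField(
        points=np.vstack(all_pts),
        orientations=np.concatenate(all_orient),
        bonds=bonds,
        island_id=np.concatenate(island_id).astype(int),
        island_class=island_class,
        faces=faces,
        lattice_nm=lattice,
    )


# ---------------------------------------------------------------------------
# rasterization

def rasterize(
    fld: SyntheticField,
    pixels: int = 256,
    field_nm: float = 750.0,
    height_nm: float = 2.0,
    noise_sd: float = 0.1,
    line_offset_sd: float = 0.2,
    seed: int = 0,
    arm_len_nm: Optional[float] = None,
    ridge_w_nm: Optional[float] = None,
) -> AFMImage:
    """Render monomers as three-armed Gaussian-ridge stars on a height grid.

    Arms follow the planted bond directions (half the bond each, so bonded
    ridges join); monomers with fewer than three bonds complete their arms at
    120-degree spacing.  Heights combine by maximum (AFM reads the top
    surface); Gaussian pixel noise and per-scan-line offsets are then added.
    """
    rng = np.random.default_rng(seed)
    px = field_nm / pixels
    lattice = fld.lattice_nm
    if arm_len_nm is None:
        arm_len_nm = lattice / 2.0
    if ridge_w_nm is None:
        # tip convolution broadens ~2 nm DNA ridges to several nm in AFM
        ridge_w_nm = lattice / 4.0
    if px > lattice / 2.0:
        log.warning("pixel size %.2f nm coarser than half the lattice "
                    "constant; centres unresolvable", px)
    img = np.zeros((pixels, pixels), dtype=np.float64)

    arm_dirs: dict[int, list[float]] = {i: [] for i in range(fld.n_particles)}
    for i, j in fld.bonds:
        d = fld.points[j] - fld.points[i]
        a = math.atan2(d[1], d[0])
        arm_dirs[i].append(a)
        arm_dirs[j].append(a + math.pi)
    for i in range(fld.n_particles):
        dirs = arm_dirs[i]
        if not dirs:
            base = float(fld.orientations[i])
            arm_dirs[i] = [base + k * TWO_PI / 3 for k in range(3)]
        elif len(dirs) < 3:
            base = dirs[0]
            for k in (1, 2):
                cand = base + k * TWO_PI / 3
                if all(abs((cand - d + math.pi) % TWO_PI - math.pi) > 0.3
                       for d in dirs):
                    dirs.append(cand)

    half_w = int(math.ceil((arm_len_nm + 3 * ridge_w_nm) / px)) + 1
    for i in range(fld.n_particles):
        cx, cy = fld.points[i]
        col0 = int(cx / px)
        row0 = int(cy / px)
        rows = np.arange(max(0, row0 - half_w), min(pixels, row0 + half_w + 1))
        cols = np.arange(max(0, col0 - half_w), min(pixels, col0 + half_w + 1))
        if not len(rows) or not len(cols):
            continue
        gx = (cols[None, :] + 0.5) * px - cx
        gy = (rows[:, None] + 0.5) * px - cy
        for a in arm_dirs[i]:
            ex, ey = math.cos(a), math.sin(a)
            t = np.clip(gx * ex + gy * ey, 0.0, arm_len_nm)
            d2 = (gx - t * ex) ** 2 + (gy - t * ey) ** 2
            h = height_nm * np.exp(-d2 / (2 * ridge_w_nm**2))
            sub = img[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
            np.maximum(sub, h, out=sub)

    if line_offset_sd > 0:
        img += rng.normal(0.0, line_offset_sd, size=(pixels, 1))
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=img.shape)
    return AFMImage(
        height=img.astype(np.float32),
        pixel_nm=px,
        field_nm=field_nm,
        provenance={
            "seed": seed, "pixels": pixels, "field_nm": field_nm,
            "height_nm": height_nm, "noise_sd": noise_sd,
            "line_offset_sd": line_offset_sd, "lattice_nm": lattice,
            "arm_len_nm": arm_len_nm, "ridge_w_nm": ridge_w_nm,
        },
    )
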
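"""Combinatorial construction of icosahedral capsid bond networks.

A Caspar-Klug capsid architecture is indexed by a pair of non-negative
integers (h, k) through the triangulation number ``T = h^2 + hk + k^2``.
The *deltahedron* of a T-capsid is the icosahedral triangulation with
``10T + 2`` vertices, ``30T`` edges and ``20T`` triangular facets obtained
by subdividing each face of the icosahedron with the (h, k) patch of the
triangular lattice.  The three homogeneous capsid tilings give rise to
three intersubunit bond networks derived from that triangulation:

* triangular tiling -- one trivalent tile per facet (face-adjacency graph),
* rhombic tiling    -- one tetravalent tile per edge (medial graph),
* kite tiling       -- 60 tetravalent tiles at T=3 (vertex-face incidences
  of the icosahedron).

Everything here is exact integer combinatorics.  Faces of the icosahedron
are charts in the triangular lattice, expressed in Eisenstein coordinates
``(u, v) == u + v*omega`` with ``omega = exp(i*pi/3)``; the planar net of
the icosahedron places all 20 charts in one plane and the cut edges of the
net are glued by exact lattice isometries (rotations by multiples of 60
degrees plus translations).  No floating point is involved, so the
construction is deterministic and tolerance-free.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "TilingSpec",
    "Triangulation",
    "CapsidGraph",
    "ValidationReport",
    "build_deltahedron",
    "triangular_network",
    "rhombic_network",
    "kite_network_t3",
    "capsid_network",
    "validate_network",
    "SUPPORTED_FAMILIES",
]

SUPPORTED_FAMILIES = ("triangular", "rhombic", "kite")

#: Expected tile count, valency and contact count per family, as functions of T.
FAMILY_COUNTS = {
    "triangular": (lambda T: 20 * T, 3, lambda T: 30 * T),
    "rhombic": (lambda T: 30 * T, 4, lambda T: 60 * T),
    "kite": (lambda T: 60, 4, lambda T: 120),
}


# ---------------------------------------------------------------------------
# TilingSpec
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TilingSpec:
    """Designation of a capsid architecture: family plus lattice indices.

    ``(h, k)`` and ``(k, h)`` describe enantiomeric (mirror) lattices whose
    bond networks are isomorphic, so the pair is canonicalised to ``h >= k``
    and the indices as given are kept in ``h_given``/``k_given``.
    """

    family: str
    h: int
    k: int = 0
    h_given: int = field(default=None, compare=False)  # type: ignore[assignment]
    k_given: int = field(default=None, compare=False)  # type: ignore[assignment]

    def __post_init__(self):
        if self.family not in SUPPORTED_FAMILIES:
            raise ValueError(
                f"unknown tiling family {self.family!r}; "
                f"expected one of {SUPPORTED_FAMILIES}"
            )
        h, k = self.h, self.k
        if not (isinstance(h, int) and isinstance(k, int)):
            raise ValueError("lattice indices h, k must be integers")
        if h < 0 or k < 0:
            raise ValueError(f"lattice indices must be non-negative, got (h, k)=({h}, {k})")
        if h == 0 and k == 0:
            raise ValueError("lattice indices h and k must not both be zero")
        object.__setattr__(self, "h_given", h)
        object.__setattr__(self, "k_given", k)
        if h < k:  # enantiomer: canonicalise silently
            object.__setattr__(self, "h", k)
            object.__setattr__(self, "k", h)
        if self.family == "kite" and self.T != 3:
            raise ValueError(
                f"the kite tiling is only defined here for T=3; got T={self.T} "
                f"from (h, k)=({h}, {k})"
            )

    @property
    def T(self) -> int:
        """Triangulation number ``T = h^2 + hk + k^2``."""
        return self.h * self.h + self.h * self.k + self.k * self.k


# ---------------------------------------------------------------------------
# Eisenstein-lattice helpers (all integer)
# ---------------------------------------------------------------------------

def _emul(a: int, b: int, h: int, k: int) -> tuple[int, int]:
    """Eisenstein product ``(a + b*omega) * (h + k*omega)``."""
    # omega^2 = omega - 1
    return (a * h - b * k, a * k + b * h + b * k)


def _rot60(p: tuple[int, int]) -> tuple[int, int]:
    """Rotate by +60 degrees about the origin: multiplication by omega."""
    return (-p[1], p[0] + p[1])


def _cross(a: tuple[int, int], b: tuple[int, int]) -> int:
    return a[0] * b[1] - a[1] * b[0]


class _Isometry:
    """Orientation-preserving lattice isometry ``p -> R60^n p + t``."""

    __slots__ = ("n", "t")

    def __init__(self, n: int, t: tuple[int, int]):
        self.n = n % 6
        self.t = t

    def __call__(self, p: tuple[int, int]) -> tuple[int, int]:
        for _ in range(self.n):
            p = _rot60(p)
        return (p[0] + self.t[0], p[1] + self.t[1])

    def inverse(self) -> "_Isometry":
        q = (-self.t[0], -self.t[1])
        for _ in range((-self.n) % 6):
            q = _rot60(q)
        return _Isometry(-self.n, q)

    def compose(self, other: "_Isometry") -> "_Isometry":
        """self after other: ``p -> self(other(p))``."""
        return _Isometry(self.n + other.n, self(other.t))

    @staticmethod
    def from_edge_match(
        a: tuple[int, int], b: tuple[int, int],
        a2: tuple[int, int], b2: tuple[int, int],
    ) -> "_Isometry":
        """The unique rotation+translation with ``a2 -> a`` and ``b2 -> b``."""
        d = (b[0] - a[0], b[1] - a[1])
        d2 = (b2[0] - a2[0], b2[1] - a2[1])
        for n in range(6):
            if d2 == d:
                ra = a2
                for _ in range(n):
                    ra = _rot60(ra)
                return _Isometry(n, (a[0] - ra[0], a[1] - ra[1]))
            d2 = _rot60(d2)
        raise ValueError("edge vectors are not related by a lattice rotation")


def _in_closed_triangle(p, c0, c1, c2) -> bool:
    """Exact point-in-closed-triangle test in lattice coordinates."""
    s0 = _cross((c1[0] - c0[0], c1[1] - c0[1]), (p[0] - c0[0], p[1] - c0[1]))
    s1 = _cross((c2[0] - c1[0], c2[1] - c1[1]), (p[0] - c1[0], p[1] - c1[1]))
    s2 = _cross((c0[0] - c2[0], c0[1] - c2[1]), (p[0] - c2[0], p[1] - c2[1]))
    return (s0 >= 0 and s1 >= 0 and s2 >= 0) or (s0 <= 0 and s1 <= 0 and s2 <= 0)


def _seg_in_triangle(p, q, c0, c1, c2) -> bool:
    """True when segment ``p->q`` overlaps the closed triangle in a set of
    positive length (exact rational arithmetic).

    Only such overlaps licence developing the lattice edge from this chart:
    the development of a surface edge is single-valued along any stretch
    that actually lies in the chart, whereas a touch at a single point (a
    chart corner, i.e. a cone point of the glued surface) does not identify
    a surface edge at all.
    """
    from fractions import Fraction

    if _cross((c1[0] - c0[0], c1[1] - c0[1]), (c2[0] - c0[0], c2[1] - c0[1])) < 0:
        c1, c2 = c2, c1
    lo, hi = Fraction(0), Fraction(1)
    for a, b in ((c0, c1), (c1, c2), (c2, c0)):
        n = (b[0] - a[0], b[1] - a[1])
        sp = _cross(n, (p[0] - a[0], p[1] - a[1]))
        sq = _cross(n, (q[0] - a[0], q[1] - a[1]))
        d = sq - sp
        if d == 0:
            if sp < 0:
                return False
        elif d > 0:
            lo = max(lo, Fraction(-sp, d))
        else:
            hi = min(hi, Fraction(-sp, d))
    return lo < hi


# ---------------------------------------------------------------------------
# Icosahedron net: 20 charts in one plane
# ---------------------------------------------------------------------------
# Abstract icosahedron vertices: north pole "N", south pole "S", upper rim
# U0..U4, lower rim L0..L4.  The planar net is the classic strip: five top
# triangles, a middle band of ten, five bottom triangles.  Unit-scale chart
# corner coordinates; the whole net is scaled by h + k*omega.

def _ico_net():
    faces = []  # list of dict: ico vertex id -> unit chart coordinate
    U = [f"U{i}" for i in range(5)]
    L = [f"L{i}" for i in range(5)]
    for i in range(5):
        j = (i + 1) % 5
        faces.append({U[i]: (i, 1), U[j]: (i + 1, 1), "N": (i, 2)})        # top_i
        faces.append({L[i]: (i, 0), L[j]: (i + 1, 0), U[i]: (i, 1)})       # up_i
        faces.append({L[j]: (i + 1, 0), U[i]: (i, 1), U[j]: (i + 1, 1)})   # down_i
        faces.append({L[i]: (i, 0), L[j]: (i + 1, 0), "S": (i + 1, -1)})   # bot_i
    return faces


class _UnionFind:
    def __init__(self):
        self.parent = {}

    def find(self, x):
        p = self.parent
        if x not in p:
            p[x] = x
            return x
        root = x
        while p[root] != root:
            root = p[root]
        while p[x] != root:
            p[x], x = root, p[x]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


# ---------------------------------------------------------------------------
# Triangulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Triangulation:
    """Icosahedral deltahedron: the (h, k) geodesic triangulation.

    Vertices are integers ``0..10T+1``; ``edges`` are sorted vertex pairs and
    ``faces`` sorted vertex triples.
    """

    T: int
    n_vertices: int
    edges: frozenset
    faces: frozenset

    def degree_census(self) -> dict[int, int]:
        deg: dict[int, int] = {}
        counts: dict[int, int] = {}
        for a, b in self.edges:
            deg[a] = deg.get(a, 0) + 1
            deg[b] = deg.get(b, 0) + 1
        for d in deg.values():
            counts[d] = counts.get(d, 0) + 1
        return counts


_UNIT_DIRS = ((1, 0), (0, 1), (-1, 1), (-1, 0), (0, -1), (1, -1))


def build_deltahedron(spec: TilingSpec) -> Triangulation:
    """Build the icosahedral triangulation for ``T(h, k)``.

    Each icosahedron face is a chart holding the lattice points of its
    scaled triangle; points shared between charts (on glued edges and at
    the twelve 5-fold corners) are identified by union-find through exact
    lattice isometries.  The result satisfies ``V = 10T + 2``, ``E = 30T``,
    ``F = 20T``, with exactly twelve degree-5 vertices.
    """
    h, k = spec.h, spec.k
    T = spec.T
    net = _ico_net()
    n_faces = len(net)

    # Scaled chart corners, per face, keyed by abstract ico vertex id.
    corners = [
        {vid: _emul(c[0], c[1], h, k) for vid, c in f.items()} for f in net
    ]
    tris = [tuple(c.values()) for c in corners]

    # Adjacency: faces sharing two abstract ico vertices; gluing isometry
    # maps the neighbour's chart into this face's extended chart, matching
    # the shared capsid edge endpoint-for-endpoint.
    glue: dict[tuple[int, int], _Isometry] = {}
    neighbours: dict[int, list[int]] = {i: [] for i in range(n_faces)}
    for i, j in itertools.combinations(range(n_faces), 2):
        shared = sorted(set(net[i]) & set(net[j]))
        if len(shared) != 2:
            continue
        a_id, b_id = shared
        iso = _Isometry.from_edge_match(
            corners[i][a_id], corners[i][b_id],
            corners[j][a_id], corners[j][b_id],
        )
        glue[(i, j)] = iso
        glue[(j, i)] = iso.inverse()
        neighbours[i].append(j)
        neighbours[j].append(i)

    # Lattice points of each closed chart triangle.
    points: list[set[tuple[int, int]]] = []
    for i in range(n_faces):
        c0, c1, c2 = tris[i]
        umin = min(c0[0], c1[0], c2[0])
        umax = max(c0[0], c1[0], c2[0])
        vmin = min(c0[1], c1[1], c2[1])
        vmax = max(c0[1], c1[1], c2[1])
        pts = set()
        for u in range(umin, umax + 1):
            for v in range(vmin, vmax + 1):
                if _in_closed_triangle((u, v), c0, c1, c2):
                    pts.add((u, v))
        points.append(pts)

    # Identify points shared by edge-adjacent charts.
    uf = _UnionFind()
    for i in range(n_faces):
        for p in points[i]:
            uf.find((i, p))
    for (i, j), iso in glue.items():
        inv = iso.inverse()
        for p in points[i]:
            q = inv(p)
            if q in points[j]:
                uf.union((i, p), (j, q))

    # Candidate unfoldings for resolving lattice neighbours that fall off a
    # chart: the chart itself, its three edge neighbours, and for each
    # corner the two second-ring wedges reached by going around that corner.
    candidates: list[list[tuple[int, _Isometry]]] = []
    for i in range(n_faces):
        cand: list[tuple[int, _Isometry]] = [(i, _Isometry(0, (0, 0)))]
        for j in neighbours[i]:
            cand.append((j, glue[(i, j)]))
        for vid in net[i]:
            wedge = [j for j in neighbours[i] if vid in net[j]]
            for j in wedge:
                nxt = [
                    m for m in neighbours[j]
                    if vid in net[m] and m != i
                ]
                for m in nxt:
                    cand.append((m, glue[(i, j)].compose(glue[(j, m)])))
        candidates.append(cand)

    def resolve(i: int, q: tuple[int, int]):
        """Capsid vertex (union-find root) of lattice point q seen from chart i."""
        root = None
        for j, iso in candidates[i]:
            qj = iso.inverse()(q)
            if qj in points[j]:
                r = uf.find((j, qj))
                if root is None:
                    root = r
                elif r != root:
                    raise AssertionError(
                        f"inconsistent chart resolution for point {q} of chart {i}"
                    )
        if root is None:
            raise AssertionError(f"lattice point {q} of chart {i} not on any chart")
        return root

    # Global vertex ids: deterministic order by canonical class representative.
    classes: dict = {}
    for i in range(n_faces):
        for p in points[i]:
            r = uf.find((i, p))
            key = (i, p)
            if r not in classes or key < classes[r]:
                classes[r] = key
    order = sorted(classes.values())
    vid_of_root = {uf.find(key): n for n, key in enumerate(order)}

    def gid(i, q):
        return vid_of_root[resolve(i, q)]

    # Edges: a lattice edge is developed from chart i exactly when its
    # segment overlaps the chart triangle in positive length; anchors range
    # over the chart's bounding box dilated by one lattice step so that
    # edges crossing a chart without containing a chart-owned endpoint are
    # still found.
    edges = set()
    for i in range(n_faces):
        c0, c1, c2 = tris[i]
        umin = min(c0[0], c1[0], c2[0]) - 1
        umax = max(c0[0], c1[0], c2[0]) + 1
        vmin = min(c0[1], c1[1], c2[1]) - 1
        vmax = max(c0[1], c1[1], c2[1]) + 1
        for u in range(umin, umax + 1):
            for v in range(vmin, vmax + 1):
                p = (u, v)
                for d in ((1, 0), (0, 1), (-1, 1)):
                    q = (u + d[0], v + d[1])
                    if _seg_in_triangle(p, q, c0, c1, c2):
                        a, b = gid(i, p), gid(i, q)
                        edges.add((a, b) if a < b else (b, a))

    # Facets: in a geodesic triangulation every 3-clique of the skeleton
    # bounds a facet, so the facet list is the triangle census of the
    # edge graph (audited below against the 20T closed form).
    adj: dict[int, set[int]] = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    faces = set()
    for a, b in edges:
        for c in adj[a] & adj[b]:
            faces.add(tuple(sorted((a, b, c))))

    n_vertices = len(order)
    tri = Triangulation(
        T=T, n_vertices=n_vertices, edges=frozenset(edges), faces=frozenset(faces)
    )
    _audit_triangulation(tri)
    return tri


def _audit_triangulation(tri: Triangulation) -> None:
    T = tri.T
    if tri.n_vertices != 10 * T + 2:
        raise AssertionError(
            f"vertex count {tri.n_vertices} != 10T+2 = {10 * T + 2}"
        )
    if len(tri.edges) != 30 * T:
        raise AssertionError(f"edge count {len(tri.edges)} != 30T = {30 * T}")
    if len(tri.faces) != 20 * T:
        raise AssertionError(f"face count {len(tri.faces)} != 20T = {20 * T}")
    census = tri.degree_census()
    if census.get(5, 0) != 12 or census.get(6, 0) != 10 * T + 2 - 12 or len(
        set(census) - {5, 6}
    ):
        raise AssertionError(f"unexpected degree census {census}")
    # every edge bounds exactly two faces
    edge_faces: dict[tuple[int, int], int] = {}
    for f in tri.faces:
        for a, b in itertools.combinations(sorted(f), 2):
            edge_faces[(a, b)] = edge_faces.get((a, b), 0) + 1
    if set(edge_faces) != set(tri.edges) or any(
        c != 2 for c in edge_faces.values()
    ):
        raise AssertionError("edge/face incidence is not 2-regular")


# ---------------------------------------------------------------------------
# CapsidGraph and the three bond networks
# ---------------------------------------------------------------------------

@dataclass
class CapsidGraph:
    """Bond network of a capsid tiling: one vertex per tile, one edge per
    intertile contact.

    Tile labels are canonical: triangular tiles carry their facet index,
    rhombic tiles the sorted endpoint pair of the underlying triangulation
    edge, kite tiles the (icosahedron vertex, facet index) incidence pair.
    """

    graph: nx.Graph
    family: str
    T: int
    k0: int
    h: int | None = None
    k: int | None = None
    h_given: int | None = None
    k_given: int | None = None

    @property
    def n_tiles(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_contacts(self) -> int:
        return self.graph.number_of_edges()

    def describe(self) -> str:
        return (
            f"{self.family} T={self.T}: {self.n_tiles} tiles, "
            f"{self.n_contacts} contacts, valency {self.k0}"
        )


def triangular_network(tri: Triangulation) -> CapsidGraph:
    """Face-adjacency graph of the deltahedron: the triangular-tiling
    bond network (20T trivalent tiles, 30T contacts)."""
    faces = sorted(tri.faces)
    face_index = {f: n for n, f in enumerate(faces)}
    edge_faces: dict[tuple[int, int], list[int]] = {}
    for f in faces:
        for a, b in itertools.combinations(f, 2):
            edge_faces.setdefault((a, b), []).append(face_index[f])
    g = nx.Graph()
    g.add_nodes_from(range(len(faces)))
    for pair in edge_faces.values():
        if len(pair) != 2:
            raise AssertionError("triangulation edge not shared by two faces")
        g.add_edge(*pair)
    return CapsidGraph(graph=g, family="triangular", T=tri.T, k0=3)


def rhombic_network(tri: Triangulation) -> CapsidGraph:
    """Medial graph of the deltahedron: the rhombic-tiling bond network
    (30T tetravalent tiles sitting on the triangulation edges, 60T
    contacts -- two edges are in contact when they bound a common facet)."""
    g = nx.Graph()
    g.add_nodes_from(sorted(tri.edges))
    for f in tri.faces:
        a, b, c = sorted(f)
        e1, e2, e3 = (a, b), (a, c), (b, c)
        g.add_edge(e1, e2)
        g.add_edge(e1, e3)
        g.add_edge(e2, e3)
    return CapsidGraph(graph=g, family="rhombic", T=tri.T, k0=4)


def kite_network_t3() -> CapsidGraph:
    """Bond network of the T=3 kite tiling.

    One tile per (vertex, face) incidence of the icosahedron (12 x 5 = 60
    tiles).  Tiles (v, F) and (v', F') are in contact when they belong to
    the same facet (F == F', v != v') or share the icosahedron vertex with
    their facets adjacent across an edge through it.  4-regular with 120
    contacts.
    """
    ico = build_deltahedron(TilingSpec("triangular", 1, 0))
    faces = sorted(ico.faces)
    g = nx.Graph()
    tiles = [(v, fi) for fi, f in enumerate(faces) for v in sorted(f)]
    g.add_nodes_from(sorted(tiles))
    # same-face contacts
    for fi, f in enumerate(faces):
        for v, w in itertools.combinations(sorted(f), 2):
            g.add_edge((v, fi), (w, fi))
    # same-vertex contacts across an edge through that vertex
    edge_faces: dict[tuple[int, int], list[int]] = {}
    for fi, f in enumerate(faces):
        for a, b in itertools.combinations(f, 2):
            edge_faces.setdefault((a, b), []).append(fi)
    for (a, b), (f1, f2) in edge_faces.items():
        g.add_edge((a, f1), (a, f2))
        g.add_edge((b, f1), (b, f2))
    return CapsidGraph(graph=g, family="kite", T=3, k0=4)


def capsid_network(spec: TilingSpec) -> CapsidGraph:
    """Build the bond network for a :class:`TilingSpec` (any family)."""
    if spec.family == "kite":
        g = kite_network_t3()
    else:
        tri = build_deltahedron(spec)
        g = triangular_network(tri) if spec.family == "triangular" else rhombic_network(tri)
    g.h, g.k = spec.h, spec.k
    g.h_given, g.k_given = spec.h_given, spec.k_given
    return g


# ---------------------------------------------------------------------------
# Validation report
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    checks: list  # (name, passed, detail)

    @property
    def ok(self) -> bool:
        return all(passed for _, passed, _ in self.checks)

    def __str__(self) -> str:
        lines = []
        for name, passed, detail in self.checks:
            mark = "PASS" if passed else "FAIL"
            lines.append(f"[{mark}] {name}: {detail}")
        return "\n".join(lines)


def validate_network(g: CapsidGraph) -> ValidationReport:
    """Check every CapsidGraph invariant, reporting the first
    counterexample for each failed check."""
    checks = []
    nv_fn, k0, ne_fn = FAMILY_COUNTS[g.family]
    nv, ne = nv_fn(g.T), ne_fn(g.T)

    checks.append((
        "tile count", g.n_tiles == nv,
        f"expected {nv}, found {g.n_tiles}",
    ))
    checks.append((
        "contact count", g.n_contacts == ne,
        f"expected {ne}, found {g.n_contacts}",
    ))

    bad = [(n, d) for n, d in g.graph.degree() if d != k0]
    checks.append((
        "regularity", not bad,
        f"all tiles have valency {k0}" if not bad
        else f"deficient tiles (first two): {bad[:2]}",
    ))

    loops = list(nx.selfloop_edges(g.graph))
    checks.append((
        "simplicity", not loops,
        "no loops or multi-edges" if not loops else f"self-loop at {loops[0]}",
    ))

    connected = g.n_tiles > 0 and nx.is_connected(g.graph)
    detail = "single connected component"
    if not connected and g.n_tiles:
        comp = min(nx.connected_components(g.graph), key=len)
        detail = f"disconnected; smallest component {sorted(comp)[:5]}..."
    checks.append(("connectivity", connected, detail))

    return ValidationReport(checks=checks)
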
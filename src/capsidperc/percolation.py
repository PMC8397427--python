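"""Monte Carlo site and bond percolation on capsid bond networks.

The removal ensemble is "exactly i elements, uniformly without
replacement" -- the perforated-capsid ensemble G_i^v (vertex mode) or
G_j^e (bond mode) -- rather than independent Bernoulli thinning.  The
connectivity criterion is strict: every surviving subunit must lie in one
connected component, so a dissociated singlet already counts as
fragmentation.  In bond mode all subunits are retained, hence an isolated
subunit means the capsid has fragmented.  States with at most one
surviving vertex are connected by convention (far from any threshold, but
fixed for determinism).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from . import _kernels
from .tilings import CapsidGraph

__all__ = [
    "RemovalSpec",
    "PerforatedState",
    "PercolationResult",
    "graph_arrays",
    "sample_removal",
    "is_fully_connected",
    "estimate_pcon",
    "pcon_curve",
    "enumerate_pcon_exact",
    "mean_edge_fraction_mc",
    "EnumerationCapExceeded",
]

MODES = ("vertex", "bond")


def _as_nx(g) -> nx.Graph:
    return g.graph if isinstance(g, CapsidGraph) else g


def graph_arrays(g) -> tuple[np.ndarray, np.ndarray, int]:
    """Flatten a graph to (edge_u, edge_v, n_vertices) int32 arrays under
    the canonical (sorted-label) vertex indexing used by all kernels."""
    G = _as_nx(g)
    nodes = sorted(G.nodes())
    idx = {n: i for i, n in enumerate(nodes)}
    m = G.number_of_edges()
    eu = np.empty(m, np.int32)
    ev = np.empty(m, np.int32)
    for e, (a, b) in enumerate(sorted((min(idx[a], idx[b]), max(idx[a], idx[b]))
                                      for a, b in G.edges())):
        eu[e] = a
        ev[e] = b
    return eu, ev, len(nodes)


@dataclass(frozen=True)
class RemovalSpec:
    """How many elements of which kind to delete from a network."""

    mode: str
    count: int

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.count < 0:
            raise ValueError(f"removal count must be non-negative, got {self.count}")

    def total_elements(self, g) -> int:
        G = _as_nx(g)
        return G.number_of_nodes() if self.mode == "vertex" else G.number_of_edges()

    def validate_range(self, g) -> None:
        total = self.total_elements(g)
        if self.count > total:
            kind = "vertices" if self.mode == "vertex" else "edges"
            raise ValueError(
                f"cannot remove {self.count} {kind} from a graph with {total}"
            )

    def fraction_removed(self, g) -> float:
        """f_v^d = i/V0 (vertex mode) or f_e^d = j/E0 (bond mode)."""
        return self.count / self.total_elements(g)


@dataclass(frozen=True)
class PerforatedState:
    """A partially disassembled network: the surviving element sets."""

    mode: str
    removed: frozenset
    surviving_vertices: frozenset
    surviving_edges: frozenset


def sample_removal(g, spec: RemovalSpec, rng: np.random.Generator) -> PerforatedState:
    """Remove exactly ``spec.count`` elements uniformly at random without
    replacement.  Vertex mode takes each vertex with its incident edges;
    bond mode removes edges only and keeps every vertex."""
    G = _as_nx(g)
    spec.validate_range(g)
    if spec.mode == "vertex":
        nodes = sorted(G.nodes())
        removed = frozenset(
            nodes[i] for i in rng.choice(len(nodes), size=spec.count, replace=False)
        )
        surv_v = frozenset(n for n in nodes if n not in removed)
        surv_e = frozenset(
            (a, b) for a, b in G.edges() if a not in removed and b not in removed
        )
    else:
        edges = sorted(tuple(sorted(e, key=repr)) for e in G.edges())
        removed = frozenset(
            edges[i] for i in rng.choice(len(edges), size=spec.count, replace=False)
        )
        surv_v = frozenset(G.nodes())
        surv_e = frozenset(e for e in edges if e not in removed)
    return PerforatedState(
        mode=spec.mode, removed=removed,
        surviving_vertices=surv_v, surviving_edges=surv_e,
    )


def is_fully_connected(state: PerforatedState) -> bool:
    """True when every surviving vertex lies in a single connected
    component.  Uses networkx's traversal-based component count, which is
    deliberately independent of the union-find used in the MC kernels
    (the two are cross-checked in the test suite)."""
    if len(state.surviving_vertices) <= 1:
        return True
    H = nx.Graph()
    H.add_nodes_from(state.surviving_vertices)
    H.add_edges_from(state.surviving_edges)
    return nx.number_connected_components(H) == 1


# ---------------------------------------------------------------------------
# Monte Carlo estimation
# ---------------------------------------------------------------------------

def _kernel_seed(master_seed: int, salt: int = 0) -> int:
    """Derive a 31-bit kernel seed from a master seed."""
    s = np.random.SeedSequence([int(master_seed), int(salt)])
    return int(s.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)


def estimate_pcon(g, spec: RemovalSpec, replicates: int, seed: int) -> tuple[float, float]:
    """Monte Carlo estimate of P_con with its binomial standard error.

    Reproducible: identical (graph, spec, replicates, seed) give
    bit-identical results.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    spec.validate_range(g)
    eu, ev, n = graph_arrays(g)
    kseed = _kernel_seed(seed, spec.count)
    kern = _kernels.pcon_vertex if spec.mode == "vertex" else _kernels.pcon_bond
    hits = kern(eu, ev, n, spec.count, replicates, kseed)
    p = hits / replicates
    se = math.sqrt(p * (1.0 - p) / replicates)
    return p, se


@dataclass
class PercolationResult:
    """P_con estimates over a grid of removal counts."""

    mode: str
    counts: np.ndarray
    pcon: np.ndarray
    se: np.ndarray
    replicates: int
    seed: int
    n_elements: int          # V0 (vertex mode) or E0 (bond mode)
    n_vertices: int
    family: str | None = None
    T: int | None = None

    @property
    def fractions(self) -> np.ndarray:
        """Deleted fractions f_v^d = i/V0 or f_e^d = j/E0."""
        return self.counts / self.n_elements

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "count": self.counts,
            "fraction_removed": self.fractions,
            "pcon": self.pcon,
            "se": self.se,
            "reps": np.full(len(self.counts), self.replicates),
        })


def pcon_curve(g, mode: str, grid, replicates: int, seed: int,
               family: str | None = None, T: int | None = None) -> PercolationResult:
    """Estimate P_con at every removal count in ``grid`` (strictly
    increasing), with an independent RNG substream per grid point so the
    curve does not depend on evaluation order."""
    grid = np.asarray(list(grid), dtype=np.int64)
    if len(grid) == 0:
        raise ValueError("grid must be non-empty")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    if isinstance(g, CapsidGraph):
        family = family or g.family
        T = T or g.T
    pcon = np.empty(len(grid))
    se = np.empty(len(grid))
    n_el = RemovalSpec(mode, 0).total_elements(g)
    G = _as_nx(g)
    for idx, c in enumerate(grid):
        spec = RemovalSpec(mode, int(c))
        spec.validate_range(g)
        if c == 0:
            # exact by definition for a connected graph
            pcon[idx] = 1.0 if nx.is_connected(G) else 0.0
            se[idx] = 0.0
        else:
            pcon[idx], se[idx] = estimate_pcon(g, spec, replicates, seed)
    return PercolationResult(
        mode=mode, counts=grid, pcon=pcon, se=se, replicates=replicates,
        seed=seed, n_elements=n_el, n_vertices=G.number_of_nodes(),
        family=family, T=T,
    )


# ---------------------------------------------------------------------------
# Exhaustive enumeration oracle
# ---------------------------------------------------------------------------

class EnumerationCapExceeded(ValueError):
    pass


def enumerate_pcon_exact(g, spec: RemovalSpec, cap: int = 2_000_000) -> float:
    """Exact P_con by enumerating every removal subset.

    Brute-force ground truth for small graphs; refuses to enumerate more
    than ``cap`` subsets.
    """
    G = _as_nx(g)
    spec.validate_range(g)
    total = spec.total_elements(g)
    n_subsets = math.comb(total, spec.count)
    if n_subsets > cap:
        raise EnumerationCapExceeded(
            f"C({total}, {spec.count}) = {n_subsets} subsets exceeds the "
            f"enumeration cap {cap}; use Monte Carlo estimation instead"
        )
    eu, ev, n = graph_arrays(g)
    m = len(eu)
    hits = 0
    if spec.mode == "vertex":
        for subset in itertools.combinations(range(n), spec.count):
            removed = np.zeros(n, bool)
            removed[list(subset)] = True
            keep = ~(removed[eu] | removed[ev])
            hits += _connected(eu[keep], ev[keep], np.flatnonzero(~removed))
    else:
        all_e = np.arange(m)
        for subset in itertools.combinations(range(m), spec.count):
            keep = np.setdiff1d(all_e, subset, assume_unique=True)
            hits += _connected(eu[keep], ev[keep], np.arange(n))
    return hits / n_subsets


def _connected(eu, ev, vertices) -> bool:
    """Union-find connectivity of the given vertex set under the given
    edges (<=1 vertex counts as connected)."""
    if len(vertices) <= 1:
        return True
    parent = {int(v): int(v) for v in vertices}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in zip(eu, ev):
        ra, rb = find(int(a)), find(int(b))
        if ra != rb:
            parent[ra] = rb
    roots = {find(int(v)) for v in vertices}
    return len(roots) == 1


def mean_edge_fraction_mc(g, count: int, replicates: int, seed: int) -> tuple[float, float]:
    """Monte Carlo mean (and SE of the mean) of the surviving-edge
    fraction after removing exactly ``count`` vertices uniformly.
    Validation companion to the closed-form hypergeometric expectation."""
    eu, ev, n = graph_arrays(g)
    rng = np.random.default_rng(seed)
    ranks = np.argsort(rng.random((replicates, n)), axis=1)
    removed = ranks < count
    surv = ~(removed[:, eu] | removed[:, ev])
    frac = surv.mean(axis=1)
    return float(frac.mean()), float(frac.std(ddof=1) / math.sqrt(replicates))
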
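"""Reference graphs with closed-form percolation behaviour.

Every stochastic operation in this package is testable against exact
ground truth at small scale: these fixtures have either a documented
closed-form P_con or a state space small enough for exhaustive
enumeration (:func:`capsidperc.percolation.enumerate_pcon_exact`).

Closed forms (vertex mode removes exactly i vertices; bond mode exactly
j edges; <=1 surviving vertex counts as connected):

* cycle C_n:    survivors are connected iff the removed vertices form one
  consecutive arc; there are n such arcs of length i for 1 <= i <= n-1,
  so P_con = n / C(n, i).  Bond mode: one removed edge leaves a path,
  two or more split the cycle, so P_con = 1 for j <= 1 else 0.
* path P_n:     survivors connected iff the removed set is a prefix plus
  a suffix, i.e. the survivors form one contiguous block: (i+1)/C(n, i).
  Bond mode: every edge is a bridge, so P_con = 0 for any j >= 1.
* star S_n (hub + n leaves): connected iff the hub survives, or at most
  one vertex survives at all: P_con = [C(n, i) + C(n, i-1) if i >= n] /
  C(n+1, i).  Bond mode: every edge is a bridge.
* complete K_n: any induced subgraph is complete, P_con = 1 in vertex
  mode.  No closed form is catalogued for bond mode.
* icosahedron / dodecahedron skeletons: no closed form; enumeration only.
"""

from __future__ import annotations

import math

import networkx as nx

__all__ = ["FIXTURE_NAMES", "make_fixture", "closed_form_pcon"]

FIXTURE_NAMES = ("cycle", "path", "star", "complete", "icosahedron", "dodecahedron")

_BOUNDS = {"cycle": (3, 1000), "path": (2, 1000), "star": (2, 1000),
           "complete": (2, 100)}


def make_fixture(name: str, n: int | None = None) -> nx.Graph:
    """Deterministic construction of a named fixture graph with canonical
    integer labels.  ``n`` is required for the parametric families and
    ignored for the platonic skeletons."""
    if name not in FIXTURE_NAMES:
        raise ValueError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    if name == "icosahedron":
        return nx.icosahedral_graph()
    if name == "dodecahedron":
        return nx.dodecahedral_graph()
    if n is None:
        raise ValueError(f"fixture {name!r} requires a size n")
    lo, hi = _BOUNDS[name]
    if not lo <= n <= hi:
        raise ValueError(f"fixture {name!r} supports {lo} <= n <= {hi}, got {n}")
    if name == "cycle":
        return nx.cycle_graph(n)
    if name == "path":
        return nx.path_graph(n)
    if name == "star":
        return nx.star_graph(n)  # hub 0 plus n leaves
    return nx.complete_graph(n)


def closed_form_pcon(name: str, n: int | None, mode: str, count: int) -> float | None:
    """Exact P_con where a closed form is catalogued, else None.

    Boundary conventions match the simulator: count 0 leaves a connected
    fixture connected; removing all (or all but one) vertices leaves a
    state that is connected by convention.
    """
    g = make_fixture(name, n)
    V = g.number_of_nodes()
    E = g.number_of_edges()
    total = V if mode == "vertex" else E
    if not 0 <= count <= total:
        raise ValueError(f"count {count} outside 0..{total}")
    if count == 0:
        return 1.0

    if mode == "vertex":
        i = count
        if V - i <= 1:
            return 1.0
        if name == "complete":
            return 1.0
        if name == "cycle":
            return V / math.comb(V, i)
        if name == "path":
            return (i + 1) / math.comb(V, i)
        if name == "star":
            # hub survives: C(n, i) removal sets among the n leaves
            return math.comb(V - 1, i) / math.comb(V, i)
        return None

    j = count
    if name in ("path", "star"):
        return 0.0 if j >= 1 else 1.0
    if name == "cycle":
        return 1.0 if j <= 1 else 0.0
    return None
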
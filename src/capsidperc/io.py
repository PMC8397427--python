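"""Readers and writers: edge lists, GraphML, CSV/JSON result files.

Tile labels serialise canonically: integers as decimal strings, pair
labels (rhombic edge tiles, kite incidence tiles) as ``a-b``.  Both
formats round-trip losslessly for networks built by this package.
Floating point in result files is printed at six significant digits for
diffability; every stochastic output embeds the seed and replicate count
that produced it.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np

from .percolation import PercolationResult
from .thresholds import FragmentDistribution, ThresholdEstimate
from .tilings import FAMILY_COUNTS, CapsidGraph

__all__ = [
    "GraphFormatError",
    "write_graph",
    "read_graph",
    "write_edgelist",
    "read_edgelist",
    "write_graphml",
    "read_graphml",
    "write_results",
    "provenance",
]

TOOL = "capsidperc"


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("capsidperc")
    except Exception:
        return "unknown"


def provenance(**params) -> dict:
    """Provenance block embedded in result files: tool version, timestamp
    and the full parameter echo."""
    import datetime

    return {
        "tool": TOOL,
        "version": _version(),
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "parameters": params,
    }


class GraphFormatError(ValueError):
    pass


def _format_label(label) -> str:
    if isinstance(label, tuple):
        return "-".join(str(x) for x in label)
    return str(label)


def _parse_label(s: str):
    if "-" in s:
        parts = s.split("-")
        if all(p.lstrip("+").isdigit() for p in parts):
            return tuple(int(p) for p in parts)
        return s
    if s.lstrip("+-").isdigit():
        return int(s)
    return s


def _graph_meta(g) -> dict:
    if isinstance(g, CapsidGraph):
        meta = {"family": g.family, "T": g.T, "k0": g.k0}
        if g.h is not None:
            meta["h"] = g.h
            meta["k"] = g.k
        return meta
    return {}


def _rebuild(G: nx.Graph, meta: dict):
    if {"family", "T"} <= set(meta) and meta["family"] in FAMILY_COUNTS:
        return CapsidGraph(
            graph=G, family=meta["family"], T=int(meta["T"]),
            k0=int(meta.get("k0", FAMILY_COUNTS[meta["family"]][1])),
            h=int(meta["h"]) if "h" in meta else None,
            k=int(meta["k"]) if "k" in meta else None,
        )
    return G


# ---------------------------------------------------------------------------
# Edge list
# ---------------------------------------------------------------------------

def write_edgelist(g, path) -> None:
    """Tab-separated edge list, one contact per line, '#'-prefixed header
    comments carrying the network metadata."""
    G = g.graph if isinstance(g, CapsidGraph) else g
    meta = _graph_meta(g)
    lines = [f"# {TOOL} edge list"]
    for key, value in meta.items():
        lines.append(f"# {key}={value}")
    lines.append(f"# vertices={G.number_of_nodes()} edges={G.number_of_edges()}")
    edges = sorted(
        tuple(sorted((_format_label(a), _format_label(b)))) for a, b in G.edges()
    )
    isolated = sorted(
        _format_label(n) for n in G.nodes() if G.degree(n) == 0
    )
    for n in isolated:
        lines.append(f"# isolated={n}")
    lines.extend(f"{a}\t{b}" for a, b in edges)
    Path(path).write_text("\n".join(lines) + "\n")


def read_edgelist(path):
    """Read an edge list written by :func:`write_edgelist` (or any
    two-column tab/space-separated file with '#' comments).  Loops and
    duplicate edges are rejected with the offending line number."""
    G = nx.Graph()
    meta = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body and " " not in body.split("=", 1)[0]:
                key, _, value = body.partition("=")
                if key == "isolated":
                    G.add_node(_parse_label(value))
                else:
                    meta[key] = value
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise GraphFormatError(
                f"{path}:{lineno}: expected two tile labels, got {raw!r}"
            )
        a, b = _parse_label(parts[0]), _parse_label(parts[1])
        if a == b:
            raise GraphFormatError(f"{path}:{lineno}: self-loop {raw!r}")
        if G.has_edge(a, b):
            raise GraphFormatError(f"{path}:{lineno}: duplicate edge {raw!r}")
        G.add_edge(a, b)
    return _rebuild(G, meta)


# ---------------------------------------------------------------------------
# GraphML
# ---------------------------------------------------------------------------

def write_graphml(g, path) -> None:
    G = g.graph if isinstance(g, CapsidGraph) else g
    H = nx.relabel_nodes(G, _format_label, copy=True)
    for key, value in _graph_meta(g).items():
        H.graph[key] = value
    nx.write_graphml(H, path)


def read_graphml(path):
    H = nx.read_graphml(path)
    if H.is_multigraph() or any(True for _ in nx.selfloop_edges(H)):
        raise GraphFormatError(f"{path}: loops/multi-edges are not allowed")
    G = nx.Graph()
    G.add_nodes_from(_parse_label(n) for n in H.nodes())
    for a, b in H.edges():
        pa, pb = _parse_label(a), _parse_label(b)
        if G.has_edge(pa, pb):
            raise GraphFormatError(f"{path}: duplicate edge {a!r}-{b!r}")
        G.add_edge(pa, pb)
    return _rebuild(G, dict(H.graph))


def write_graph(g, path, format: str = "edgelist") -> None:
    if format == "edgelist":
        write_edgelist(g, path)
    elif format == "graphml":
        write_graphml(g, path)
    else:
        raise ValueError(f"unknown graph format {format!r}")


def read_graph(path, format: str | None = None):
    if format is None:
        format = "graphml" if str(path).endswith(".graphml") else "edgelist"
    if format == "edgelist":
        return read_edgelist(path)
    if format == "graphml":
        return read_graphml(path)
    raise ValueError(f"unknown graph format {format!r}")


# ---------------------------------------------------------------------------
# Result files
# ---------------------------------------------------------------------------

def _fmt(x) -> str:
    if isinstance(x, (float, np.floating)):
        return f"{x:.6g}"
    return str(x)


def _write_csv(path, header_comments, columns, rows) -> None:
    lines = [f"# {c}" for c in header_comments]
    lines.append(",".join(columns))
    for row in rows:
        lines.append(",".join(_fmt(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def write_results(result, path, format: str | None = None) -> None:
    """Write a PercolationResult, ThresholdEstimate, FragmentDistribution
    or comparison DataFrame to CSV or JSON."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix == ".json" else "csv"

    if isinstance(result, PercolationResult):
        if format == "json":
            payload = {
                "mode": result.mode,
                "n_elements": result.n_elements,
                "seed": result.seed,
                "replicates": result.replicates,
                "family": result.family,
                "T": result.T,
                "count": [int(c) for c in result.counts],
                "fraction_removed": [round(float(f), 9) for f in result.fractions],
                "pcon": [round(float(p), 9) for p in result.pcon],
                "se": [round(float(s), 9) for s in result.se],
            }
            path.write_text(json.dumps(payload, indent=1) + "\n")
        else:
            _write_csv(
                path,
                [f"P_con curve mode={result.mode} family={result.family} "
                 f"T={result.T} seed={result.seed} reps={result.replicates}"],
                ["count", "fraction_removed", "pcon", "se", "reps"],
                [(int(c), f, p, s, result.replicates)
                 for c, f, p, s in zip(result.counts, result.fractions,
                                       result.pcon, result.se)],
            )
    elif isinstance(result, ThresholdEstimate):
        payload = {
            "mode": result.mode,
            "symbol": result.symbol,
            "threshold": round(result.threshold, 9),
            "se": round(result.se, 9),
            "bracket": [result.i_low, result.i_high],
            "n_elements": result.n_elements,
            "replicates": result.replicates,
            "seed": result.seed,
            "family": result.family,
            "T": result.T,
        }
        path.write_text(json.dumps(payload, indent=1) + "\n")
    elif isinstance(result, FragmentDistribution):
        _write_csv(
            path,
            [f"fragment size distribution mode={result.mode} "
             f"family={result.family} T={result.T} f={_fmt(result.mean_fraction)} "
             f"sd={result.sd_fraction} seed={result.seed} "
             f"reps={result.replicates}"],
            ["size", "pdf", "cdf"],
            [(int(s), p, c)
             for s, p, c in zip(result.sizes, result.pdf, result.cdf)],
        )
    else:  # pandas DataFrame (family comparison table)
        import pandas as pd

        if not isinstance(result, pd.DataFrame):
            raise TypeError(f"cannot serialise result of type {type(result)!r}")
        cols = list(result.columns)
        _write_csv(path, ["family comparison table"], cols,
                   [tuple(row[c] for c in cols) for _, row in result.iterrows()])
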
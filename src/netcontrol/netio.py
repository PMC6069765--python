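"""Directed network data model and readers/writers.

The pipeline's in-memory container is :class:`DirectedNetwork`, a thin wrapper
around :class:`networkx.DiGraph` that fixes the conventions the controllability
core relies on:

* an edge ``(u, v)`` means *u influences v* — in the linear-system picture the
  state matrix entry ``A[v, u]`` is nonzero;
* parallel edges between the same ordered pair are collapsed to one edge, with
  interaction signs (activation / inhibition) retained as an annotation set;
* node identifiers are opaque, case-sensitive, non-empty strings.

Supported formats: whitespace/TSV edge lists, Cytoscape SIF, and directed
GraphML (the ``graph.xml`` output consumed by Cytoscape).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "DirectedNetwork",
    "NetworkParseError",
    "read_edge_list",
    "read_sif",
    "read_graphml",
    "write_graphml",
    "ACTIVATION",
    "INHIBITION",
]

ACTIVATION = "activation"
INHIBITION = "inhibition"

# SIF relation vocabulary interpreted as signed interactions; any other
# relation string is accepted but stored with sign "unknown".
_ACTIVATION_WORDS = {"activates", "activate", "activation", "promotes", "promote"}
_INHIBITION_WORDS = {"inhibits", "inhibit", "inhibition", "represses", "repress"}

_SIGN_SEP = "|"  # serialization of multi-sign annotations in GraphML


class NetworkParseError(ValueError):
    """Raised when a network file cannot be parsed."""


class DirectedNetwork:
    """A directed molecular interaction network.

    Parameters
    ----------
    nodes
        Iterable of node identifiers (non-empty strings).
    edges
        Iterable of ``(source, target)`` or ``(source, target, sign)`` tuples.
        Duplicate ordered pairs are collapsed; conflicting signs accumulate
        into a set.
    """

    def __init__(self, nodes: Iterable[str] = (), edges: Iterable[tuple] = ()):
        self._g = nx.DiGraph()
        for n in nodes:
            self.add_node(n)
        for e in edges:
            self.add_edge(*e)

    # -- construction -----------------------------------------------------

    def add_node(self, node: str, **attrs: str) -> None:
        if not isinstance(node, str) or not node:
            raise ValueError(f"node identifier must be a non-empty string, got {node!r}")
        self._g.add_node(node, **attrs)

    def add_edge(self, u: str, v: str, sign: str | None = None) -> None:
        self.add_node(u)
        self.add_node(v)
        if self._g.has_edge(u, v):
            if sign is not None:
                self._g.edges[u, v].setdefault("signs", set()).add(sign)
        else:
            self._g.add_edge(u, v, signs=set() if sign is None else {sign})

    # -- views -------------------------------------------------------------

    @property
    def graph(self) -> nx.DiGraph:
        """The underlying :class:`networkx.DiGraph` (shared, not a copy)."""
        return self._g

    @property
    def nodes(self) -> frozenset:
        return frozenset(self._g.nodes)

    @property
    def edges(self) -> frozenset:
        return frozenset(self._g.edges)

    @property
    def edge_sign(self) -> dict:
        """Map edge -> frozenset of sign annotations (may be empty)."""
        return {e: frozenset(d.get("signs", ())) for e, d in self._g.edges.items()}

    @property
    def node_attrs(self) -> dict:
        return {n: dict(d) for n, d in self._g.nodes(data=True)}

    def set_node_attr(self, node: str, key: str, value: str) -> None:
        if node not in self._g:
            raise KeyError(node)
        self._g.nodes[node][key] = value

    def in_neighbors(self, node: str) -> list:
        return sorted(self._g.predecessors(node))

    def number_of_nodes(self) -> int:
        return self._g.number_of_nodes()

    def number_of_edges(self) -> int:
        return self._g.number_of_edges()

    def __contains__(self, node: str) -> bool:
        return node in self._g

    def __eq__(self, other) -> bool:
        if not isinstance(other, DirectedNetwork):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.edges == other.edges
            and self.edge_sign == other.edge_sign
            and self.node_attrs == other.node_attrs
        )

    def __repr__(self) -> str:
        return (
            f"DirectedNetwork({self._g.number_of_nodes()} nodes, "
            f"{self._g.number_of_edges()} edges)"
        )


# -- file formats ----------------------------------------------------------


def read_edge_list(path, delimiter: str | None = None) -> DirectedNetwork:
    """Read a two/three-column edge list (source, target[, sign]).

    ``delimiter=None`` splits on any whitespace run (covers both space- and
    tab-separated tables). Duplicate rows are collapsed to one edge.
    """
    net = DirectedNetwork()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split(delimiter) if delimiter else line.split()
            fields = [f for f in fields if f]
            if len(fields) < 2:
                raise NetworkParseError(
                    f"{path}:{lineno}: expected at least 2 columns, got {len(fields)}"
                )
            sign = fields[2] if len(fields) >= 3 else None
            net.add_edge(fields[0], fields[1], sign=sign)
    if net.number_of_edges() == 0:
        raise NetworkParseError(f"{path}: no edges")
    return net


def _relation_sign(relation: str) -> str:
    rel = relation.lower()
    if rel in _ACTIVATION_WORDS:
        return ACTIVATION
    if rel in _INHIBITION_WORDS:
        return INHIBITION
    return "unknown"


def read_sif(path) -> DirectedNetwork:
    """Read a Cytoscape SIF file.

    Dialect: ``source relation target [target2 ...]`` separated by whitespace;
    a row with a single token adds an isolated node.  Relations matching an
    activation/inhibition vocabulary are stored as edge signs; anything else
    is kept with sign ``unknown``.
    """
    net = DirectedNetwork()
    n_rows = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            fields = [f.strip() for f in fields if f.strip()]
            n_rows += 1
            if len(fields) == 1:
                net.add_node(fields[0])
                continue
            if len(fields) == 2:
                raise NetworkParseError(
                    f"{path}:{lineno}: SIF row with a relation needs at least 3 columns"
                )
            source, relation, *targets = fields
            sign = _relation_sign(relation)
            for t in targets:
                net.add_edge(source, t, sign=sign)
    if n_rows == 0:
        raise NetworkParseError(f"{path}: no edges")
    return net


def write_graphml(net: DirectedNetwork, path) -> None:
    """Write a directed GraphML file with node attributes and edge signs.

    Sign sets are serialized as a ``|``-joined sorted string so the file
    round-trips losslessly through :func:`read_graphml`.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("refusing to write an empty network")
    g = nx.DiGraph()
    for n, attrs in net.node_attrs.items():
        g.add_node(n, **{str(k): str(v) for k, v in attrs.items()})
    for (u, v), signs in net.edge_sign.items():
        if signs:
            g.add_edge(u, v, sign=_SIGN_SEP.join(sorted(signs)))
        else:
            g.add_edge(u, v)
    nx.write_graphml(g, path, encoding="utf-8")


def read_graphml(path) -> DirectedNetwork:
    """Read a directed GraphML file written by :func:`write_graphml`.

    Undirected GraphML is rejected: edge direction is semantically load-bearing
    for controllability analysis.
    """
    g = nx.read_graphml(path)
    if not g.is_directed():
        raise NetworkParseError(
            f"{path}: GraphML declares an undirected graph; directed edges are required"
        )
    net = DirectedNetwork()
    for n, attrs in g.nodes(data=True):
        net.add_node(str(n), **{str(k): str(v) for k, v in attrs.items()})
    for u, v, attrs in g.edges(data=True):
        sign_field = attrs.get("sign")
        if sign_field:
            for s in str(sign_field).split(_SIGN_SEP):
                net.add_edge(str(u), str(v), sign=s)
        else:
            net.add_edge(str(u), str(v))
    return net
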
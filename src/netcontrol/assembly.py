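"""Gap-bounded network assembly and essentiality-based target selection.

Starting from a user-supplied seed protein list and a local interaction table,
the analysis network is grown by admitting every directed walk of at most
``gap + 1`` edges between seed nodes (equivalently: at most ``gap``
intermediate non-seed nodes).  Rather than enumerating walks explicitly, a
node ``u`` is admitted when ``dF(u) + dB(u) <= gap + 1``, where ``dF`` is the
shortest directed distance from any seed to ``u`` and ``dB`` the shortest
distance from ``u`` to any seed; an edge ``(u, v)`` is admitted when
``dF(u) + 1 + dB(v) <= gap + 1``.  Both criteria are exactly the union of all
bounded seed-to-seed walks, computed in polynomial time via multi-source BFS.

Target proteins are selected from cell-line essentiality screens: a protein is
kept when its GARP (Gene Activity Rank Profile) score is strictly negative and
its GARP p-value is strictly below 0.05 — more negative scores mark stronger
essentiality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .netio import DirectedNetwork

__all__ = [
    "InteractionTable",
    "AssemblyConfig",
    "GarpRecord",
    "load_interaction_table",
    "load_garp_table",
    "assemble_network",
    "select_essential_targets",
    "load_drug_targets",
]

MAX_GAP = 5


@dataclass(frozen=True)
class GarpRecord:
    """One (protein, cell line) essentiality measurement from an shRNA screen."""

    protein: str
    cell_line: str
    garp_score: float
    garp_p: float

    def __post_init__(self):
        if not 0.0 <= self.garp_p <= 1.0:
            raise ValueError(f"garp_p must be in [0, 1], got {self.garp_p}")


@dataclass
class InteractionTable:
    """A local stand-in for a pathway interaction store: directed signed edges."""

    rows: list = field(default_factory=list)  # (source, target, sign-or-None)

    def __post_init__(self):
        seen, dedup = set(), []
        for row in self.rows:
            source, target = row[0], row[1]
            sign = row[2] if len(row) > 2 else None
            if (source, target) not in seen:
                seen.add((source, target))
                dedup.append((source, target, sign))
        self.rows = dedup

    def as_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for source, target, sign in self.rows:
            g.add_edge(source, target, sign=sign)
        return g


@dataclass(frozen=True)
class AssemblyConfig:
    """Seed set plus the gap bound on intermediate nodes between seeds."""

    seeds: frozenset
    gap: int

    def __post_init__(self):
        if not self.seeds:
            raise ValueError("seed set must be non-empty")
        if not 0 <= self.gap <= MAX_GAP:
            raise ValueError(f"gap must be in [0, {MAX_GAP}], got {self.gap}")


def load_interaction_table(path) -> InteractionTable:
    """Load a TSV interaction table with columns source, target[, sign]."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = [f for f in line.replace("\t", " ").split() if f]
            if lineno == 1 and fields[:2] == ["source", "target"]:
                continue  # optional header
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected >=2 columns")
            rows.append(tuple(fields[:3]))
    return InteractionTable(rows)


def _multi_source_distances(g: nx.DiGraph, sources: Iterable[str]) -> dict:
    """Shortest directed distance (in edges) from the nearest source."""
    sources = [s for s in sources if s in g]
    if not sources:
        return {}
    return nx.multi_source_dijkstra_path_length(g, sources, weight=None)


def assemble_network(table: InteractionTable, config: AssemblyConfig) -> DirectedNetwork:
    """Grow the analysis network from seeds, bounded by the gap parameter.

    Every returned non-seed node and every edge lies on some directed
    seed-to-seed walk of at most ``gap + 1`` edges.  Seeds absent from the
    interaction table are kept as isolated nodes (with a warning) so that
    user-listed proteins are never silently dropped.  Nodes that lie on a
    bounded cycle through a single seed are flagged with the node attribute
    ``on_seed_cycle``.
    """
    g = table.as_digraph()
    seeds = set(config.seeds)
    bound = config.gap + 1

    missing = seeds - set(g.nodes)
    if missing:
        warnings.warn(
            f"seed nodes absent from the interaction table kept as isolated nodes: "
            f"{sorted(missing)}",
            stacklevel=2,
        )

    d_fwd = _multi_source_distances(g, seeds)  # nearest seed -> u
    d_bwd = _multi_source_distances(g.reverse(copy=False), seeds)  # u -> nearest seed
    for s in seeds:
        d_fwd[s] = 0
        d_bwd[s] = 0

    def df(u):
        return d_fwd.get(u, float("inf"))

    def db(u):
        return d_bwd.get(u, float("inf"))

    net = DirectedNetwork()
    for s in sorted(seeds):
        net.add_node(s, seed="true")
    for u in g.nodes:
        if u not in seeds and df(u) + db(u) <= bound:
            net.add_node(u)
    for u, v, attrs in g.edges(data=True):
        if df(u) + 1 + db(v) <= bound:
            net.add_edge(u, v, sign=attrs.get("sign"))

    # flag nodes reachable from and back to the *same* seed within the bound
    flagged = set()
    for s in sorted(seeds):
        if s not in g:
            continue
        fwd = nx.single_source_shortest_path_length(g, s, cutoff=bound)
        bwd = nx.single_source_shortest_path_length(g.reverse(copy=False), s, cutoff=bound)
        for u in net.nodes:
            if u != s and fwd.get(u, bound + 1) + bwd.get(u, bound + 1) <= bound:
                flagged.add(u)
    for u in flagged:
        net.set_node_attr(u, "on_seed_cycle", "true")

    return net


def select_essential_targets(
    records: Iterable[GarpRecord],
    cell_line: str,
    score_max: float = 0.0,
    p_max: float = 0.05,
) -> set:
    """Select essential proteins for one cell line by strict GARP thresholds.

    A protein qualifies when ``garp_score < score_max`` (default: strictly
    negative score) and ``garp_p < p_max``.  An unknown cell line yields an
    empty set with a warning, not an error.
    """
    records = list(records)
    matching = [r for r in records if r.cell_line == cell_line]
    if records and not matching:
        warnings.warn(f"no GARP records for cell line {cell_line!r}", stacklevel=2)
    return {r.protein for r in matching if r.garp_score < score_max and r.garp_p < p_max}


def load_garp_table(path) -> list:
    """Load a GARP score table (CSV/TSV with header: protein, cell_line,
    garp_score, garp_p)."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"protein", "cell_line", "garp_score", "garp_p"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        GarpRecord(str(r.protein), str(r.cell_line), float(r.garp_score), float(r.garp_p))
        for r in df.itertuples(index=False)
    ]


def load_drug_targets(path=None, extra: set | None = None) -> set:
    """Load drug-targetable protein IDs: one per line, unioned with ``extra``.

    FDA-approved drug targets and user-defined custom drug targets are treated
    identically downstream; the union is deduplicated.
    """
    if path is None and extra is None:
        raise ValueError("either a drug-target file or an extra set is required")
    ids = set()
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            for raw in fh:
                line = raw.strip()
                if line:
                    ids.add(line)
    if extra:
        ids |= set(extra)
    if not ids:
        warnings.warn("drug-target set is empty", stacklevel=2)
    return ids
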
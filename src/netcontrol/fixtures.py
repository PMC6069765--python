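"""In-package example networks and synthetic generators.

``fig3_network`` rebuilds the published ERBB/PI3K/AKT/MTOR worked example of
the pipeline; the random generators supply reproducible test instances with
either homogeneous (Erdős–Rényi) or heavy-tailed (preferential-attachment)
degree structure, the latter mimicking protein–protein interaction networks.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .netio import ACTIVATION, INHIBITION, DirectedNetwork

__all__ = ["Fig3Example", "fig3_network", "random_digraph", "random_scale_free_digraph"]

PIK3_PROTEINS = (
    "PIK3R3",
    "PIK3CB",
    "PIK3R1",
    "PIK3CG",
    "PIK3CD",
    "PIK3CA",
    "PIK3R5",
    "PIK3R2",
)


@dataclass(frozen=True)
class Fig3Example:
    """The breast-cancer worked example: network plus its run inputs."""

    network: DirectedNetwork
    seeds: frozenset
    targets: frozenset
    drug_targets: frozenset


def fig3_network() -> Fig3Example:
    """The ERBB3/PI3K/AKT/MTOR signaling network of the published example.

    14 nodes: NRG1 activates ERBB3; ERBB3 activates all eight PI3K subunits;
    each PI3K subunit activates AKT1, AKT2, AKT3 and MTOR and additionally
    inhibits AKT1–3 (the parallel activation+inhibition pairs collapse to one
    signed edge each); AKT1 activates MTOR; the PI3K subunits do not interact
    with each other.  Seeds are {AKT1, AKT3, NRG1, MTOR, ERBB3}; targets are
    the breast-cancer essential proteins {MTOR, ERBB3}; AKT1 is the
    drug-targetable node.
    """
    net = DirectedNetwork()
    net.add_edge("NRG1", "ERBB3", sign=ACTIVATION)
    for p in PIK3_PROTEINS:
        net.add_edge("ERBB3", p, sign=ACTIVATION)
        for akt in ("AKT1", "AKT2", "AKT3"):
            net.add_edge(p, akt, sign=ACTIVATION)
            net.add_edge(p, akt, sign=INHIBITION)
        net.add_edge(p, "MTOR", sign=ACTIVATION)
    net.add_edge("AKT1", "MTOR", sign=ACTIVATION)
    return Fig3Example(
        network=net,
        seeds=frozenset({"AKT1", "AKT3", "NRG1", "MTOR", "ERBB3"}),
        targets=frozenset({"MTOR", "ERBB3"}),
        drug_targets=frozenset({"AKT1"}),
    )


def random_digraph(n: int, edge_prob: float, rng_seed: int = 0) -> DirectedNetwork:
    """Erdős–Rényi directed graph G(n, p) without self-loops or parallel edges."""
    rng = np.random.default_rng(rng_seed)
    names = [f"n{i}" for i in range(n)]
    net = DirectedNetwork(nodes=names)
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < edge_prob:
                net.add_edge(names[i], names[j])
    return net


def random_scale_free_digraph(n: int, rng_seed: int = 0) -> DirectedNetwork:
    """Preferential-attachment directed graph with heavy-tailed degrees.

    Wraps :func:`networkx.scale_free_graph`, collapsing parallel edges and
    dropping self-loops; node degrees are far more heterogeneous than an
    Erdős–Rényi graph of the same density, as in real interaction networks.
    """
    g = nx.scale_free_graph(n, seed=int(rng_seed))
    net = DirectedNetwork(nodes=[f"n{i}" for i in range(n)])
    for u, v in g.edges():
        if u != v:
            net.add_edge(f"n{u}", f"n{v}")
    return net
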
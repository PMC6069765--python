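"""Node-role classification and the pipeline's output bundle.

The run result is delivered as a zip archive with five members, mirroring the
original web pipeline's downloads:

* ``driven.csv``  — drug-targetable driven nodes and how many targets each controls;
* ``extra.csv``   — non-drug-targetable driven nodes, same columns;
* ``details.txt`` — heuristic name, driven-node list, and the control paths;
* ``graph.xml``   — the analyzed network as GraphML with a per-node role attribute;
* ``graph.pdf``   — a network rendering colored by role.

Roles follow the published five-way coloring: driven roles take precedence
over controlled roles, which take precedence over the plain seed role.
"""

from __future__ import annotations

import csv
import io
import zipfile
from pathlib import Path

from .control import ControlSolution
from .netio import DirectedNetwork, write_graphml

__all__ = [
    "ROLES",
    "ROLE_COLORS",
    "classify_nodes",
    "write_driven_csv",
    "write_extra_csv",
    "write_details_txt",
    "render_network_pdf",
    "bundle_output",
]

ROLES = (
    "seed",
    "driven_drug_target",
    "controlled_from_drug_target",
    "driven_non_drug_target",
    "controlled_from_non_drug_target",
    "other",
)

# colors follow the published legend: seeds green, drug-targetable driven
# nodes aqua, their controlled targets purple, non-drug driven nodes red,
# their controlled targets orange-yellow
ROLE_COLORS = {
    "seed": "#2ca02c",
    "driven_drug_target": "#00ffff",
    "controlled_from_drug_target": "#9467bd",
    "driven_non_drug_target": "#d62728",
    "controlled_from_non_drug_target": "#ffbf00",
    "other": "#d9d9d9",
}

BUNDLE_MEMBERS = ("driven.csv", "extra.csv", "details.txt", "graph.xml", "graph.pdf")


def classify_nodes(
    net: DirectedNetwork,
    solution: ControlSolution,
    seeds,
    drug_targets,
) -> dict:
    """Assign each network node exactly one role for output coloring.

    Precedence: driven (drug / non-drug) > controlled (by the drug status of
    the driven node its path starts at) > seed > other.  A node that is both a
    seed and driven is therefore reported as driven.
    """
    seeds = set(seeds)
    drug_targets = set(drug_targets)
    roles = {}
    for t, p in solution.paths.items():
        if p.start in drug_targets:
            roles[t] = "controlled_from_drug_target"
        else:
            roles[t] = "controlled_from_non_drug_target"
    for d in solution.driven:
        roles[d] = "driven_drug_target" if d in drug_targets else "driven_non_drug_target"
    for node in net.nodes:
        if node not in roles:
            roles[node] = "seed" if node in seeds else "other"
    return roles


def _write_count_csv(solution: ControlSolution, keep, path) -> None:
    counts = solution.targets_controlled
    rows = [(d, counts[d]) for d in solution.driven if keep(d)]
    rows.sort(key=lambda r: (-r[1], r[0]))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["driven_node", "targets_controlled"])
        writer.writerows(rows)


def write_driven_csv(solution: ControlSolution, drug_targets, path) -> None:
    """Write the drug-targetable driven nodes with their target counts.

    Header-only when no driven node is drug-targetable."""
    drug_targets = set(drug_targets)
    _write_count_csv(solution, lambda d: d in drug_targets, path)


def write_extra_csv(solution: ControlSolution, drug_targets, path) -> None:
    """Write the non-drug-targetable driven nodes with their target counts."""
    drug_targets = set(drug_targets)
    _write_count_csv(solution, lambda d: d not in drug_targets, path)


def write_details_txt(solution: ControlSolution, path) -> None:
    """Write the run details: heuristic name, driven nodes, control paths.

    Layout: the heuristic name on line 1; a blank line; one driven node per
    line (sorted); a blank line; one rendered control path per line.
    """
    assert solution.driven or not solution.paths, "non-empty targets need driven nodes"
    lines = [solution.heuristic_name, ""]
    lines.extend(sorted(solution.driven))
    lines.append("")
    lines.extend(solution.paths[t].render() for t in sorted(solution.paths))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def render_network_pdf(net: DirectedNetwork, roles: dict, path, layout_seed: int = 7) -> None:
    """Best-effort PDF rendering of the network colored by node role."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import networkx as nx

    g = net.graph
    pos = nx.spring_layout(g, seed=layout_seed)
    fig, ax = plt.subplots(figsize=(8, 6))
    colors = [ROLE_COLORS[roles.get(n, "other")] for n in g.nodes]
    nx.draw_networkx(
        g,
        pos=pos,
        ax=ax,
        node_color=colors,
        node_size=900,
        font_size=7,
        edge_color="#888888",
        arrowsize=10,
    )
    handles = [
        plt.Line2D([], [], marker="o", linestyle="", color=ROLE_COLORS[r], label=r)
        for r in ROLES
    ]
    ax.legend(handles=handles, fontsize=6, loc="lower right")
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, format="pdf")
    plt.close(fig)


def bundle_output(
    net: DirectedNetwork,
    solution: ControlSolution,
    roles: dict,
    out_dir,
    drug_targets=frozenset(),
    archive_name: str = "results.zip",
    extra_files: dict | None = None,
) -> Path:
    """Write all output members into ``out_dir`` and pack them into a zip.

    Archive member timestamps are fixed so that re-runs with the same seed
    produce byte-identical CSV/TXT members.  Returns the archive path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    annotated = DirectedNetwork()
    for n, attrs in net.node_attrs.items():
        annotated.add_node(n, **attrs)
        annotated.set_node_attr(n, "role", roles.get(n, "other"))
    for (u, v), signs in net.edge_sign.items():
        if signs:
            for s in sorted(signs):
                annotated.add_edge(u, v, sign=s)
        else:
            annotated.add_edge(u, v)

    write_driven_csv(solution, drug_targets, out_dir / "driven.csv")
    write_extra_csv(solution, drug_targets, out_dir / "extra.csv")
    write_details_txt(solution, out_dir / "details.txt")
    write_graphml(annotated, out_dir / "graph.xml")
    render_network_pdf(annotated, roles, out_dir / "graph.pdf")

    members = list(BUNDLE_MEMBERS)
    for name, text in (extra_files or {}).items():
        (out_dir / name).write_text(text, encoding="utf-8")
        members.append(name)

    archive = out_dir / archive_name
    with zipfile.ZipFile(archive, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        for name in members:
            info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, (out_dir / name).read_bytes())
    return archive
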
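"""Structural target controllability: stochastic heuristic and algebraic oracles.

Model
-----
The network is viewed as a discrete-time linear system

    x_{t+1} = A x_t + B u_t,      y_t = C x_t,

where ``A`` (n x n) has a nonzero entry ``A[v, u]`` for every network edge
``u -> v``, ``B`` (n x m) wires one external driver to each *driven* node, and
``C`` (l x n) selects the target nodes.  The target set is controllable iff
the controllability matrix ``[CB, CAB, ..., CA^{n-1}B]`` has rank ``l``;
structurally (for generic weights) this is equivalent to the existence of a
family of directed paths, one ending at each target, such that no two paths
pass through the same node at the same distance from their respective
endpoints.

Heuristic
---------
Finding a minimum driven set is NP-hard, so the solver grows the path family
backwards from the targets.  At distance ``d`` each still-open path either
terminates (its current start node becomes driven) or extends to an
in-neighbor; the extension nodes chosen at distance ``d+1`` must be distinct
across paths, which is enforced with an assignment (maximum bipartite
matching) between open paths and candidate nodes.  Candidates are preferred in
tiers — nodes already driven, then drug-targetable nodes, then the rest — with
random tie-breaking, and a path whose start is already driven or
drug-targetable may terminate early with a configurable probability.  Many
independent randomized runs are made and the best solution kept, ranked by
(drug-targetable coverage, driven-set size, total path length).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .netio import DirectedNetwork

__all__ = [
    "ControlPath",
    "ControlSolution",
    "ControlConfig",
    "LinearSystemRealization",
    "ValidityReport",
    "single_run",
    "find_driven_nodes",
    "verify_path_family",
    "build_realization",
    "kalman_rank_check",
    "is_target_controllable_generic",
    "brute_force_minimum_driven",
]

_NO_EDGE_COST = 1e9  # assignment cost for forbidden (path, node) pairs
ORACLE_NODE_CAP = 200  # rank-oracle size limit
_BRUTE_FORCE_NODE_CAP = 15


@dataclass(frozen=True)
class ControlPath:
    """A directed path from a driven node to the target it controls.

    ``node_sequence[0]`` is the driven node, ``node_sequence[-1]`` the target;
    a single-element sequence means the target is driven directly.  The node
    at index ``i`` sits at distance ``len - 1 - i`` from the endpoint.
    """

    node_sequence: tuple

    @property
    def target(self) -> str:
        return self.node_sequence[-1]

    @property
    def start(self) -> str:
        return self.node_sequence[0]

    def __len__(self) -> int:
        return len(self.node_sequence)

    def node_at_distance(self, d: int) -> str | None:
        """Node occupying distance ``d`` from the endpoint, or None."""
        if 0 <= d < len(self.node_sequence):
            return self.node_sequence[len(self.node_sequence) - 1 - d]
        return None

    def render(self) -> str:
        return " -> ".join(self.node_sequence)


@dataclass
class ControlSolution:
    """A driven-node set together with its certifying control-path family."""

    driven: frozenset
    paths: dict  # target -> ControlPath
    heuristic_name: str = "layered-matching"

    @property
    def targets_controlled(self) -> dict:
        """Map driven node -> number of targets whose path starts at it."""
        counts: dict = {d: 0 for d in self.driven}
        for p in self.paths.values():
            counts[p.start] = counts.get(p.start, 0) + 1
        return counts

    @property
    def total_path_length(self) -> int:
        return sum(len(p) for p in self.paths.values())

    def objective(self, preferred: frozenset) -> tuple:
        """Lexicographic objective, smaller is better:
        (-targets controlled from preferred driven nodes, |driven|, total length)."""
        preferred_controlled = sum(
            n for d, n in self.targets_controlled.items() if d in preferred
        )
        return (-preferred_controlled, len(self.driven), self.total_path_length)


@dataclass(frozen=True)
class ControlConfig:
    """Heuristic-search configuration.

    ``runs`` independent restarts are made (production-scale default 1000);
    ``preferred`` holds drug-targetable node IDs that the search steers driven
    nodes toward; ``termination_prob`` is the chance an open path stops early
    when its start is already driven or preferred; ``max_path_length`` bounds
    path length in nodes (``None`` means n, the Cayley–Hamilton bound).
    """

    runs: int = 1000
    rng_seed: int = 0
    max_path_length: int | None = None
    preferred: frozenset = frozenset()
    termination_prob: float = 0.5
    heuristic_name: str = "layered-matching"

    def __post_init__(self):
        if self.runs < 1:
            raise ValueError("runs must be >= 1")
        if not 0.0 <= self.termination_prob <= 1.0:
            raise ValueError("termination_prob must be in [0, 1]")


@dataclass
class LinearSystemRealization:
    """A numeric (A, B, C) realization of a network/driven/target triple."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    node_index: dict

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def m(self) -> int:
        return self.B.shape[1]

    @property
    def l(self) -> int:
        return self.C.shape[0]


# ---------------------------------------------------------------------------
# heuristic search
# ---------------------------------------------------------------------------


def _check_targets(net: DirectedNetwork, targets) -> list:
    targets = sorted(targets)
    if not targets:
        raise ValueError("target set must be non-empty")
    for t in targets:
        if t not in net:
            raise ValueError(f"target node {t!r} is not in the network")
    return targets


def single_run(
    net: DirectedNetwork,
    targets,
    config: ControlConfig,
    rng: np.random.Generator,
) -> ControlSolution:
    """One randomized pass of the layered-matching heuristic.

    Paths are grown backwards from the targets, one frontier layer per
    distance.  At each layer an assignment problem matches open paths to
    distinct in-neighbor candidates (tiers: already-driven, preferred, other;
    random jitter breaks ties); unmatched paths terminate and contribute their
    start node to the driven set.  The returned family always satisfies the
    layer-disjointness certificate.
    """
    targets = _check_targets(net, targets)
    g = net.graph
    max_len = config.max_path_length or net.number_of_nodes()
    preferred = frozenset(config.preferred)

    # paths stored start-first; index parallel to `targets`
    paths: list = [[t] for t in targets]
    open_idx = list(range(len(targets)))
    driven: set = set()

    for _d in range(max_len - 1):
        if not open_idx:
            break
        # voluntary early termination on driven/preferred frontiers
        still_open = []
        for i in open_idx:
            frontier = paths[i][0]
            if (frontier in driven or frontier in preferred) and (
                rng.random() < config.termination_prob
            ):
                driven.add(frontier)
            else:
                still_open.append(i)
        if not still_open:
            open_idx = []
            break

        candidates = {i: net.in_neighbors(paths[i][0]) for i in still_open}
        pool = sorted({u for cs in candidates.values() for u in cs})
        if not pool:
            for i in still_open:
                driven.add(paths[i][0])
            open_idx = []
            break

        col_of = {u: j for j, u in enumerate(pool)}
        cost = np.full((len(still_open), len(pool)), _NO_EDGE_COST)
        for row, i in enumerate(still_open):
            for u in candidates[i]:
                if u in driven:
                    tier = 0.0
                elif u in preferred:
                    tier = 1.0
                else:
                    tier = 2.0
                cost[row, col_of[u]] = tier + 0.9 * rng.random()
        rows, cols = linear_sum_assignment(cost)

        next_open = []
        assigned = {r: c for r, c in zip(rows, cols)}
        for row, i in enumerate(still_open):
            c = assigned.get(row)
            if c is not None and cost[row, c] < _NO_EDGE_COST:
                paths[i].insert(0, pool[c])
                next_open.append(i)
            else:
                driven.add(paths[i][0])
        open_idx = next_open

    for i in open_idx:  # length budget exhausted
        driven.add(paths[i][0])

    solution = ControlSolution(
        driven=frozenset(driven),
        paths={targets[i]: ControlPath(tuple(paths[i])) for i in range(len(targets))},
        heuristic_name=config.heuristic_name,
    )
    return solution


def find_driven_nodes(net: DirectedNetwork, targets, config: ControlConfig) -> ControlSolution:
    """Best-of-``config.runs`` stochastic search for a small driven set.

    Each run draws an independent RNG substream derived from ``rng_seed``, so
    the result is reproducible and independent of execution order.  Solutions
    are ranked lexicographically: maximize targets controlled from preferred
    (drug-targetable) driven nodes, then minimize driven-set size, then total
    path length; the earliest run wins ties.
    """
    targets = _check_targets(net, targets)
    preferred = frozenset(config.preferred)
    best: ControlSolution | None = None
    best_key: tuple | None = None
    for run in range(config.runs):
        rng = np.random.default_rng([config.rng_seed, run])
        sol = single_run(net, targets, config, rng)
        key = sol.objective(preferred)
        if best_key is None or key < best_key:
            best, best_key = sol, key
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# certificates and algebraic oracles
# ---------------------------------------------------------------------------


@dataclass
class ValidityReport:
    ok: bool
    violations: list = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.ok


def verify_path_family(net: DirectedNetwork, solution: ControlSolution, targets) -> ValidityReport:
    """Check the control-path-family certificate of a solution.

    Verifies (a) exactly one path per target, ending at it; (b) consecutive
    path elements are network edges; (c) no two paths occupy the same node at
    the same distance from their endpoints; (d) path starts lie in the driven
    set.  Returns a report rather than raising.
    """
    violations = []
    targets = set(targets)
    if set(solution.paths) != targets:
        violations.append(("targets", sorted(targets ^ set(solution.paths)), None))
    for t, p in solution.paths.items():
        if p.target != t:
            violations.append(("endpoint", t, p.node_sequence))
        for a, b in zip(p.node_sequence, p.node_sequence[1:]):
            if (a, b) not in net.edges:
                violations.append(("edge", (a, b), t))
        if p.start not in solution.driven:
            violations.append(("start", p.start, t))
    ordered = sorted(solution.paths)
    max_d = max((len(solution.paths[t]) for t in ordered), default=0)
    for d in range(max_d):
        seen: dict = {}
        for idx, t in enumerate(ordered):
            u = solution.paths[t].node_at_distance(d)
            if u is None:
                continue
            if u in seen:
                violations.append(("layer", d, u, seen[u], idx))
            else:
                seen[u] = idx
    return ValidityReport(ok=not violations, violations=violations)


def build_realization(
    net: DirectedNetwork,
    driven,
    targets,
    rng: np.random.Generator,
    weight_range: tuple = (0.5, 1.5),
) -> LinearSystemRealization:
    """Draw a random numeric realization matching the network's structure.

    Every edge position of ``A`` gets an independent uniform weight from
    ``weight_range`` (a range bounded away from zero keeps powers of ``A``
    well-conditioned at oracle scale); ``B`` has one column per driven node
    with a single nonzero; ``C`` selects the targets.
    """
    driven = sorted(driven)
    targets = sorted(targets)
    if not driven or not targets:
        raise ValueError("driven and target sets must be non-empty")
    nodes = sorted(net.nodes)
    index = {u: i for i, u in enumerate(nodes)}
    for u in list(driven) + list(targets):
        if u not in index:
            raise ValueError(f"node {u!r} is not in the network")
    n = len(nodes)
    lo, hi = weight_range
    A = np.zeros((n, n))
    for (u, v) in sorted(net.edges):
        A[index[v], index[u]] = rng.uniform(lo, hi)
    B = np.zeros((n, len(driven)))
    for j, u in enumerate(driven):
        B[index[u], j] = rng.uniform(lo, hi)
    C = np.zeros((len(targets), n))
    for i, t in enumerate(targets):
        C[i, index[t]] = 1.0
    return LinearSystemRealization(A=A, B=B, C=C, node_index=index)


def kalman_rank_check(real: LinearSystemRealization, rtol: float = 1e-8) -> int:
    """Numerical rank of the output controllability matrix
    ``[CB, CAB, ..., CA^{n-1}B]``.

    Blocks are built iteratively as ``M_{k+1} = A M_k`` with per-iteration
    column normalization so entries neither overflow nor vanish; the rank is
    read off the singular values with a relative tolerance of
    ``rtol * max(dims)``.
    """
    n = real.n
    if n > ORACLE_NODE_CAP:
        raise ValueError(
            f"network has {n} nodes, above the rank-oracle cap {ORACLE_NODE_CAP}; "
            "use the path-family certificate instead"
        )
    blocks = []
    M = real.B.copy()
    for _ in range(n):
        blocks.append(real.C @ M)
        M = real.A @ M
        norms = np.linalg.norm(M, axis=0)
        norms[norms == 0] = 1.0
        M = M / norms
    K = np.hstack(blocks)
    s = np.linalg.svd(K, compute_uv=False)
    if s.size == 0 or s[0] == 0:
        return 0
    tol = s[0] * rtol * max(K.shape)
    return int(np.sum(s > tol))


def is_target_controllable_generic(
    net: DirectedNetwork,
    driven,
    targets,
    trials: int = 3,
    rng_seed: int = 0,
) -> bool:
    """Structural target controllability test via random numeric realizations.

    Generic weights avoid the measure-zero exceptional set with probability 1,
    so one full-rank realization certifies structural controllability;
    ``trials`` independent draws guard against unlucky numerics.
    """
    targets = sorted(targets)
    for trial in range(trials):
        rng = np.random.default_rng([rng_seed, trial])
        real = build_realization(net, driven, targets, rng)
        if kalman_rank_check(real) == len(targets):
            return True
    return False


def brute_force_minimum_driven(
    net: DirectedNetwork,
    targets,
    max_cardinality: int | None = None,
    rng_seed: int = 0,
) -> frozenset | None:
    """Exhaustive minimum driven set, for small test instances only.

    Enumerates candidate driven sets in increasing cardinality and returns the
    first that passes the structural rank test; ``None`` when nothing within
    ``max_cardinality`` works.  Exponential — capped at 15 nodes.
    """
    targets = sorted(targets)
    nodes = sorted(net.nodes)
    if len(nodes) > _BRUTE_FORCE_NODE_CAP:
        raise ValueError(
            f"brute force is capped at {_BRUTE_FORCE_NODE_CAP} nodes, got {len(nodes)}"
        )
    if max_cardinality is None:
        max_cardinality = len(targets)
    for k in range(1, max_cardinality + 1):
        for cand in combinations(nodes, k):
            if is_target_controllable_generic(net, cand, targets, rng_seed=rng_seed):
                return frozenset(cand)
    return None
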
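# Methods

## Problem and model

The package decides, and constructively certifies, *structural target
controllability* of a directed molecular interaction network. The network is
identified with the zero/nonzero pattern of the state matrix `A` of a linear
system `x_{t+1} = A x_t + B u_t`, `y_t = C x_t`: an edge `u → v` means
`A[v, u] ≠ 0`. Each driven node receives one dedicated external driver (one
column of `B` with a single nonzero); `C` has one row per target with a single
1. The `l` targets are controllable exactly when the output controllability
matrix `[CB, CAB, …, CA^{n-1}B]` has rank `l`; truncation at `n` blocks is
justified by Cayley–Hamilton. Structural (generic-weight) controllability is
equivalent to the existence of a control-path family: one directed path ending
at each target such that no two paths occupy the same node at the same
distance from their respective endpoints. A path of one node (a target driven
directly) is legal; paths are allowed to revisit nodes at different distances
and to pass through other targets — only the layer rule governs.

Edge signs (activation/inhibition) are carried as annotations only; the
structural formalism uses edge existence alone, so parallel signed edges
between the same ordered pair are collapsed to one edge with a sign set.

## Heuristic search

Exact minimization of the driven set is NP-hard, so the solver uses a
randomized layered construction, restarted many times:

1. At distance 0 each target starts its own path (injective by construction).
2. At each distance `d`, every still-open path either terminates — its current
   start node joins the driven set — or extends to an in-neighbor of its
   start. Extensions chosen at distance `d+1` must be distinct across open
   paths; this is enforced by solving an assignment problem (maximum bipartite
   matching via `scipy.optimize.linear_sum_assignment`) between open paths and
   candidate in-neighbors. Forbidden pairs carry a prohibitive cost, so
   match cardinality is maximized first; within that, candidates are scored in
   tiers — already-driven node (cost 0, free reuse), drug-targetable node
   (cost 1), anything else (cost 2) — plus uniform jitter in `[0, 0.9)` that
   breaks ties randomly without ever crossing a tier boundary.
3. Before matching, a path whose start node is already driven or
   drug-targetable terminates voluntarily with probability `termination_prob`
   (default 0.5). This is the main source of run-to-run diversity: it lets
   the search trade a longer merged path against an earlier drug-targetable
   anchor.
4. A path with no candidates (in-degree 0, or unmatched) terminates. Paths
   are capped at `max_path_length` nodes, default `n` (rank contributions
   stop at `A^{n-1}`).

Closed paths occupy only distances up to their own length, and extensions at
a given layer are injective, so the layer-disjointness certificate holds by
construction; `verify_path_family` re-checks it independently after the fact.

`find_driven_nodes` repeats `runs` independent single runs (default 1000,
matching the production-scale "thousands of restarts" regime) and keeps the
lexicographically best solution: maximize the number of targets controlled
from drug-targetable driven nodes, then minimize the driven-set size, then
the total path length. The drug-preference term is ranked first deliberately:
a slightly larger driven set anchored at a druggable protein is the useful
answer for intervention design, and it is what makes the worked example
return {AKT1, NRG1} rather than the strictly smaller {NRG1}.

### Randomness and determinism

All stochastic choices flow from one user-visible integer seed. Run `k` uses
the substream `default_rng([seed, k])`, so results are independent of
execution order and reproducible bit-for-bit; ties between equally good runs
are resolved in favor of the earliest run index.

## Oracles

Two independent checks guard the heuristic:

* **Algebraic oracle** — `build_realization` draws uniform weights from
  `[0.5, 1.5]` at every structural nonzero (bounded away from zero so powers
  of `A` stay well-conditioned at oracle scale, up to a 200-node cap);
  `kalman_rank_check` builds the blocks iteratively with per-iteration column
  normalization and reads the rank off singular values, counting values below
  `σ_max · 10⁻⁸ · max(dims)` as zero. Generic weights avoid the measure-zero
  exceptional set with probability 1; `is_target_controllable_generic` tries
  3 independent realizations and accepts if any reaches full rank.
* **Exhaustive oracle** — `brute_force_minimum_driven` enumerates candidate
  driven sets in increasing cardinality (≤ 15 nodes, test scale only). Since
  driving every target directly always works, enumeration up to `|T|`
  suffices.

The central cross-validation — every heuristic solution passes both the
certificate check and the rank oracle — is exercised on hundreds of random
digraphs in the test suite and the acceptance script.

## Network assembly and target selection

The `gap` parameter (0–5) bounds the number of intermediate nodes on
seed-to-seed walks: a walk of ≤ `gap+1` edges. Instead of enumerating walks,
multi-source BFS computes `dF(u)` (nearest seed → `u`) and `dB(u)` (`u` →
nearest seed); node `u` is admitted when `dF(u) + dB(u) ≤ gap+1` and edge
`(u, v)` when `dF(u) + 1 + dB(v) ≤ gap+1` — exactly the union of all bounded
walks, in polynomial time (the test suite verifies the equivalence against a
brute-force walk enumerator). Walks may start and end at the same seed; nodes
on such cycles get an `on_seed_cycle` attribute. Seeds missing from the
interaction table are kept as isolated nodes with a warning, since a
user-listed protein must still be reported (it becomes its own driven node).

Targets from essentiality screens are filtered with strict inequalities:
GARP score < 0 (the "negative range"; more negative = more essential) and
GARP-P < 0.05, per cell line. Both thresholds are configurable; strictness at
the boundary follows the published filter wording. By default (and
controllable by a flag) targets are appended to the seed set before assembly
so that they are guaranteed to be present in the network.

## Outputs

`driven.csv` / `extra.csv` split the driven nodes by drug-targetability, each
with the number of targets controlled, sorted by count descending then name
(comma-separated, header row, LF endings — the concrete dialect is this
package's choice). `details.txt` lists the heuristic name, the sorted driven
nodes, and each control path. `graph.xml` is directed GraphML with a `role`
attribute per node using the five-way classification (driven roles beat
controlled roles, which beat the plain seed role — precedence chosen so a
seed that ends up driven is reported as driven). `graph.pdf` is a best-effort
spring-layout rendering with the role color legend; no layout contract is
made. All members are packed into a zip with fixed timestamps so re-runs with
the same seed are byte-identical on the text members.

## Synthetic data

`random_digraph` (Erdős–Rényi, directed, no self-loops) and
`random_scale_free_digraph` (preferential attachment, heavy-tailed degrees
as in real PPI networks) provide reproducible test instances. They emulate
wiring statistics only — no edge signs, no biological node identities, no
database noise or literature bias — so passing tests demonstrate algorithmic
correctness on those wiring regimes, not biological validity of predictions
on real pathway data. The packaged 14-node ERBB3/PI3K/AKT/MTOR example is an
exact reconstruction of a published signaling subnetwork and is the only
fixture with biological identity.

## Problem sizes and defaults

The acceptance computations use 300 random digraphs (n ∈ [3, 30], edge
probability 0.1–0.3, 1–5 targets) for the certificate/rank-oracle agreement
and 100 digraphs (n ∈ [4, 12]) for the brute-force comparison at the full
1000 restarts; these sizes give stable rates while keeping the whole script
in the tens of seconds on one CPU. Within the agreement batch each instance
uses 10 restarts, since certificate validity is a per-run property that does
not depend on the restart count.

## Limitations

* Heuristic only: no minimality guarantee (the problem is NP-hard); the
  brute-force oracle exists purely for small-instance testing.
* The numeric rank oracle is capped at 200 nodes; beyond that only the
  path-family certificate is available.
* Discrete-time structural formalism: no control-energy accounting, no
  continuous dynamics, no use of interaction signs in the control logic.
* Identifier handling is opaque — no HGNC/UniProt normalization; users must
  supply consistent IDs across network, target, and drug-target files.
* Assembly operates on a user-supplied local interaction table; no pathway
  databases are queried.
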
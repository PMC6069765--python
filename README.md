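# netcontrol

Structural **target controllability** analysis of directed molecular
interaction networks: given a signaling/PPI network and a set of target
proteins (for example cancer cell-line essential genes), find a small set of
*driven* nodes — preferring proteins with known drugs — through which external
inputs can steer the targets.

The intended users are systems-biology and network-medicine researchers who
want to turn a list of disease-essential proteins into candidate intervention
points (e.g. combined multi-drug therapy hypotheses) without measuring any
kinetic parameters: only the wiring of the network is used.

## The model

The network `G = (V, E)` with `n` nodes is viewed as a discrete-time linear
time-invariant system

```
x_{t+1} = A x_t + B u_t,        y_t = C x_t
```

where `A` is `n×n` with `a_{i,j} ≠ 0` exactly when edge `j → i` exists, `B`
(`n×m`) attaches one external driver signal to each of the `m` driven nodes,
and `C` (`l×n`) selects the `l` target nodes. The targets are controllable iff

```
rank [CB, CAB, CA²B, …, CA^{n-1}B] = l          (Kalman rank condition)
```

*Structurally*, i.e. for generic edge weights, this is equivalent to a purely
graph-theoretic certificate: a family of directed paths, one ending at each
target, such that **no two paths pass through the same node at the same
distance from their endpoints**. Finding a minimum driven set is NP-hard, so
the solver grows such a path family backwards from the targets with a
randomized layered-matching heuristic, repeats it many times (default 1000),
and keeps the best solution — ranked by drug-targetable coverage first, then
driven-set size, then total path length. Both sides of the equivalence are
implemented: the heuristic emits the path-family certificate, and a numeric
rank oracle on random realizations cross-checks it.

The surrounding pipeline mirrors the classic web tool workflow: a network is
either supplied directly (edge list / SIF / GraphML) or assembled from seed
proteins and a local interaction table by admitting every directed seed-to-seed
walk with at most `gap` intermediate nodes (`gap ≤ 5`); targets can be drawn
from GARP essentiality screens (strictly negative GARP score, GARP-P < 0.05);
results are written as a zip bundle (`driven.csv`, `extra.csv`, `details.txt`,
`graph.xml`, `graph.pdf`) with the five-way node-role coloring.

## Worked example

The packaged `fig3_network()` fixture is a 14-node ERBB3/PI3K/AKT/MTOR
signaling network: NRG1 activates ERBB3, ERBB3 activates eight PI3K subunits,
each PI3K subunit regulates AKT1–3 and MTOR, and AKT1 activates MTOR. The
breast-cancer essential proteins MTOR and ERBB3 are the targets; AKT1 is the
drug-targetable protein.

```python
from netcontrol import ControlConfig, find_driven_nodes, fig3_network

ex = fig3_network()
cfg = ControlConfig(runs=1000, rng_seed=42, preferred=ex.drug_targets)
sol = find_driven_nodes(ex.network, ex.targets, cfg)
print("driven nodes:", sorted(sol.driven))
for target in sorted(sol.paths):
    print(f"  {sol.paths[target].render()}")
print("targets controlled:", dict(sorted(sol.targets_controlled.items())))
```

prints

```
driven nodes: ['AKT1', 'NRG1']
  NRG1 -> ERBB3
  AKT1 -> MTOR
targets controlled: {'AKT1': 1, 'NRG1': 1}
```

Control over the essential protein MTOR is gained through the drug-targetable
driven node AKT1, and over ERBB3 through the (non-drug-targetable) driven node
NRG1. With an empty `preferred` set the solver instead finds the single driven
node NRG1, which reaches ERBB3 directly and MTOR through a four-step path —
smaller, but with no drug-targetable entry point.

The same run from the shell:

```sh
netcontrol --network fig3.sif --targets targets.txt --drug-targets fda.txt \
           --runs 1000 --rng-seed 42 -o out/
```

writes `out/results.zip`; `out/driven.csv` then contains the single row
`AKT1,1` and `out/extra.csv` the single row `NRG1,1`.

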
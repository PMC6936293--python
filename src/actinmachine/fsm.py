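"""Finite-state machine view of the droplet network.

The machine's state at an instant is the k-bit string of per-electrode
spike presence within one coincidence group, decimal-encoded with
electrode 0 as the most significant bit (a spike only on electrode e5 at
k=6 is state 1; only on e0, state 32).  Stimulating the network with every
non-zero input string and reading the resulting state sequences yields:

- per-input transition graphs (edge a→b for consecutive state events);
- a weighted global graph G pooling all inputs, with each node's outgoing
  transition counts normalized to weights summing to 1;
- a pruned graph G* keeping only the maximum-weight outgoing edge of each
  node (at most one out-edge per node), on which nodes are classified as
  Garden-of-Eden (no predecessors), fixed points (self-edge or no
  successor), or ordinary;
- richness statistics: the number and set of distinct states observed at
  each transition step over all inputs, states per input, inputs per state;
- the step-indexed response map g(t): input string → state at the t-th
  event, from which per-electrode Boolean functions are reconstructed.

"Transition step" indexes successive non-zero state events (coincidence
groups), not raw automaton iterations — at almost every raw iteration no
electrode spikes and the state string would be all-zero.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .spikes import COINCIDENCE_WINDOW, SpikeTrain, group_coincident

__all__ = [
    "state_to_bits",
    "bits_to_state",
    "StateSequence",
    "states_from_spikes",
    "transition_graph",
    "weighted_global_graph",
    "PrunedGraph",
    "prune",
    "RichnessTable",
    "richness",
    "g_of_t",
    "to_dot",
]


def state_to_bits(state: int, k: int) -> tuple[int, ...]:
    """Decimal machine state -> per-electrode bits (electrode 0 = MSB)."""
    if not 0 <= state < 2**k:
        raise ValueError(f"state {state} out of range for k={k}")
    return tuple((state >> (k - 1 - i)) & 1 for i in range(k))


def bits_to_state(bits: Sequence[int]) -> int:
    """Per-electrode bits (electrode 0 = MSB) -> decimal machine state."""
    k = len(bits)
    if any(b not in (0, 1) for b in bits):
        raise ValueError("bits must be 0 or 1")
    return sum(b << (k - 1 - i) for i, b in enumerate(bits))


@dataclass(frozen=True)
class StateSequence:
    """Time-ordered non-zero machine states produced by one input string."""

    events: tuple[tuple[int, int], ...]  # (representative time, state)
    input: int | None = None

    def __post_init__(self) -> None:
        times = [t for t, _ in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        if any(s == 0 for _, s in self.events):
            raise ValueError("all-zero states are never stored")

    @property
    def states(self) -> tuple[int, ...]:
        return tuple(s for _, s in self.events)


def states_from_spikes(
    trains: Sequence[SpikeTrain],
    k: int | None = None,
    window: int = COINCIDENCE_WINDOW,
    input: int | None = None,
) -> StateSequence:
    """Build the machine-state sequence from per-electrode spike trains.

    ``trains[i]`` is electrode i's train (bit i of the state, MSB-first
    encoding).  All spikes are pooled and coincidence-grouped; each group
    maps to the state whose bit i is 1 iff electrode i spikes in the group.
    """
    k = k if k is not None else len(trains)
    if len(trains) != k:
        raise ValueError(f"expected {k} spike trains, got {len(trains)}")
    # group by electrode *index* so duplicate labels cannot collide
    indexed = [SpikeTrain(str(i), train.times) for i, train in enumerate(trains)]
    events = []
    for group in group_coincident(indexed, window):
        bits = [0] * k
        for idx_label, _ in group.members:
            bits[int(idx_label)] = 1
        events.append((group.time, bits_to_state(bits)))
    return StateSequence(tuple(events), input=input)


def transition_graph(seq: StateSequence) -> nx.DiGraph:
    """Simple digraph of consecutive state transitions for one input.

    Parallel repeats collapse into a single edge; the observation count is
    kept on the edge attribute ``count``.
    """
    g = nx.DiGraph()
    g.add_nodes_from(seq.states)
    for (_, a), (_, b) in zip(seq.events, seq.events[1:]):
        if g.has_edge(a, b):
            g[a][b]["count"] += 1
        else:
            g.add_edge(a, b, count=1)
    return g


def weighted_global_graph(sequences: Iterable[StateSequence]) -> nx.DiGraph:
    """Pool transitions over all inputs into the weighted global graph G.

    Edge weight w(a, b) is the number of observed a→b transitions divided
    by the total number of transitions leaving a (self-transitions
    included), so every non-terminal node's outgoing weights sum to 1.
    """
    counts: Counter[tuple[int, int]] = Counter()
    nodes: set[int] = set()
    for seq in sequences:
        nodes.update(seq.states)
        for (_, a), (_, b) in zip(seq.events, seq.events[1:]):
            counts[(a, b)] += 1
    out_total: Counter[int] = Counter()
    for (a, _), n in counts.items():
        out_total[a] += n
    g = nx.DiGraph()
    g.add_nodes_from(sorted(nodes))
    for (a, b), n in sorted(counts.items()):
        g.add_edge(a, b, count=n, weight=n / out_total[a])
    return g


@dataclass
class PrunedGraph:
    """Maximum-weight skeleton G* of the global graph: <=1 out-edge per node."""

    graph: nx.DiGraph
    node_class: dict[int, str]  # garden_of_eden | fixed_point | ordinary
    indegree: dict[int, int]

    def nodes_of_class(self, cls: str) -> list[int]:
        return sorted(n for n, c in self.node_class.items() if c == cls)


def prune(graph: nx.DiGraph) -> PrunedGraph:
    """Keep each node's maximum-weight outgoing edge and classify the nodes.

    Weight ties break toward the smallest successor decimal, which keeps the
    skeleton deterministic across platforms.  Classes: ``garden_of_eden``
    for nodes without predecessors in G*; otherwise ``fixed_point`` for
    nodes with a self-edge or no outgoing edge; otherwise ``ordinary``.
    """
    pruned = nx.DiGraph()
    pruned.add_nodes_from(graph.nodes)
    for a in graph.nodes:
        succs = graph.succ[a]
        if not succs:
            continue
        best = min(succs, key=lambda b: (-succs[b]["weight"], b))
        pruned.add_edge(a, best, weight=succs[best]["weight"])
    indegree = dict(pruned.in_degree())
    node_class = {}
    for n in pruned.nodes:
        if indegree[n] == 0:
            node_class[n] = "garden_of_eden"
        elif pruned.out_degree(n) == 0 or pruned.has_edge(n, n):
            node_class[n] = "fixed_point"
        else:
            node_class[n] = "ordinary"
    return PrunedGraph(pruned, node_class, indegree)


@dataclass
class RichnessTable:
    """Distinct-state statistics of the machine's responses.

    ``table`` has one row per transition step t with mu(t) = number of
    distinct states over all inputs and the sorted state set P(t);
    ``per_input`` counts distinct states in each input's evolution;
    ``per_state`` counts how many inputs ever reach each state.
    """

    table: pd.DataFrame
    per_input: dict[int, int]
    per_state: dict[int, int]

    def mu(self, t: int) -> int:
        row = self.table.loc[self.table["t"] == t, "mu"]
        return int(row.iloc[0]) if len(row) else 0


def richness(sequences: Iterable[StateSequence]) -> RichnessTable:
    """Tabulate mu(t), P(t) and the per-input / per-state distributions."""
    seqs = list(sequences)
    by_step: defaultdict[int, set[int]] = defaultdict(set)
    per_input: dict[int, int] = {}
    per_state: Counter[int] = Counter()
    for n, seq in enumerate(seqs):
        key = seq.input if seq.input is not None else n
        states = seq.states
        per_input[key] = len(set(states))
        for s in set(states):
            per_state[s] += 1
        for t, s in enumerate(states, start=1):
            by_step[t].add(s)
    rows = [
        {"t": t, "mu": len(states), "states": tuple(sorted(states))}
        for t, states in sorted(by_step.items())
    ]
    table = pd.DataFrame(rows, columns=["t", "mu", "states"])
    return RichnessTable(table, per_input, dict(per_state))


def g_of_t(sequences: Iterable[StateSequence], t: int) -> dict[int, int]:
    """The response map at transition step t: input → t-th event state.

    Inputs with fewer than t events are absent from the mapping (and become
    don't-cares when Boolean functions are reconstructed downstream).
    """
    if t < 1:
        raise ValueError("transition step t must be >= 1")
    out: dict[int, int] = {}
    for n, seq in enumerate(sequences):
        key = seq.input if seq.input is not None else n
        if len(seq.events) >= t:
            out[key] = seq.events[t - 1][1]
    return out


def to_dot(graph: nx.DiGraph, node_class: Mapping[int, str] | None = None) -> str:
    """Render a transition graph as GraphViz DOT text (weights as labels)."""
    lines = ["digraph M {"]
    shapes = {"fixed_point": "doublecircle", "garden_of_eden": "diamond"}
    for n in sorted(graph.nodes):
        attrs = []
        if node_class and node_class.get(n) in shapes:
            attrs.append(f'shape={shapes[node_class[n]]}')
        lines.append(f'  "{n}"' + (f" [{', '.join(attrs)}]" if attrs else "") + ";")
    for a, b, data in sorted(graph.edges(data=True)):
        w = data.get("weight")
        label = f' [label="{w:.3f}"]' if w is not None else ""
        lines.append(f'  "{a}" -> "{b}"{label};')
    lines.append("}")
    return "\n".join(lines) + "\n"
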
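"""Independent brute-force reference implementations used as test oracles.

The naive automaton keeps per-voxel state in plain dictionaries keyed by
coordinate tuples and applies the update rule voxel by voxel, literally:
no arrays, no convolutions.  It is deliberately implemented in a
different style from the package so that agreement is informative.
"""

from __future__ import annotations

import itertools

RESTING, EXCITED, REFRACTORY = 0, 1, 2


def brute_force_offsets(radius: int) -> list[tuple[int, int, int]]:
    out = []
    for d in itertools.product(range(-radius, radius + 1), repeat=3):
        if d != (0, 0, 0) and d[0] ** 2 + d[1] ** 2 + d[2] ** 2 <= radius**2:
            out.append(d)
    return out


class NaiveAutomaton:
    """Literal per-voxel simulator over a set of conductive coordinates."""

    def __init__(self, conductive: set[tuple[int, int, int]], theta: int, delta: int, radius: int):
        self.conductive = conductive
        self.theta = theta
        self.delta = delta
        self.offsets = brute_force_offsets(radius)
        self.state = {p: RESTING for p in conductive}
        self.h = {p: 0 for p in conductive}

    def excite(self, voxels) -> None:
        for p in voxels:
            if p in self.conductive and self.state[p] == RESTING:
                self.state[p] = EXCITED

    def step(self) -> None:
        excited_now = {p for p, s in self.state.items() if s == EXCITED}
        new_state = {}
        new_h = {}
        for p in self.conductive:
            s, h = self.state[p], self.h[p]
            sigma = sum(
                1
                for dx, dy, dz in self.offsets
                if (p[0] + dx, p[1] + dy, p[2] + dz) in excited_now
            )
            if s == RESTING and sigma > self.theta:
                ns = EXCITED
            elif s == EXCITED or (s == REFRACTORY and h > 0):
                ns = REFRACTORY
            else:
                ns = RESTING
            if ns == REFRACTORY and s == EXCITED:
                nh = self.delta
            elif ns == REFRACTORY and h > 0:
                nh = h - 1
            else:
                nh = 0
            new_state[p] = ns
            new_h[p] = nh
        self.state = new_state
        self.h = new_h


def transitive_closure_groups(events: list[tuple[int, str]], window: int) -> list[list[tuple[int, str]]]:
    """Brute-force coincidence grouping: union-find over all event pairs < window apart."""
    n = len(events)
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a in range(n):
        for b in range(a + 1, n):
            if abs(events[a][0] - events[b][0]) < window:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
    groups: dict[int, list[tuple[int, str]]] = {}
    for idx, ev in enumerate(events):
        groups.setdefault(find(idx), []).append(ev)
    return sorted((sorted(g) for g in groups.values()), key=lambda g: g[0])
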
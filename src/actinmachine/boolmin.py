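"""Truth tables and two-level Boolean minimization to disjunctive normal form.

Each electrode's reconstructed k-ary function is given as a truth table
over input strings (rows indexed by the decimal input, variable x_i bound
to electrode i, MSB-first, matching the machine-state encoding).  Rows can
be 1, 0, or don't-care — inputs never observed at a transition step are
don't-cares rather than fabricated zeros (a strict mode maps them to 0).

Minimization is classical Quine–McCluskey: merge implicants differing in
one bit to obtain the prime implicants, take the essential primes, and
close the remaining cover with Petrick's method.  Don't-cares participate
in merging but never have to be covered.  Among minimal covers ties break
by fewest total literals, then lexicographically on the rendered terms, so
output strings are reproducible.  Exhaustive at k = 6 (64 rows) in
milliseconds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

__all__ = [
    "TruthTable",
    "DNF",
    "table_from_g",
    "minimize_dnf",
    "dnf_to_string",
]

_OVERBAR = "̄"  # combining macron: x̄


@dataclass(frozen=True)
class TruthTable:
    """Outputs for all 2^k assignments: 1, 0 or None (don't-care)."""

    k: int
    outputs: tuple[int | None, ...]

    def __post_init__(self) -> None:
        if len(self.outputs) != 2**self.k:
            raise ValueError(f"expected {2**self.k} rows, got {len(self.outputs)}")
        if any(o not in (0, 1, None) for o in self.outputs):
            raise ValueError("outputs must be 0, 1 or None")

    @property
    def minterms(self) -> tuple[int, ...]:
        return tuple(v for v, o in enumerate(self.outputs) if o == 1)

    @property
    def dontcares(self) -> tuple[int, ...]:
        return tuple(v for v, o in enumerate(self.outputs) if o is None)

    @classmethod
    def from_minterms(
        cls, k: int, minterms: Sequence[int], dontcares: Sequence[int] = ()
    ) -> "TruthTable":
        outputs: list[int | None] = [0] * 2**k
        for m in dontcares:
            outputs[m] = None
        for m in minterms:
            outputs[m] = 1
        return cls(k, tuple(outputs))


@dataclass(frozen=True)
class DNF:
    """Disjunction of product terms.

    Each term is a tuple of (variable index, polarity) literals sorted by
    variable; polarity False means the variable appears negated.  The empty
    DNF is the constant False.
    """

    k: int
    terms: tuple[tuple[tuple[int, bool], ...], ...]

    def evaluate(self, assignment: int) -> bool:
        """Evaluate on a decimal assignment (x0 = most significant bit)."""
        for term in self.terms:
            if all(
                ((assignment >> (self.k - 1 - var)) & 1) == int(pol)
                for var, pol in term
            ):
                return True
        return False

    def __str__(self) -> str:
        return dnf_to_string(self)


def table_from_g(
    g: Mapping[int, int], electrode: int, k: int, absent: str = "dontcare"
) -> TruthTable:
    """Truth table of one electrode's bit of the response map g.

    Row v is bit ``electrode`` of g(v) (MSB-first) for inputs in g's
    domain.  Input 0 is fixed to output 0: the unstimulated network is
    quiescent.  Other absent inputs are don't-cares, or 0 when
    ``absent='zero'``.
    """
    if not 0 <= electrode < k:
        raise ValueError(f"electrode index {electrode} out of range for k={k}")
    if absent not in {"dontcare", "zero"}:
        raise ValueError("absent must be 'dontcare' or 'zero'")
    fill = None if absent == "dontcare" else 0
    outputs: list[int | None] = []
    for v in range(2**k):
        if v == 0:
            outputs.append(0)
        elif v in g:
            outputs.append((g[v] >> (k - 1 - electrode)) & 1)
        else:
            outputs.append(fill)
    return TruthTable(k, tuple(outputs))


# ---------------------------------------------------------------------------
# Quine–McCluskey
# ---------------------------------------------------------------------------

def _prime_implicants(k: int, terms: Sequence[int]) -> set[tuple[int, int]]:
    """Prime implicants as (value, mask) pairs; mask bits are free positions."""
    current: set[tuple[int, int]] = {(t, 0) for t in terms}
    primes: set[tuple[int, int]] = set()
    while current:
        merged: set[tuple[int, int]] = set()
        used: set[tuple[int, int]] = set()
        groups: dict[tuple[int, int], list[int]] = {}
        for value, mask in current:
            groups.setdefault((mask, bin(value).count("1")), []).append(value)
        by_mask: dict[int, dict[int, list[int]]] = {}
        for (mask, ones), values in groups.items():
            by_mask.setdefault(mask, {})[ones] = values
        for mask, by_ones in by_mask.items():
            for ones, values in by_ones.items():
                for v1 in values:
                    for v2 in by_ones.get(ones + 1, ()):
                        diff = v1 ^ v2
                        if diff & (diff - 1) == 0:  # single differing bit
                            merged.add((v1 & ~diff, mask | diff))
                            used.add((v1, mask))
                            used.add((v2, mask))
        primes |= current - used
        current = merged
    return primes


def _covers(prime: tuple[int, int], minterm: int) -> bool:
    value, mask = prime
    return (minterm & ~mask) == value


def _term_literals(prime: tuple[int, int], k: int) -> tuple[tuple[int, bool], ...]:
    value, mask = prime
    lits = []
    for var in range(k):
        bit = 1 << (k - 1 - var)
        if not mask & bit:
            lits.append((var, bool(value & bit)))
    return tuple(lits)


def _petrick_covers(
    primes: Sequence[tuple[int, int]], minterms: Sequence[int]
) -> list[frozenset[int]]:
    """All irredundant covers (as sets of prime indices) via Petrick's product."""
    product: list[frozenset[int]] = [frozenset()]
    for m in minterms:
        options = [i for i, p in enumerate(primes) if _covers(p, m)]
        new: list[frozenset[int]] = []
        for partial in product:
            for opt in options:
                new.append(partial | {opt})
        # absorption: drop supersets
        new.sort(key=len)
        kept: list[frozenset[int]] = []
        for s in new:
            if not any(t <= s for t in kept):
                kept.append(s)
        product = kept
    return product


def _reduce_chart(
    primes: Sequence[tuple[int, int]], minterms: Sequence[int], k: int
) -> tuple[set[int], set[int], list[int]]:
    """Classical covering-chart reduction before Petrick's method.

    Iterates essential-prime extraction, row dominance (a minterm whose
    covering-prime set contains another's is automatically covered) and
    column dominance (a prime whose remaining coverage is contained in a
    no-costlier prime's can be dropped) until a fixpoint.  Returns the
    chosen essential primes, the surviving candidate primes, and the still
    uncovered minterms — the cyclic core, which is small enough for
    Petrick's exhaustive product.
    """
    chosen: set[int] = set()
    active = set(range(len(primes)))
    remaining = set(minterms)

    def prime_cost(i: int) -> tuple[int, int]:
        value, mask = primes[i]
        return (k - bin(mask).count("1"), i)  # number of literals, then index

    changed = True
    while changed and remaining:
        changed = False
        # essential primes: sole cover of some minterm
        for m in sorted(remaining):
            opts = [i for i in active if _covers(primes[i], m)]
            if len(opts) == 1 and opts[0] not in chosen:
                chosen.add(opts[0])
                changed = True
        covered = {
            m for m in remaining if any(_covers(primes[i], m) for i in chosen)
        }
        if covered:
            remaining -= covered
            changed = True
        active -= chosen
        # row dominance: if options(a) >= options(b), covering b covers a
        opts_map = {
            m: frozenset(i for i in active if _covers(primes[i], m))
            for m in remaining
        }
        rows = sorted(remaining)
        dropped_rows = set()
        for a in rows:
            for b in rows:
                if a == b or a in dropped_rows or b in dropped_rows:
                    continue
                if opts_map[a] > opts_map[b] or (opts_map[a] == opts_map[b] and a > b):
                    dropped_rows.add(a)
        if dropped_rows:
            remaining -= dropped_rows
            changed = True
        # column dominance: coverage subset of a no-costlier prime
        cover_map = {
            i: frozenset(m for m in remaining if _covers(primes[i], m))
            for i in active
        }
        dropped_cols = {i for i, c in cover_map.items() if not c}
        cols = sorted(active - dropped_cols)
        for a in cols:
            for b in cols:
                if a == b or a in dropped_cols or b in dropped_cols:
                    continue
                if cover_map[a] < cover_map[b] and prime_cost(b)[0] <= prime_cost(a)[0]:
                    dropped_cols.add(a)
                elif cover_map[a] == cover_map[b] and prime_cost(b) < prime_cost(a):
                    dropped_cols.add(a)
        if dropped_cols:
            active -= dropped_cols
            changed = True
    return chosen, active, sorted(remaining)


def minimize_dnf(table: TruthTable) -> DNF:
    """Minimize a truth table to a minimal-cover DNF.

    The result covers every 1-row, no 0-row, and is locally minimal: no
    term can be dropped and no literal removed without changing the
    function on the specified rows.  Constant-0 tables yield the empty DNF.
    """
    minterms = table.minterms
    if not minterms:
        return DNF(table.k, ())
    primes = sorted(_prime_implicants(table.k, [*minterms, *table.dontcares]))
    chosen, active, remaining = _reduce_chart(primes, minterms, table.k)
    covers = _petrick_covers([primes[i] for i in sorted(active)], remaining)
    index_map = sorted(active)

    def cost(cover: frozenset[int]) -> tuple:
        terms = sorted(
            _term_literals(primes[i], table.k) for i in cover
        )
        n_literals = sum(len(t) for t in terms)
        return (len(cover), n_literals, _render_terms(terms))

    best = (
        min((frozenset(index_map[i] for i in c) for c in covers), key=cost) | chosen
    )
    terms = tuple(
        sorted(
            (_term_literals(primes[i], table.k) for i in best),
            key=lambda t: (len(t), _render_terms([t])),
        )
    )
    return DNF(table.k, terms)


def _render_literal(var: int, polarity: bool) -> str:
    return f"x{var}" if polarity else f"x{_OVERBAR}{var}"


def _render_terms(terms: Sequence[tuple[tuple[int, bool], ...]]) -> str:
    return " + ".join(
        "·".join(_render_literal(v, p) for v, p in term) for term in terms
    )


def dnf_to_string(dnf: DNF) -> str:
    """Deterministic text rendering: terms by (size, lexicographic), x̄ negation.

    The constant-False DNF renders as ``"0"``.
    """
    if not dnf.terms:
        return "0"
    terms = sorted(dnf.terms, key=lambda t: (len(t), _render_terms([t])))
    return _render_terms(terms)
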
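"""Execution semantics: programs as mappings Sigma -> Sigma+.

Octagon vertices are labelled 0..7 increasing clockwise, so ``+k`` moves k
steps clockwise and ``-k`` anticlockwise (the worked convention 0 -> 1 -> 2
for ``[+1, +1]``).  Reflections are the permutations ``pos -> (c - pos) mod
8`` with an odd constant c per axis; ``P`` is the half-turn ``pos -> (pos +
4) mod 8``.  Ad-hoc symbols map a position through arithmetic on its label
or through a digit table of a mathematical constant, everything reduced
mod 8.

Execution threads a *current position* through the emitted points: an
atomic emits one point and moves there; concatenation runs left then right;
plain repetition (rep0) runs its block n times.  The two variated
repetitions differ:

* rep1 ("starting point variation"): cycle i starts where the parameter
  symbol maps cycle i-1's *starting* position (cycle 1 starts at the
  incoming position);
* rep2 ("resulting sequence variation"): cycle 1 is the block's output and
  cycle i is cycle i-1's output with the parameter applied pointwise.

After any repetition the threaded position is the last emitted point.
"""

from __future__ import annotations

import math
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .grammar import Grammar, Program

__all__ = ["apply_atomic", "execute", "output_length", "build_atomic_table"]


def build_atomic_table(symbol: str, grammar: "Grammar") -> tuple[int, ...]:
    """The lookup table pos -> symbol(pos) for one atomic symbol."""
    if symbol in ("+0", "+1", "+2", "+3", "-1", "-2", "-3"):
        k = int(symbol)
        return tuple((pos + k) % 8 for pos in range(8))
    if symbol in grammar.axes:
        c = grammar.axes[symbol]
        return tuple((c - pos) % 8 for pos in range(8))
    if symbol == "P":
        return tuple((pos + 4) % 8 for pos in range(8))
    if symbol == "DOUBLE":
        return tuple((2 * pos) % 8 for pos in range(8))
    if symbol == "-DOUBLE":
        return tuple((-2 * pos) % 8 for pos in range(8))
    if symbol == "SQUARE":
        return tuple((pos * pos) % 8 for pos in range(8))
    if symbol == "GAMMA":
        return tuple(math.factorial(pos) % 8 for pos in range(8))
    if symbol in grammar.digit_tables:
        return grammar.digit_tables[symbol]
    from .grammar import GrammarError

    raise GrammarError(f"unknown atomic symbol {symbol!r}")


def apply_atomic(symbol: str, pos: int, grammar: "Grammar") -> int:
    """Apply one atomic transition from ``pos``."""
    try:
        table = grammar.atomic_tables[symbol]
    except KeyError:
        from .grammar import GrammarError

        raise GrammarError(f"symbol {symbol!r} is not in this grammar") from None
    if not 0 <= pos <= 7:
        raise ValueError(f"octagon position must be in 0..7, got {pos}")
    return table[pos]


def execute(p: "Program", anchor: int, grammar: "Grammar") -> tuple[int, ...]:
    """Run a program from ``anchor`` and return the emitted point sequence."""
    if not 0 <= anchor <= 7:
        raise ValueError(f"anchor must be in 0..7, got {anchor}")
    tabs = grammar.atomic_tables
    out: list[int] = []

    def run(node: "Program", pos: int) -> int:
        kind = node.kind
        if kind == "atomic":
            try:
                q = tabs[node.symbol][pos]
            except KeyError:
                from .grammar import GrammarError

                raise GrammarError(
                    f"symbol {node.symbol!r} is not in this grammar"
                ) from None
            out.append(q)
            return q
        if kind == "concat":
            return run(node.right, run(node.left, pos))
        if kind == "rep0":
            for _ in range(node.n):
                pos = run(node.block, pos)
            return pos
        if kind == "rep1":
            ptab = tabs[node.param]
            start = pos
            last = pos
            for j in range(node.n):
                if j:
                    start = ptab[start]
                last = run(node.block, start)
            return last
        # rep2
        ptab = tabs[node.param]
        i0 = len(out)
        last = run(node.block, pos)
        cycle = out[i0:]
        for _ in range(node.n - 1):
            cycle = [ptab[q] for q in cycle]
            out.extend(cycle)
        return cycle[-1]

    run(p, anchor)
    return tuple(out)


def output_length(p: "Program") -> int:
    """Number of points :func:`execute` will emit, computed structurally."""
    return p.output_length()
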
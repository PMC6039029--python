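"""Minimum description length relative to the language of geometry (K_Geo).

The description length of a program charges 2 units per atomic production,
nothing for concatenation (the cost of joining two lists is the sum of
their costs), and ``floor(log2(n))`` extra units for repeating a block n
times.  The ATOMIC parameter of the variated repetitions REP1/REP2 is
itself an atomic production and charges the atomic cost (configurable via
``Grammar.param_cost``).  Logarithms are base 2: costs are bit-like
description-length units.

``K_Geo(anchor, x)`` is the minimum cost over *all* programs that compute
the sequence x from the anchor; it is found by a min-plus evaluation of
the enumeration hypergraph, without materializing any program.
"""

from __future__ import annotations

import math
from typing import Sequence

from .enumeration import ExplanationGraph
from .grammar import Grammar, Program

__all__ = ["program_cost", "sequence_complexity"]


def program_cost(p: Program, param_cost: float = 2.0) -> float:
    """Description length of one derivation tree."""
    if p.kind == "atomic":
        return 2.0
    if p.kind == "concat":
        return program_cost(p.left, param_cost) + program_cost(p.right, param_cost)
    cost = program_cost(p.block, param_cost) + float(int(math.log2(p.n)))
    if p.kind in ("rep1", "rep2"):
        cost += param_cost
    return cost


def sequence_complexity(
    anchor: int,
    sequence: Sequence[int],
    grammar: Grammar,
    graph: ExplanationGraph | None = None,
) -> float:
    """K_Geo: minimal program cost over all explaining programs.

    Raises :class:`ValueError` when no program computes the sequence (this
    cannot happen under the original or extended grammar, whose atomic
    inventory reaches every position from every position).
    """
    graph = graph or ExplanationGraph(grammar)
    node = graph.node_for(anchor, sequence)
    k = graph.min_cost(node)
    if math.isinf(k):
        raise ValueError(
            f"no program in this grammar computes {tuple(sequence)} from {anchor}"
        )
    return k
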
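"""Exhaustive enumeration of the programs that explain an observed sequence.

Every derivation tree p with ``execute(p, anchor) == sequence`` is found by
a dynamic program over *constraint sets*: a node of the DP is a set of
(start position, target subsequence) instances that a candidate subtree
must satisfy simultaneously.  The root holds the single instance
``(anchor, sequence)``; decompositions generate children:

* an atomic leaf must map every instance's start to its single target
  point (intersection of per-instance valid-atomic sets);
* a binary concatenation splits every instance at the same offset k, the
  right part starting at the left part's last point (execution threads the
  current position through emitted points);
* plain repetition (rep0) with count n divides every instance into n
  cycles, each a fresh instance starting at the point emitted just before
  it — the block must satisfy all of them at once;
* starting-point-variated repetition (rep1) is identical except cycle j
  starts at ``param^(j-1)(start)``, a pure function of the parameter
  symbol, giving one child constraint set per parameter;
* sequence-variated repetition (rep2) requires cycles j >= 2 of the
  *observed* span to equal the previous cycle mapped pointwise through the
  parameter (a direct check), and constrains the block by cycle 1 only.

Because execution is deterministic, a constraint set containing two
instances with the same start but different targets admits no tree; such
nodes are pruned immediately, as are nodes whose every decomposition leads
to a pruned child.

The resulting hypergraph (nodes = constraint sets, hyperedges =
decompositions with their grammar productions attached) is shared across
all sequences enumerated through one :class:`ExplanationGraph`, and is
evaluated in four semirings over the same structure: exact big-integer
program counts, materialized program lists, minimum description-length
cost (see :mod:`geolot.complexity`) and probability-weighted inside sums
(see :mod:`geolot.coding`).  Exact posterior sampling of a program given
theta walks the same hyperedges top-down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .grammar import Grammar, GrammarError, Program, atomic, concat, rep0, rep1, rep2
from .semantics import execute
from .trials import Trial, TrialDataset

__all__ = [
    "EnumerationResult",
    "ExplanationGraph",
    "valid_atomics",
    "enumerate_programs",
    "count_programs",
    "brute_force_enumerate",
    "brute_force_many",
    "all_trees",
]

#: Safety cap on materialized programs per sequence (counts stay exact beyond it).
DEFAULT_MATERIALIZE_LIMIT = 10**7


@dataclass
class EnumerationResult:
    """All programs explaining one (anchor, sequence) pair.

    ``programs`` is None when the exact ``count`` exceeds the materialize
    limit; every listed program executes to the target sequence.
    """

    anchor: int
    sequence: tuple[int, ...]
    count: int
    programs: list[Program] | None

    @property
    def key(self):
        return (self.anchor, self.sequence)


def valid_atomics(from_pos: int, to_pos: int, grammar: Grammar) -> set[str]:
    """Atomic symbols a with ``apply_atomic(a, from_pos) == to_pos``."""
    if not (0 <= from_pos <= 7 and 0 <= to_pos <= 7):
        raise ValueError("positions must be in 0..7")
    return {
        sym for sym, tab in grammar.atomic_tables.items() if tab[from_pos] == to_pos
    }


@dataclass(frozen=True)
class _Edge:
    kind: str                    # atomic | concat | rep0 | rep1 | rep2
    tidx: tuple[int, ...]        # production indices contributing theta factors
    const: float                 # uniform repetition-count factor
    children: tuple[int, ...]    # child node ids
    sym: str | None = None       # atomic symbol or REP parameter
    n: int | None = None         # repetition count

    def cost(self, grammar: Grammar) -> float:
        """MDL cost contributed by this decomposition (children excluded)."""
        if self.kind == "atomic":
            return 2.0
        if self.kind == "concat":
            return 0.0
        c = float(int(math.log2(self.n)))
        if self.kind in ("rep1", "rep2"):
            c += grammar.param_cost
        return c


class ExplanationGraph:
    """Shared enumeration hypergraph for one grammar.

    Nodes are created on demand by :meth:`node_for` and shared between all
    sequences queried through the same instance, so datasets with common
    sub-structure (in particular all single-step spans) are deduplicated.
    """

    def __init__(self, grammar: Grammar):
        self.grammar = grammar
        g = grammar
        # per (from, to) pair: tuple of production-index pairs and symbols
        self._atomics_by_pair: dict[tuple[int, int], tuple[tuple[str, int], ...]] = {}
        i_atomic_leaf = g.index["INST:ATOMIC"]
        for s in range(8):
            for t in range(8):
                syms = tuple(
                    (sym, g.index[f"ATOMIC:{sym}"])
                    for sym in g.atomic_symbols
                    if g.atomic_tables[sym][s] == t
                )
                self._atomics_by_pair[(s, t)] = syms
        self._i_atomic_leaf = i_atomic_leaf
        self._i_concat = g.index["INST:INST,INST"]
        self._i_rep = g.index["INST:REP[INST]^n"]
        self._i_rep0 = g.index["REP:REP0"]
        self._i_rep1 = g.index["REP:REP1<ATOMIC>"]
        self._i_rep2 = g.index["REP:REP2<ATOMIC>"]
        self._i_start = g.index["START:[INST]"]
        self._rep_const = 1.0 / g.n_rep_choices
        self._param_syms = tuple(
            (sym, g.index[f"ATOMIC:{sym}"]) for sym in g.atomic_symbols
        )

        self.edges_of: list[list[_Edge]] = []
        self.level: list[int] = []
        self.feasible: list[bool] = []
        self._memo: dict[tuple, int] = {}
        self._compiled = None
        self._counts_cache: tuple[int, list[int]] | None = None
        self._mincost_cache: tuple[int, list[float]] | None = None

    # -- construction -----------------------------------------------------------

    def node_for(self, anchor: int, sequence: Sequence[int]) -> int:
        """Node id for the root constraint {(anchor, sequence)}."""
        seq = tuple(int(p) for p in sequence)
        if len(seq) < 1:
            raise ValueError("sequence must be non-empty")
        if not 0 <= anchor <= 7 or any(not 0 <= p <= 7 for p in seq):
            raise ValueError("positions must be in 0..7")
        return self._node(((int(anchor), seq),))

    def _node(self, instances: tuple[tuple[int, tuple[int, ...]], ...]) -> int:
        key = tuple(sorted(set(instances)))
        nid = self._memo.get(key)
        if nid is not None:
            return nid
        m = len(key[0][1])
        starts: dict[int, tuple[int, ...]] = {}
        dead = False
        for s, x in key:
            if starts.setdefault(s, x) != x:
                dead = True  # deterministic execution: contradictory targets
                break
        edges: list[_Edge] = []
        lvl = 1
        if not dead:
            edges, lvl = self._build_edges(key, m)
        nid = len(self.edges_of)
        self.edges_of.append(edges)
        self.level.append(lvl)
        self.feasible.append(bool(edges))
        self._memo[key] = nid
        self._compiled = None
        return nid

    def _build_edges(self, key, m: int):
        g = self.grammar
        edges: list[_Edge] = []
        lvl = 1
        if m == 1:
            syms = None
            for s, x in key:
                cand = self._atomics_by_pair[(s, x[0])]
                cand_set = {c for c in cand}
                syms = cand_set if syms is None else (syms & cand_set)
            for sym, pidx in self._param_syms:
                if (sym, pidx) in syms:
                    edges.append(
                        _Edge("atomic", (self._i_atomic_leaf, pidx), 1.0, (), sym=sym)
                    )
        # binary concatenations: split every instance at offset k
        for k in range(1, m):
            left = tuple((s, x[:k]) for s, x in key)
            right = tuple((x[k - 1], x[k:]) for s, x in key)
            lid = self._node(left)
            if not self.feasible[lid]:
                continue
            rid = self._node(right)
            if not self.feasible[rid]:
                continue
            edges.append(_Edge("concat", (self._i_concat,), 1.0, (lid, rid)))
            lvl = max(lvl, 1 + self.level[lid], 1 + self.level[rid])
        # repetitions
        if m >= 2:
            lo, hi = g.rep_range
            for n in range(lo, min(hi, m) + 1):
                if m % n:
                    continue
                c = m // n
                # rep0: cycle j starts at the point emitted just before it
                inst0 = []
                for s, x in key:
                    for j in range(n):
                        start = s if j == 0 else x[j * c - 1]
                        inst0.append((start, x[j * c: (j + 1) * c]))
                bid = self._node(tuple(inst0))
                if self.feasible[bid]:
                    edges.append(
                        _Edge(
                            "rep0", (self._i_rep, self._i_rep0), self._rep_const,
                            (bid,), n=n,
                        )
                    )
                    lvl = max(lvl, 1 + self.level[bid])
                # rep1: cycle j starts at param^(j-1)(start)
                for sym, pidx in self._param_syms:
                    tab = g.atomic_tables[sym]
                    inst1 = []
                    for s, x in key:
                        start = s
                        for j in range(n):
                            if j:
                                start = tab[start]
                            inst1.append((start, x[j * c: (j + 1) * c]))
                    bid = self._node(tuple(inst1))
                    if self.feasible[bid]:
                        edges.append(
                            _Edge(
                                "rep1", (self._i_rep, self._i_rep1, pidx),
                                self._rep_const, (bid,), sym=sym, n=n,
                            )
                        )
                        lvl = max(lvl, 1 + self.level[bid])
                # rep2: observed cycles must be pointwise-param images;
                # the block is constrained by cycle 1 only
                for sym, pidx in self._param_syms:
                    tab = g.atomic_tables[sym]
                    ok = all(
                        x[j * c + i] == tab[x[(j - 1) * c + i]]
                        for s, x in key
                        for j in range(1, n)
                        for i in range(c)
                    )
                    if not ok:
                        continue
                    inst2 = tuple((s, x[:c]) for s, x in key)
                    bid = self._node(inst2)
                    if self.feasible[bid]:
                        edges.append(
                            _Edge(
                                "rep2", (self._i_rep, self._i_rep2, pidx),
                                self._rep_const, (bid,), sym=sym, n=n,
                            )
                        )
                        lvl = max(lvl, 1 + self.level[bid])
        return edges, lvl

    # -- semiring evaluations ----------------------------------------------------

    def count(self, node: int) -> int:
        """Exact number of derivation trees at ``node`` (big integers)."""
        return self._counts_upto()[node]

    def _counts_upto(self) -> list[int]:
        n = len(self.edges_of)
        if self._counts_cache is not None and self._counts_cache[0] == n:
            return self._counts_cache[1]
        counts = [0] * n
        for nid in sorted(range(n), key=lambda i: (self.level[i], i)):
            total = 0
            for e in self.edges_of[nid]:
                prod = 1
                for ch in e.children:
                    prod *= counts[ch]
                    if not prod:
                        break
                total += prod
            counts[nid] = total
        self._counts_cache = (n, counts)
        return counts

    def min_cost(self, node: int) -> float:
        """Minimum MDL cost over all trees at ``node`` (inf if none)."""
        return self._min_costs_upto()[node]

    def _min_costs_upto(self) -> list[float]:
        n = len(self.edges_of)
        if self._mincost_cache is not None and self._mincost_cache[0] == n:
            return self._mincost_cache[1]
        g = self.grammar
        cost = [math.inf] * n
        for nid in sorted(range(n), key=lambda i: (self.level[i], i)):
            best = math.inf
            for e in self.edges_of[nid]:
                c = e.cost(g)
                for ch in e.children:
                    c += cost[ch]
                if c < best:
                    best = c
            cost[nid] = best
        self._mincost_cache = (n, cost)
        return cost

    def materialize(self, node: int, limit: int = DEFAULT_MATERIALIZE_LIMIT):
        """All derivation trees at ``node``, or None if more than ``limit``."""
        if self.count(node) > limit:
            return None
        cache: dict[int, list[Program]] = {}

        def build(nid: int) -> list[Program]:
            got = cache.get(nid)
            if got is not None:
                return got
            out: list[Program] = []
            for e in self.edges_of[nid]:
                if e.kind == "atomic":
                    out.append(atomic(e.sym))
                elif e.kind == "concat":
                    lefts = build(e.children[0])
                    rights = build(e.children[1])
                    out.extend(concat(l, r) for l in lefts for r in rights)
                elif e.kind == "rep0":
                    out.extend(rep0(b, e.n) for b in build(e.children[0]))
                elif e.kind == "rep1":
                    out.extend(rep1(b, e.n, e.sym) for b in build(e.children[0]))
                else:
                    out.extend(rep2(b, e.n, e.sym) for b in build(e.children[0]))
            cache[nid] = out
            return out

        return build(node)

    # -- compiled (vectorised) inside evaluation ---------------------------------

    def _compile(self):
        if self._compiled is not None:
            return self._compiled
        n = len(self.edges_of)
        flat: list[tuple[int, int, _Edge]] = []
        for nid in range(n):
            for e in self.edges_of[nid]:
                flat.append((self.level[nid], nid, e))
        flat.sort(key=lambda t: (t[0], t[1]))
        E = len(flat)
        npad = self.grammar.n_productions
        e_target = np.empty(E, dtype=np.int64)
        e_f = np.full((E, 3), npad, dtype=np.int64)
        e_const = np.empty(E, dtype=np.float64)
        e_c1 = np.full(E, n, dtype=np.int64)
        e_c2 = np.full(E, n, dtype=np.int64)
        node_start = np.zeros(n + 1, dtype=np.int64)
        levels: list[tuple[int, int]] = []
        prev_level = None
        for i, (lvl, nid, e) in enumerate(flat):
            e_target[i] = nid
            for j, t in enumerate(e.tidx):
                e_f[i, j] = t
            e_const[i] = e.const
            if e.children:
                e_c1[i] = e.children[0]
                if len(e.children) > 1:
                    e_c2[i] = e.children[1]
            if lvl != prev_level:
                levels.append((i, i))
                prev_level = lvl
            levels[-1] = (levels[-1][0], i + 1)
        # contiguous per-node slices (flat is sorted by (level, node))
        counts_per_node = np.zeros(n, dtype=np.int64)
        for lvl, nid, e in flat:
            counts_per_node[nid] += 1
        order = sorted(range(n), key=lambda i: (self.level[i], i))
        pos = 0
        starts = np.zeros(n, dtype=np.int64)
        ends = np.zeros(n, dtype=np.int64)
        for nid in order:
            starts[nid] = pos
            pos += counts_per_node[nid]
            ends[nid] = pos
        self._compiled = {
            "edges": [e for _, _, e in flat],
            "target": e_target,
            "f": e_f,
            "const": e_const,
            "c1": e_c1,
            "c2": e_c2,
            "levels": levels,
            "starts": starts,
            "ends": ends,
            "n_nodes": n,
        }
        return self._compiled

    def inside(self, theta_vec: np.ndarray):
        """Probability-weighted sums of all trees at every node.

        Returns ``(vals, edge_vals)``: per-node inside values and per-edge
        contributions under the given production-probability vector.
        """
        c = self._compile()
        n = c["n_nodes"]
        th = np.append(np.asarray(theta_vec, dtype=float), 1.0)
        fprod = th[c["f"][:, 0]] * th[c["f"][:, 1]] * th[c["f"][:, 2]] * c["const"]
        vals_ext = np.zeros(n + 1)
        vals_ext[n] = 1.0
        edge_vals = np.empty(len(fprod))
        for s, e in c["levels"]:
            ev = fprod[s:e] * vals_ext[c["c1"][s:e]] * vals_ext[c["c2"][s:e]]
            edge_vals[s:e] = ev
            vals_ext[:n] += np.bincount(c["target"][s:e], weights=ev, minlength=n)
        return vals_ext[:n], edge_vals

    def sample(
        self,
        node: int,
        vals: np.ndarray,
        edge_vals: np.ndarray,
        rng: np.random.Generator,
        counts_out: np.ndarray | None = None,
    ) -> Program:
        """Draw one tree at ``node`` with probability proportional to its
        program probability, using precomputed :meth:`inside` values.

        When ``counts_out`` is given, production usage (theta-factor
        indices) of the sampled tree is accumulated into it; the START
        production is the caller's responsibility.
        """
        c = self._compile()
        starts, ends, edges = c["starts"], c["ends"], c["edges"]

        def draw(nid: int) -> Program:
            s, e = starts[nid], ends[nid]
            total = vals[nid]
            if total <= 0.0 or s == e:
                raise GrammarError("no explaining program with positive probability")
            r = rng.random() * total
            acc = 0.0
            pick = e - 1
            for i in range(s, e):
                acc += edge_vals[i]
                if r <= acc:
                    pick = i
                    break
            edge = edges[pick]
            if counts_out is not None:
                for t in edge.tidx:
                    counts_out[t] += 1
            if edge.kind == "atomic":
                return atomic(edge.sym)
            if edge.kind == "concat":
                left = draw(edge.children[0])
                return concat(left, draw(edge.children[1]))
            block = draw(edge.children[0])
            if edge.kind == "rep0":
                return rep0(block, edge.n)
            if edge.kind == "rep1":
                return rep1(block, edge.n, edge.sym)
            return rep2(block, edge.n, edge.sym)

        return draw(node)


# ---------------------------------------------------------------------------
# Functional surface
# ---------------------------------------------------------------------------

def enumerate_programs(
    anchor: int,
    sequence: Sequence[int],
    grammar: Grammar,
    materialize_limit: int = DEFAULT_MATERIALIZE_LIMIT,
    graph: ExplanationGraph | None = None,
) -> EnumerationResult:
    """All derivation trees that compute ``sequence`` from ``anchor``.

    Distinct trees are counted distinctly (all concatenation associations).
    If the exact count exceeds ``materialize_limit`` the program list is
    withheld but the count is still exact.
    """
    graph = graph or ExplanationGraph(grammar)
    node = graph.node_for(anchor, sequence)
    count = graph.count(node)
    programs = graph.materialize(node, materialize_limit) if count <= materialize_limit else None
    return EnumerationResult(int(anchor), tuple(int(p) for p in sequence), count, programs)


def count_programs(
    anchor: int,
    sequence: Sequence[int],
    grammar: Grammar,
    graph: ExplanationGraph | None = None,
) -> int:
    """Exact number of explaining programs, without materializing them."""
    graph = graph or ExplanationGraph(grammar)
    return graph.count(graph.node_for(anchor, sequence))


# ---------------------------------------------------------------------------
# Brute-force oracle: exhaustive grammar expansion, then filter by execution
# ---------------------------------------------------------------------------

_TREE_CACHE: dict[tuple, list[Program]] = {}


def all_trees(length: int, grammar: Grammar) -> list[Program]:
    """Every derivation tree with the given output length (shared subtrees).

    Grows combinatorially; intended for small lengths as a test oracle.
    """
    key = (grammar.atomic_symbols, grammar.rep_range, length)
    got = _TREE_CACHE.get(key)
    if got is not None:
        return got
    if length == 1:
        trees = [atomic(s) for s in grammar.atomic_symbols]
    else:
        trees = []
        for k in range(1, length):
            lefts = all_trees(k, grammar)
            rights = all_trees(length - k, grammar)
            trees.extend(concat(l, r) for l in lefts for r in rights)
        lo, hi = grammar.rep_range
        for n in range(lo, min(hi, length) + 1):
            if length % n:
                continue
            blocks = all_trees(length // n, grammar)
            trees.extend(rep0(b, n) for b in blocks)
            for sym in grammar.atomic_symbols:
                trees.extend(rep1(b, n, sym) for b in blocks)
            for sym in grammar.atomic_symbols:
                trees.extend(rep2(b, n, sym) for b in blocks)
    _TREE_CACHE[key] = trees
    return trees


def brute_force_enumerate(
    anchor: int,
    sequence: Sequence[int],
    grammar: Grammar,
    max_len: int = 5,
) -> EnumerationResult:
    """Test oracle: generate every tree of matching output length and keep
    those that execute to the target.  Refuses sequences longer than
    ``max_len`` (capped at 5)."""
    seq = tuple(int(p) for p in sequence)
    if max_len > 5:
        raise ValueError("brute force is limited to max_len <= 5")
    if len(seq) > max_len:
        raise ValueError(f"sequence length {len(seq)} exceeds max_len {max_len}")
    progs = [
        t for t in all_trees(len(seq), grammar) if execute(t, anchor, grammar) == seq
    ]
    return EnumerationResult(int(anchor), seq, len(progs), progs)


def brute_force_many(
    inputs: Iterable[tuple[int, Sequence[int]]],
    grammar: Grammar,
    max_len: int = 5,
) -> dict[tuple[int, tuple[int, ...]], list[Program]]:
    """Batched oracle: one execution pass per (length, anchor) group."""
    targets: dict[tuple[int, int], set[tuple[int, ...]]] = {}
    keys = []
    for anchor, seq in inputs:
        seq = tuple(int(p) for p in seq)
        if len(seq) > max_len or max_len > 5:
            raise ValueError("brute force is limited to lengths <= 5")
        keys.append((anchor, seq))
        targets.setdefault((len(seq), anchor), set()).add(seq)
    out: dict[tuple[int, tuple[int, ...]], list[Program]] = {k: [] for k in keys}
    for (length, anchor), seqs in sorted(targets.items()):
        for t in all_trees(length, grammar):
            got = execute(t, anchor, grammar)
            if got in seqs:
                out[(anchor, got)].append(t)
    return out
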
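"""The language of geometry (Geo): grammar, programs and production counting.

Geo is a context-free grammar whose programs describe movements on the eight
labelled vertices of a regular octagon (the alphabet ``Sigma = {0..7}``).  A
program is a *derivation tree* of the grammar: atomic moves and symmetries at
the leaves, combined by binary concatenation and by three repetition
operators (plain repetition, repetition with starting-point variation, and
repetition with pointwise variation of the resulting sequence).

The grammar has four nonterminals::

    START  -> [INST]
    INST   -> ATOMIC | INST,INST | REP[INST]^n      (n in rep_range)
    REP    -> REP0 | REP1<ATOMIC> | REP2<ATOMIC>
    ATOMIC -> one of the atomic symbols

The original inventory holds twelve geometric atomic symbols (rotations by
0..3 steps in either direction plus five symmetries).  An extended inventory
adds eleven deliberately implausible "ad-hoc" symbols (digits of famous
constants, squaring, doubling...) used to test whether Bayesian inference
prunes productions that have no cognitive justification.

Attaching a probability vector ``theta`` (normalised within each
nonterminal) turns the grammar into a PCFG; the probability of a program is
the product of ``theta_r`` over the productions used in its derivation,
times a uniform factor for each repetition count.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping

__all__ = [
    "ORIGINAL_ATOMIC_SYMBOLS",
    "ADHOC_ATOMIC_SYMBOLS",
    "DEFAULT_AXES",
    "DIGIT_TABLES",
    "Production",
    "Grammar",
    "Program",
    "Theta",
    "GrammarError",
    "ParseError",
    "build_grammar",
    "parse_program",
    "serialize_program",
    "production_counts",
    "atomic",
    "concat",
    "rep0",
    "rep1",
    "rep2",
]

#: Atomic symbols of the original inventory, in presentation order:
#: anticlockwise moves, stay, clockwise moves, symmetries.
ORIGINAL_ATOMIC_SYMBOLS = (
    "-1", "-2", "-3", "+0", "+1", "+2", "+3", "A", "B", "H", "V", "P",
)

#: Ad-hoc atomic symbols of the extended inventory.
ADHOC_ATOMIC_SYMBOLS = (
    "DOUBLE", "-DOUBLE", "SQUARE", "GAMMA",
    "PI", "EULER", "GOLD", "PYTH", "KHINCHIN", "GLAISHER", "CHAITIN",
)

_FAMILY_OF_ATOMIC = {
    "-1": "acw", "-2": "acw", "-3": "acw",
    "+0": "stay",
    "+1": "cw", "+2": "cw", "+3": "cw",
    "A": "symmetry", "B": "symmetry", "H": "symmetry", "V": "symmetry",
    "P": "symmetry",
    **{s: "adhoc" for s in ADHOC_ATOMIC_SYMBOLS},
}

#: Default reflection constants c (reflection maps pos -> (c - pos) mod 8).
#: A is pinned to c=5 by the worked alternation example (A swaps 6 and 7);
#: B, H, V are conventional and configurable.
DEFAULT_AXES = {"A": 5, "B": 1, "H": 7, "V": 3}

# Leading base-10 digits of each constant (index 0 = leading printed digit),
# reduced mod 8 to yield octagon positions, e.g. PI(0) = 3, PI(1) = 1.
# CHAITIN uses the decimal expansion 0.0078749969... of the published
# 84-bit-programs approximation of a Chaitin Omega number; this table is an
# editable fixture (replace via Grammar.digit_tables / config "digits").
_RAW_DIGITS = {
    "PI":       (3, 1, 4, 1, 5, 9, 2, 6),
    "EULER":    (2, 7, 1, 8, 2, 8, 1, 8),
    "GOLD":     (1, 6, 1, 8, 0, 3, 3, 9),
    "PYTH":     (1, 4, 1, 4, 2, 1, 3, 5),
    "KHINCHIN": (2, 6, 8, 5, 4, 5, 2, 0),
    "GLAISHER": (1, 2, 8, 2, 4, 2, 7, 1),
    "CHAITIN":  (0, 0, 7, 8, 7, 4, 9, 9),
}

DIGIT_TABLES = {k: tuple(d % 8 for d in v) for k, v in _RAW_DIGITS.items()}


class GrammarError(ValueError):
    """Invalid grammar configuration or symbol not in the grammar."""


class ParseError(ValueError):
    """Malformed program notation; carries the offending position."""

    def __init__(self, message: str, pos: int):
        super().__init__(f"{message} (at position {pos})")
        self.pos = pos


@dataclass(frozen=True)
class Production:
    """One rewrite rule of the grammar.

    ``id`` is the stable string ``"LHS:label"`` (e.g. ``"ATOMIC:+1"``) used
    to key theta vectors and result files across runs.
    """

    id: str
    lhs: str
    rhs_kind: str
    symbol: str | None = None
    family: str = "basic"


@dataclass(frozen=True)
class Program:
    """A derivation tree of the grammar.

    ``kind`` is one of ``atomic``, ``concat``, ``rep0``, ``rep1``, ``rep2``;
    only the fields relevant to the kind are set.  Use the module-level
    constructors :func:`atomic`, :func:`concat`, :func:`rep0`, :func:`rep1`,
    :func:`rep2`.
    """

    kind: str
    symbol: str | None = None
    left: "Program | None" = None
    right: "Program | None" = None
    block: "Program | None" = None
    n: int | None = None
    param: str | None = None

    def output_length(self) -> int:
        """Number of octagon points the program emits when executed."""
        if self.kind == "atomic":
            return 1
        if self.kind == "concat":
            return self.left.output_length() + self.right.output_length()
        return self.n * self.block.output_length()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Program({serialize_program(self)!r})"


def atomic(symbol: str) -> Program:
    return Program(kind="atomic", symbol=symbol)


def concat(left: Program, right: Program) -> Program:
    return Program(kind="concat", left=left, right=right)


def rep0(block: Program, n: int) -> Program:
    return Program(kind="rep0", block=block, n=n)


def rep1(block: Program, n: int, param: str) -> Program:
    return Program(kind="rep1", block=block, n=n, param=param)


def rep2(block: Program, n: int, param: str) -> Program:
    return Program(kind="rep2", block=block, n=n, param=param)


class Grammar:
    """The Geo production inventory plus its interpretation constants.

    Parameters
    ----------
    include_adhoc:
        Add the eleven ad-hoc atomic productions to the original twelve.
    axes:
        Mapping from the four reflection symbols to their odd reflection
        constants (distinct values in {1,3,5,7}).
    rep_range:
        Inclusive ``(lo, hi)`` interval of admissible repetition counts,
        within [2, 8].
    digit_tables:
        Per-constant tuple of 8 octagon positions; defaults to the built-in
        leading-decimal-digit tables.
    param_cost:
        MDL cost charged for the ATOMIC parameter of REP1/REP2 (see
        :mod:`geolot.complexity`).
    """

    def __init__(
        self,
        include_adhoc: bool = False,
        axes: Mapping[str, int] | None = None,
        rep_range: tuple[int, int] = (2, 8),
        digit_tables: Mapping[str, tuple[int, ...]] | None = None,
        param_cost: float = 2.0,
    ):
        axes = dict(DEFAULT_AXES if axes is None else axes)
        if set(axes) != {"A", "B", "H", "V"}:
            raise GrammarError(f"axes must map exactly A,B,H,V; got {sorted(axes)}")
        vals = list(axes.values())
        if any(v % 2 == 0 for v in vals) or len(set(vals)) != 4:
            raise GrammarError(
                f"axis constants must be distinct odd values in {{1,3,5,7}}; got {axes}"
            )
        lo, hi = int(rep_range[0]), int(rep_range[1])
        if not (2 <= lo <= hi <= 8):
            raise GrammarError(f"rep_range must lie within [2, 8]; got {rep_range}")

        self.include_adhoc = bool(include_adhoc)
        self.axes = axes
        self.rep_range = (lo, hi)
        self.param_cost = float(param_cost)
        tables = dict(DIGIT_TABLES if digit_tables is None else digit_tables)
        for name, tab in tables.items():
            tab = tuple(int(d) for d in tab)
            if len(tab) != 8 or any(not 0 <= d <= 7 for d in tab):
                raise GrammarError(f"digit table for {name} must be 8 positions in 0..7")
            tables[name] = tab
        self.digit_tables = tables

        self.atomic_symbols: tuple[str, ...] = ORIGINAL_ATOMIC_SYMBOLS + (
            ADHOC_ATOMIC_SYMBOLS if self.include_adhoc else ()
        )

        prods: list[Production] = [
            Production("START:[INST]", "START", "start", family="start"),
            Production("INST:ATOMIC", "INST", "atomic_leaf", family="basic"),
            Production("INST:INST,INST", "INST", "concat", family="concat"),
            Production("INST:REP[INST]^n", "INST", "rep_apply", family="rep"),
            Production("REP:REP0", "REP", "rep0", family="rep"),
            Production("REP:REP1<ATOMIC>", "REP", "rep1", family="rep"),
            Production("REP:REP2<ATOMIC>", "REP", "rep2", family="rep"),
        ]
        for sym in self.atomic_symbols:
            prods.append(
                Production(
                    f"ATOMIC:{sym}", "ATOMIC", "atomic_symbol",
                    symbol=sym, family=_FAMILY_OF_ATOMIC[sym],
                )
            )
        self.productions: tuple[Production, ...] = tuple(prods)
        self.production_ids: tuple[str, ...] = tuple(p.id for p in prods)
        self.index: dict[str, int] = {p.id: i for i, p in enumerate(prods)}
        self.blocks: dict[str, tuple[int, ...]] = {}
        for i, p in enumerate(prods):
            self.blocks.setdefault(p.lhs, ())
            self.blocks[p.lhs] += (i,)
        self.n_productions = len(prods)
        self.n_rep_choices = hi - lo + 1

        # permutation/lookup tables for every atomic symbol (semantics kernel)
        from . import semantics  # local import to avoid a cycle

        self.atomic_tables: dict[str, tuple[int, ...]] = {
            s: semantics.build_atomic_table(s, self) for s in self.atomic_symbols
        }

    # -- identity / serialization -------------------------------------------------

    def config(self) -> dict:
        """JSON-serializable configuration that fully determines the grammar."""
        return {
            "include_adhoc": self.include_adhoc,
            "rep_range": list(self.rep_range),
            "axes": dict(sorted(self.axes.items())),
            "digits": {k: list(v) for k, v in sorted(self.digit_tables.items())},
            "param_cost": self.param_cost,
        }

    def hash(self) -> str:
        import hashlib

        blob = json.dumps(self.config(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_config(cls, cfg: Mapping) -> "Grammar":
        return cls(
            include_adhoc=cfg.get("include_adhoc", False),
            axes=cfg.get("axes"),
            rep_range=tuple(cfg.get("rep_range", (2, 8))),
            digit_tables={k: tuple(v) for k, v in cfg["digits"].items()}
            if "digits" in cfg
            else None,
            param_cost=cfg.get("param_cost", 2.0),
        )

    # -- theta helpers ------------------------------------------------------------

    def uniform_theta(self) -> "Theta":
        """Per-nonterminal uniform production probabilities."""
        values = {}
        for lhs, idxs in self.blocks.items():
            for i in idxs:
                values[self.productions[i].id] = 1.0 / len(idxs)
        return Theta(values)

    def theta_vector(self, theta: "Theta | Mapping[str, float]"):
        import numpy as np

        vals = theta.values if isinstance(theta, Theta) else theta
        try:
            return np.array([vals[pid] for pid in self.production_ids], dtype=float)
        except KeyError as e:  # pragma: no cover - defensive
            raise GrammarError(f"theta is missing production {e.args[0]!r}") from None

    def theta_from_vector(self, vec) -> "Theta":
        return Theta({pid: float(v) for pid, v in zip(self.production_ids, vec)})

    def family_map(self) -> dict[str, str]:
        return {p.id: p.family for p in self.productions}

    def __repr__(self) -> str:  # pragma: no cover
        kind = "extended" if self.include_adhoc else "original"
        return f"Grammar({kind}, {self.n_productions} productions)"


@dataclass
class Theta:
    """Per-production probabilities, normalised within each nonterminal."""

    values: dict[str, float]

    def __getitem__(self, pid: str) -> float:
        return self.values[pid]

    def __iter__(self) -> Iterator[str]:
        return iter(self.values)

    def validate(self, grammar: Grammar, tol: float = 1e-9) -> None:
        for lhs, idxs in grammar.blocks.items():
            s = sum(self.values[grammar.productions[i].id] for i in idxs)
            if abs(s - 1.0) > tol:
                raise ValueError(f"theta block {lhs} sums to {s}, expected 1")


def build_grammar(
    include_adhoc: bool = False,
    axes: Mapping[str, int] | None = None,
    rep_range: tuple[int, int] = (2, 8),
    **kwargs,
) -> Grammar:
    """Build the Geo grammar (original, or extended with ad-hoc productions)."""
    return Grammar(include_adhoc=include_adhoc, axes=axes, rep_range=rep_range, **kwargs)


# ---------------------------------------------------------------------------
# Program notation
#
#   program := '[' elem (',' elem)* ']'
#   elem    := program | rep | SYMBOL
#   rep     := 'REP'  program '^' INT
#            | 'REP1' '<' SYMBOL '>' program '^' INT
#            | 'REP2' '<' SYMBOL '>' program '^' INT
#
# A flat comma list is read as the left-associated concatenation; nested
# bracket groups make any other association expressible, so serialization
# (which flattens maximal left spines and brackets everything else)
# round-trips every derivation tree.
# ---------------------------------------------------------------------------

_ALL_SYMBOLS = ORIGINAL_ATOMIC_SYMBOLS + ADHOC_ATOMIC_SYMBOLS
_SYMBOL_RE = "|".join(
    re.escape(s) for s in sorted(_ALL_SYMBOLS, key=len, reverse=True)
)
_TOKEN_RE = re.compile(
    rf"\s*(?:(?P<rep>REP[12]?)|(?P<sym>{_SYMBOL_RE})|(?P<int>\d+)|(?P<punct>[\[\],^<>]))"
)


class _Parser:
    def __init__(self, text: str, grammar: Grammar | None):
        self.text = text
        self.pos = 0
        self.grammar = grammar
        self.symbols = set(grammar.atomic_symbols if grammar else _ALL_SYMBOLS)
        self.rep_range = grammar.rep_range if grammar else (2, 8)

    def error(self, msg: str):
        raise ParseError(msg, self.pos)

    def peek(self) -> tuple[str, str]:
        m = _TOKEN_RE.match(self.text, self.pos)
        if m is None:
            rest = self.text[self.pos:].strip()
            if rest:
                self.error(f"unrecognized token {rest.split()[0]!r}")
            return "", ""
        return m.lastgroup, m.group(m.lastgroup)  # type: ignore[return-value]

    def take(self) -> tuple[str, str]:
        m = _TOKEN_RE.match(self.text, self.pos)
        if m is None:
            self.error("unexpected end of input" if not self.text[self.pos:].strip()
                       else f"unrecognized token {self.text[self.pos:].strip()[:8]!r}")
        self.pos = m.end()
        return m.lastgroup, m.group(m.lastgroup)  # type: ignore[return-value]

    def expect(self, value: str):
        kind, tok = self.take()
        if tok != value:
            self.error(f"expected {value!r}, found {tok!r}")

    def parse(self) -> Program:
        p = self.parse_list()
        if self.text[self.pos:].strip():
            self.error("trailing input after program")
        return p

    def parse_list(self) -> Program:
        self.expect("[")
        items = [self.parse_elem()]
        while True:
            kind, tok = self.take()
            if tok == "]":
                break
            if tok != ",":
                self.error(f"expected ',' or ']', found {tok!r}")
            items.append(self.parse_elem())
        prog = items[0]
        for item in items[1:]:
            prog = concat(prog, item)
        return prog

    def parse_elem(self) -> Program:
        kind, tok = self.peek()
        if kind == "punct":
            if tok != "[":
                self.error("expected an instruction")
            return self.parse_list()
        if kind == "rep":
            return self.parse_rep()
        if kind == "sym":
            _, sym = self.take()
            if sym not in self.symbols:
                self.error(f"symbol {sym!r} not in grammar")
            return atomic(sym)
        self.error("expected an instruction")

    def parse_rep(self) -> Program:
        _, rep_tok = self.take()
        param = None
        if rep_tok in ("REP1", "REP2"):
            self.expect("<")
            kind, param = self.take()
            if kind != "sym" or param not in self.symbols:
                self.error(f"invalid REP parameter {param!r}")
            self.expect(">")
        block = self.parse_list()
        self.expect("^")
        kind, tok = self.take()
        if kind != "int":
            self.error(f"expected repetition count, found {tok!r}")
        n = int(tok)
        lo, hi = self.rep_range
        if not lo <= n <= hi:
            self.error(f"repetition count {n} outside [{lo}, {hi}]")
        if rep_tok == "REP":
            return rep0(block, n)
        if rep_tok == "REP1":
            return rep1(block, n, param)
        return rep2(block, n, param)


def parse_program(text: str, grammar: Grammar | None = None) -> Program:
    """Parse program notation like ``"[REP[+1]^8]"`` into a derivation tree.

    With a ``grammar``, symbols and repetition counts are validated against
    its inventory and ``rep_range``; without one, the full extended symbol
    set and the default range [2, 8] are accepted.
    """
    return _Parser(text, grammar).parse()


def _elem_str(p: Program) -> str:
    if p.kind == "atomic":
        return p.symbol
    if p.kind == "concat":
        return serialize_program(p)
    inner = serialize_program(p.block)
    if p.kind == "rep0":
        return f"REP{inner}^{p.n}"
    tag = "REP1" if p.kind == "rep1" else "REP2"
    return f"{tag}<{p.param}>{inner}^{p.n}"


def serialize_program(p: Program) -> str:
    """Canonical text for a derivation tree; round-trips with parse_program."""
    spine: list[Program] = []
    while p.kind == "concat":
        spine.append(p.right)
        p = p.left
    spine.append(p)
    return "[" + ", ".join(_elem_str(q) for q in reversed(spine)) + "]"


def production_counts(p: Program, grammar: Grammar) -> dict[str, int]:
    """Occurrences f_r(p) of every production r in the derivation tree of p.

    Includes the START expansion, every INST-level choice, the REP-variant
    choices, the ATOMIC symbol choices, and the ATOMIC expansion of
    REP1/REP2 parameters.  Unknown symbols (e.g. an ad-hoc symbol under the
    original grammar) raise :class:`GrammarError`.
    """
    counts = dict.fromkeys(grammar.production_ids, 0)

    def visit_atomic_symbol(sym: str):
        pid = f"ATOMIC:{sym}"
        if pid not in counts:
            raise GrammarError(f"symbol {sym!r} is not a production of this grammar")
        counts[pid] += 1

    def visit(q: Program):
        if q.kind == "atomic":
            counts["INST:ATOMIC"] += 1
            visit_atomic_symbol(q.symbol)
        elif q.kind == "concat":
            counts["INST:INST,INST"] += 1
            visit(q.left)
            visit(q.right)
        else:
            counts["INST:REP[INST]^n"] += 1
            lo, hi = grammar.rep_range
            if not lo <= q.n <= hi:
                raise GrammarError(f"repetition count {q.n} outside rep_range {grammar.rep_range}")
            if q.kind == "rep0":
                counts["REP:REP0"] += 1
            elif q.kind == "rep1":
                counts["REP:REP1<ATOMIC>"] += 1
                visit_atomic_symbol(q.param)
            else:
                counts["REP:REP2<ATOMIC>"] += 1
                visit_atomic_symbol(q.param)
            visit(q.block)

    counts["START:[INST]"] += 1
    visit(p)
    return counts
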
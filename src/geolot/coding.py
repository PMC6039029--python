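"""Algorithmic probability P_Geo and the empirical Coding-Theorem test.

``P_Geo(x) = P(x | Geo, theta)`` is proportional to the sum of program
probabilities over *all* programs that compute the sequence x from its
anchor (the normalisation factor over Sigma+ is irrelevant for the
relationship under test and is not computed).  The sum is evaluated by the
probability-weighted (inside) form of the enumeration DP, so no program
list is ever materialized.

Levin's Coding Theorem states that for a universal prefix machine,
``log(1/P(x))`` equals the Kolmogorov complexity ``K(x)`` up to an
additive constant.  Geo is not Turing-complete, so the theorem does not
apply; the experiment here measures whether the inverse-logarithmic
relationship nevertheless holds empirically: sample unique (anchor,
sequence) records of a given length, compute (K_Geo, P_Geo) for each,
average P within each distinct K value, and fit an ordinary least squares
regression of log10(mean P) on K.  A strongly negative slope with high
R-squared reproduces the relationship.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .complexity import sequence_complexity
from .enumeration import ExplanationGraph
from .grammar import Grammar, Theta

__all__ = [
    "CodingRecord",
    "CodingFit",
    "sequence_probability",
    "sample_unique_records",
    "coding_theorem_experiment",
]


@dataclass(frozen=True)
class CodingRecord:
    """One sequence with its complexity and (unnormalized) probability."""

    anchor: int
    sequence: tuple[int, ...]
    complexity: float
    probability: float


@dataclass
class CodingFit:
    """Per-length summary of the complexity/probability relationship.

    ``points`` maps each distinct complexity value present in the sample
    to (mean probability, number of sequences).  ``defined`` is False when
    fewer than two distinct complexity values occurred, in which case the
    regression fields are NaN.
    """

    length: int
    n_sequences: int
    points: dict[float, tuple[float, int]]
    slope: float
    intercept: float
    r_squared: float
    defined: bool = True
    complexity_histogram: dict[float, int] = field(default_factory=dict)
    log10_probabilities: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "length": self.length,
            "n_sequences": self.n_sequences,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "defined": self.defined,
            "points": [
                {"K": k, "mean_P": p, "count": c}
                for k, (p, c) in sorted(self.points.items())
            ],
        }


def sequence_probability(
    anchor: int,
    sequence: Sequence[int],
    grammar: Grammar,
    theta: Theta | Mapping[str, float],
    graph: ExplanationGraph | None = None,
) -> float:
    """Unnormalized P_Geo: sum of program probabilities over all explaining
    programs, via the inside evaluation of the enumeration hypergraph."""
    graph = graph or ExplanationGraph(grammar)
    node = graph.node_for(anchor, sequence)
    vec = grammar.theta_vector(theta)
    vals, _ = graph.inside(vec)
    start = vec[grammar.index["START:[INST]"]]
    return float(vals[node] * start)


def sample_unique_records(
    length: int,
    max_n: int = 10000,
    rng: np.random.Generator | int | None = None,
) -> list[tuple[int, tuple[int, ...]]]:
    """Unique random (anchor, sequence) pairs of a given length.

    Exhaustive (all ``8**(length+1)`` pairs, in order) whenever that many
    pairs do not exceed ``max_n``; otherwise a uniform sample without
    replacement of exactly ``max_n`` pairs.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    total = 8 ** (length + 1)

    def decode(code: int) -> tuple[int, tuple[int, ...]]:
        digits = []
        for _ in range(length + 1):
            digits.append(code % 8)
            code //= 8
        return digits[-1], tuple(reversed(digits[:-1]))

    if total <= max_n:
        return [decode(i) for i in range(total)]
    if total <= 2**22:
        codes = rng.choice(total, size=max_n, replace=False)
        return [decode(int(i)) for i in codes]
    # huge spaces: draw batches and deduplicate (uniform without replacement)
    seen: dict[int, None] = {}
    while len(seen) < max_n:
        for code in rng.integers(0, total, size=2 * (max_n - len(seen))):
            if len(seen) >= max_n:
                break
            seen.setdefault(int(code), None)
    return [decode(i) for i in list(seen)[:max_n]]


def coding_theorem_experiment(
    theta: Theta | Mapping[str, float],
    grammar: Grammar,
    lengths: Sequence[int],
    max_n: int = 10000,
    rng: np.random.Generator | int | None = None,
    graph: ExplanationGraph | None = None,
    return_records: bool = False,
):
    """Run the Coding-Theorem experiment for each sequence length.

    For each length: sample unique records, compute K_Geo (min-cost DP) and
    P_Geo (inside DP) per record, average P within identical K, and fit
    log10(mean P) = slope * K + intercept by OLS.  Returns a list of
    :class:`CodingFit` (and the raw per-length records when requested).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    graph = graph or ExplanationGraph(grammar)
    vec = grammar.theta_vector(theta)
    start = vec[grammar.index["START:[INST]"]]
    fits: list[CodingFit] = []
    all_records: dict[int, list[CodingRecord]] = {}
    for length in lengths:
        pairs = sample_unique_records(length, max_n=max_n, rng=rng)
        nodes = [graph.node_for(a, s) for a, s in pairs]
        vals, _ = graph.inside(vec)
        costs = graph._min_costs_upto()
        records = [
            CodingRecord(a, s, float(costs[nid]), float(vals[nid] * start))
            for (a, s), nid in zip(pairs, nodes)
        ]
        all_records[length] = records
        fits.append(fit_coding_relation(records, length))
    if return_records:
        return fits, all_records
    return fits


def fit_coding_relation(records: Sequence[CodingRecord], length: int) -> CodingFit:
    """Group records by identical complexity and fit log10(mean P) on K."""
    groups: dict[float, list[float]] = {}
    for r in records:
        groups.setdefault(r.complexity, []).append(r.probability)
    points = {k: (float(np.mean(ps)), len(ps)) for k, ps in groups.items()}
    hist = {k: c for k, (_, c) in sorted(points.items())}
    log_p = [math.log10(r.probability) for r in records if r.probability > 0]
    ks = sorted(points)
    if len(ks) < 2:
        return CodingFit(
            length, len(records), points,
            math.nan, math.nan, math.nan, defined=False,
            complexity_histogram=hist, log10_probabilities=log_p,
        )
    x = np.array(ks, dtype=float)
    y = np.array([math.log10(points[k][0]) for k in ks])
    res = stats.linregress(x, y)
    return CodingFit(
        length, len(records), points,
        float(res.slope), float(res.intercept), float(res.rvalue**2),
        defined=True, complexity_histogram=hist, log10_probabilities=log_p,
    )
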
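"""Gibbs sampling of production probabilities for the Geo PCFG.

The model: observed concepts ``D = (d_1..d_n)`` are sequences, each
explained by some program ``p_i`` of the grammar; programs are drawn from
the PCFG prior ``P(p | theta) = prod_r theta_r^{f_r(p)}`` (times a uniform
factor over repetition counts), the likelihood is exact match
(``P(d | p) = 1`` iff p computes d), and ``theta`` carries a Dirichlet
prior — one independent Dirichlet per nonterminal block, since a PCFG
normalises production probabilities within each left-hand side.

Inference alternates the two exact conditionals:

1. ``p_i | d_i, theta``: a multinomial over *all* programs that compute
   d_i.  This package samples it by top-down stochastic backtracking
   through the inside-weighted enumeration hypergraph, which draws from
   exactly that multinomial without materializing the program list (the
   explicit multinomial over a materialized enumeration is also provided
   as :func:`sample_program_posterior`).
2. ``theta | Prog``: per-block Dirichlet with concentrations updated by
   the production counts of the sampled programs.

Chains are initialized at per-block uniform theta and use deterministic
seed substreams (chain c draws from ``seed + c``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .enumeration import EnumerationResult, ExplanationGraph
from .grammar import Grammar, Program, Theta, production_counts
from .trials import Trial, TrialDataset

__all__ = [
    "InferenceConfig",
    "PosteriorResult",
    "UnexplainableTrialError",
    "program_log_prob",
    "sample_program_posterior",
    "sample_theta",
    "gibbs_infer",
    "summarize_posterior",
    "group_by_family",
    "compare_populations",
    "compare_all_productions",
    "ProductionInference",
]


class UnexplainableTrialError(ValueError):
    """A trial admits no explaining program under the grammar."""


@dataclass
class InferenceConfig:
    """MCMC settings.

    ``alpha`` is the Dirichlet concentration: a scalar (broadcast to every
    production) or a per-production-id mapping; the default unit
    concentration makes the prior uniform on each block's simplex.
    """

    alpha: float | Mapping[str, float] = 1.0
    n_steps: int = 50
    burn_in: int = 10
    n_chains: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if not 0 <= self.burn_in < self.n_steps:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_steps")

    def alpha_vector(self, grammar: Grammar) -> np.ndarray:
        if isinstance(self.alpha, Mapping):
            vec = np.array([self.alpha[pid] for pid in grammar.production_ids], float)
        else:
            vec = np.full(grammar.n_productions, float(self.alpha))
        if np.any(vec <= 0):
            raise ValueError("alpha entries must be > 0")
        return vec


@dataclass
class PosteriorResult:
    """MCMC traces of theta plus provenance.

    ``traces`` has shape (n_chains, n_steps, n_productions); every stored
    sample is normalised within each nonterminal block.
    """

    production_ids: tuple[str, ...]
    traces: np.ndarray
    config: InferenceConfig
    grammar_hash: str
    program_assignments: list[Program] | None = None

    def pooled(self, production_id: str | None = None) -> np.ndarray:
        """Post-burn-in samples pooled across chains."""
        post = self.traces[:, self.config.burn_in:, :]
        flat = post.reshape(-1, post.shape[-1])
        if production_id is None:
            return flat
        try:
            j = self.production_ids.index(production_id)
        except ValueError:
            raise KeyError(f"production {production_id!r} not in result") from None
        return flat[:, j]

    def posterior_mean(self) -> Theta:
        means = self.pooled().mean(axis=0)
        return Theta(dict(zip(self.production_ids, map(float, means))))


def program_log_prob(
    p: Program, theta: Theta | Mapping[str, float], grammar: Grammar
) -> float:
    """log P(p | theta): production probabilities to their usage counts,
    times the uniform repetition-count factor per repetition node."""
    vals = theta.values if isinstance(theta, Theta) else theta
    counts = production_counts(p, grammar)
    log_p = 0.0
    for pid, f in counts.items():
        if not f:
            continue
        try:
            t = vals[pid]
        except KeyError:
            raise KeyError(f"theta is missing production {pid!r}") from None
        if t <= 0.0:
            return -np.inf
        log_p += f * np.log(t)
    n_rep = counts["INST:REP[INST]^n"]
    if n_rep:
        log_p += n_rep * np.log(1.0 / grammar.n_rep_choices)
    return float(log_p)


def sample_program_posterior(
    trial: Trial,
    enumeration: EnumerationResult,
    theta: Theta | Mapping[str, float],
    grammar: Grammar,
    rng: np.random.Generator,
) -> Program:
    """Exact multinomial draw of p_i given d_i and theta over a
    materialized enumeration (the exact-match likelihood is enforced by
    enumerating only computing programs)."""
    if enumeration.programs is None:
        raise ValueError("enumeration has no materialized programs")
    if not enumeration.programs:
        raise UnexplainableTrialError(
            f"trial {trial.subject_id}/{trial.trial_id} has no explaining program"
        )
    log_w = np.array(
        [program_log_prob(q, theta, grammar) for q in enumeration.programs]
    )
    w = np.exp(log_w - log_w.max())
    w /= w.sum()
    return enumeration.programs[int(rng.choice(len(w), p=w))]


def sample_theta(
    assignments: Iterable[Program],
    grammar: Grammar,
    alpha: float | Mapping[str, float],
    rng: np.random.Generator,
) -> Theta:
    """Conjugate update: per-block Dirichlet draw with concentrations
    alpha + total production counts of the assigned programs."""
    f = np.zeros(grammar.n_productions)
    for p in assignments:
        for pid, c in production_counts(p, grammar).items():
            f[grammar.index[pid]] += c
    cfg = InferenceConfig(alpha=alpha)
    avec = cfg.alpha_vector(grammar)
    theta = np.empty(grammar.n_productions)
    for lhs, idxs in grammar.blocks.items():
        idx = np.asarray(idxs)
        theta[idx] = rng.dirichlet(f[idx] + avec[idx])
    return grammar.theta_from_vector(theta)


def gibbs_infer(
    dataset: TrialDataset | Sequence[Trial],
    grammar: Grammar,
    config: InferenceConfig | None = None,
    graph: ExplanationGraph | None = None,
) -> PosteriorResult:
    """Run the alternating Gibbs sampler and return theta traces.

    Every trial's enumeration hypergraph is built once (shared across
    trials); each step evaluates inside weights under the current theta,
    draws one explaining program per trial exactly, accumulates production
    counts, and redraws theta from the per-block Dirichlet conditionals.
    """
    config = config or InferenceConfig()
    trials = list(dataset)
    if not trials:
        raise ValueError("dataset is empty")
    graph = graph or ExplanationGraph(grammar)
    roots = []
    for t in trials:
        node = graph.node_for(t.anchor, t.sequence)
        if not graph.feasible[node]:
            raise UnexplainableTrialError(
                f"trial {t.subject_id}/{t.trial_id} "
                f"({t.anchor} -> {t.sequence}) has no explaining program"
            )
        roots.append(node)

    nprod = grammar.n_productions
    avec = config.alpha_vector(grammar)
    blocks = {lhs: np.asarray(idxs) for lhs, idxs in grammar.blocks.items()}
    i_start = grammar.index["START:[INST]"]
    uniform = grammar.theta_vector(grammar.uniform_theta())
    traces = np.empty((config.n_chains, config.n_steps, nprod))
    assignments: list[Program] | None = None

    for chain in range(config.n_chains):
        rng = np.random.default_rng(config.seed + chain)
        theta = uniform.copy()
        for step in range(config.n_steps):
            vals, edge_vals = graph.inside(theta)
            f = np.zeros(nprod)
            progs = [
                graph.sample(node, vals, edge_vals, rng, counts_out=f)
                for node in roots
            ]
            f[i_start] += len(roots)
            for lhs, idx in blocks.items():
                theta[idx] = rng.dirichlet(f[idx] + avec[idx])
            traces[chain, step] = theta
        assignments = progs

    return PosteriorResult(
        production_ids=grammar.production_ids,
        traces=traces,
        config=config,
        grammar_hash=grammar.hash(),
        program_assignments=assignments,
    )


def summarize_posterior(
    result: PosteriorResult, ess_corrected: bool = False
) -> pd.DataFrame:
    """Per-production mean and standard error over pooled post-burn-in
    samples.

    The default SE is the naive pooled standard error; with
    ``ess_corrected`` it is inflated by the per-chain autocorrelation
    (effective sample size estimated by the initial-positive-sequence
    rule).
    """
    cfg = result.config
    if cfg.burn_in >= result.traces.shape[1]:
        raise ValueError("burn_in >= recorded steps: no post-burn-in samples")
    flat = result.pooled()
    n = flat.shape[0]
    mean = flat.mean(axis=0)
    sd = flat.std(axis=0, ddof=1) if n > 1 else np.zeros(flat.shape[1])
    se = sd / np.sqrt(n)
    if ess_corrected:
        ess = np.array([_effective_n(result, j) for j in range(flat.shape[1])])
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.where(ess > 0, sd / np.sqrt(ess), se)
    return pd.DataFrame(
        {"mean": mean, "se": se}, index=pd.Index(result.production_ids, name="production")
    )


def _effective_n(result: PosteriorResult, j: int) -> float:
    post = result.traces[:, result.config.burn_in:, j]
    n_chains, n = post.shape
    if n < 3 or np.allclose(post.std(), 0):
        return float(n_chains * n)
    ess = 0.0
    for c in range(n_chains):
        x = post[c] - post[c].mean()
        var = float(np.dot(x, x)) / n
        if var == 0:
            ess += n
            continue
        rho_sum = 0.0
        for lag in range(1, n):
            rho = float(np.dot(x[:-lag], x[lag:])) / (n * var)
            if rho <= 0:
                break
            rho_sum += rho
        ess += n / (1 + 2 * rho_sum)
    return ess


def group_by_family(
    summary: pd.DataFrame, family_map: Mapping[str, str]
) -> pd.DataFrame:
    """Aggregate posterior mean probability by production family."""
    missing = [pid for pid in summary.index if pid not in family_map]
    if missing:
        raise KeyError(f"productions without a family tag: {missing}")
    rows = {}
    for pid in summary.index:
        fam = family_map[pid]
        entry = rows.setdefault(fam, {"probability": 0.0, "members": []})
        entry["probability"] += float(summary.loc[pid, "mean"])
        entry["members"].append(pid)
    out = pd.DataFrame(
        {
            "probability": {f: v["probability"] for f, v in rows.items()},
            "members": {f: v["members"] for f, v in rows.items()},
        }
    )
    out.index.name = "family"
    return out.sort_values("probability", ascending=False)


def compare_populations(
    result_a: PosteriorResult, result_b: PosteriorResult, production_id: str
) -> tuple[float, float]:
    """Welch two-sample t-test on pooled post-burn-in theta samples of one
    production (A vs B; negative t means A below B)."""
    a = result_a.pooled(production_id)
    b = result_b.pooled(production_id)
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def compare_all_productions(
    result_a: PosteriorResult, result_b: PosteriorResult
) -> pd.DataFrame:
    """Grammar-wide population comparison with Bonferroni control."""
    shared = [p for p in result_a.production_ids if p in result_b.production_ids]
    rows = []
    for pid in shared:
        t, p = compare_populations(result_a, result_b, pid)
        rows.append({"production": pid, "t": t, "p": p})
    df = pd.DataFrame(rows).set_index("production")
    df["p_bonferroni"] = np.minimum(df["p"] * len(shared), 1.0)
    return df


class ProductionInference(BaseEstimator):
    """Scikit-learn style estimator for Geo production probabilities.

    Parameters
    ----------
    grammar:
        A :class:`~geolot.grammar.Grammar`; None builds the original
        inventory (``include_adhoc`` selects the extended one instead).
    include_adhoc:
        Used only when ``grammar`` is None.
    alpha, n_steps, burn_in, n_chains:
        See :class:`InferenceConfig`.
    random_state:
        Master seed; chain c uses the substream ``random_state + c``.

    Attributes
    ----------
    result_ : PosteriorResult
    production_ids_ : tuple of production id strings
    theta_ : Theta of posterior means
    traces_ : ndarray (n_chains, n_steps, n_productions)
    summary_ : DataFrame of per-production posterior mean and SE
    """

    def __init__(
        self,
        grammar: Grammar | None = None,
        include_adhoc: bool = False,
        alpha: float | Mapping[str, float] = 1.0,
        n_steps: int = 50,
        burn_in: int = 10,
        n_chains: int = 4,
        random_state: int = 0,
    ):
        self.grammar = grammar
        self.include_adhoc = include_adhoc
        self.alpha = alpha
        self.n_steps = n_steps
        self.burn_in = burn_in
        self.n_chains = n_chains
        self.random_state = random_state

    def _resolved_grammar(self) -> Grammar:
        return self.grammar if self.grammar is not None else Grammar(
            include_adhoc=self.include_adhoc
        )

    @staticmethod
    def _as_dataset(X) -> TrialDataset:
        if isinstance(X, TrialDataset):
            return X
        items = list(X)
        if items and isinstance(items[0], Trial):
            return TrialDataset(items)
        return TrialDataset.from_keys(items)

    def fit(self, X, y=None):
        """Fit on trials: a TrialDataset, a sequence of Trial objects, or
        a sequence of (anchor, sequence) pairs."""
        grammar = self._resolved_grammar()
        config = InferenceConfig(
            alpha=self.alpha,
            n_steps=self.n_steps,
            burn_in=self.burn_in,
            n_chains=self.n_chains,
            seed=self.random_state,
        )
        result = gibbs_infer(self._as_dataset(X), grammar, config)
        self.grammar_ = grammar
        self.result_ = result
        self.production_ids_ = result.production_ids
        self.traces_ = result.traces
        self.summary_ = summarize_posterior(result)
        self.theta_ = result.posterior_mean()
        return self

    def score(self, X, y=None) -> float:
        """Mean log P_Geo of held-out trials under the posterior-mean theta
        (up to the shared normalisation constant)."""
        from .coding import sequence_probability

        dataset = self._as_dataset(X)
        graph = ExplanationGraph(self.grammar_)
        logs = [
            np.log(sequence_probability(t.anchor, t.sequence, self.grammar_, self.theta_, graph))
            for t in dataset
        ]
        return float(np.mean(logs))
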
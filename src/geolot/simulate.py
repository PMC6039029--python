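"""Synthetic trial generation with the statistical structure the inference
assumes.

The human sequence data the method was designed for is not publicly
deposited, so recovery experiments run on synthetic stand-ins: programs
are drawn from the PCFG under a known ground-truth theta, executed from
uniform random anchors, and (optionally) corrupted by pointwise response
noise.  The generator emulates the shape of the original experiments —
about two dozen subjects contributing eight-point octagon sequences — but
none of their psychology: no learning within a session, no error
correction loop, no sequence-difficulty curriculum.

Programs are drawn *conditioned on their output length* via
length-indexed inside weights, which samples the exact conditional
distribution P(p | theta, output_length = L); naive ancestral sampling
would produce arbitrary lengths and, under heavy concatenation mass,
could fail to terminate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .grammar import (
    Grammar,
    Program,
    Theta,
    atomic,
    concat,
    parse_program,
    rep0,
    rep1,
    rep2,
)
from .inference import PosteriorResult, summarize_posterior
from .semantics import execute
from .trials import Trial, TrialDataset

__all__ = [
    "GeneratorConfig",
    "adult_like_theta",
    "sample_program_from_pcfg",
    "generate_dataset",
    "ideal_learner_dataset",
    "parameter_recovery_report",
]

#: Ground-truth production probabilities used as the generator default: a
#: repetition-heavy profile with mirror-symmetric clockwise/anticlockwise
#: and axis-symmetry masses, qualitatively matching production
#: probabilities inferred from adult sequence data.
_ADULT_LIKE_ATOMIC = {
    "-1": 0.15, "-2": 0.09, "-3": 0.07,
    "+0": 0.10,
    "+1": 0.15, "+2": 0.09, "+3": 0.07,
    "A": 0.06, "B": 0.06, "H": 0.06, "V": 0.06, "P": 0.04,
}
_ADULT_LIKE_INST = {"INST:ATOMIC": 0.55, "INST:INST,INST": 0.10, "INST:REP[INST]^n": 0.35}
_ADULT_LIKE_REP = {"REP:REP0": 0.70, "REP:REP1<ATOMIC>": 0.15, "REP:REP2<ATOMIC>": 0.15}


def adult_like_theta(grammar: Grammar) -> Theta:
    """The default ground-truth theta over a grammar's productions.

    Ad-hoc atomic productions (when present) receive probability zero, so
    data generated under this theta uses original productions only.
    """
    values = {"START:[INST]": 1.0}
    values.update(_ADULT_LIKE_INST)
    values.update(_ADULT_LIKE_REP)
    for sym in grammar.atomic_symbols:
        values[f"ATOMIC:{sym}"] = _ADULT_LIKE_ATOMIC.get(sym, 0.0)
    theta = Theta(values)
    theta.validate(grammar)
    return theta


@dataclass
class GeneratorConfig:
    """Settings of the synthetic generator.

    ``noise_rate`` is the probability of replacing each emitted point with
    a uniform random position; the inference likelihood is noise-free, so
    it defaults to 0 and exists only for robustness experiments.
    """

    theta_true: Theta | None = None
    n_trials: int = 300
    length: int = 8
    noise_rate: float = 0.0
    seed: int = 0
    n_subjects: int = 23

    def __post_init__(self):
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not 1 <= self.length <= 8:
            raise ValueError("length must be in [1, 8]")
        if not 0 <= self.noise_rate < 1:
            raise ValueError("noise_rate must be in [0, 1)")


def _length_weights(grammar: Grammar, theta: Theta, L: int) -> list[float]:
    """Z[m] = total probability of INST derivation trees with output length m."""
    v = theta.values
    th_at = v["INST:ATOMIC"]
    th_cc = v["INST:INST,INST"]
    th_rep = v["INST:REP[INST]^n"]
    rep_mass = v["REP:REP0"] + v["REP:REP1<ATOMIC>"] + v["REP:REP2<ATOMIC>"]
    lo, hi = grammar.rep_range
    R = grammar.n_rep_choices
    Z = [0.0] * (L + 1)
    for m in range(1, L + 1):
        z = th_at if m == 1 else 0.0
        z += th_cc * sum(Z[k] * Z[m - k] for k in range(1, m))
        if m >= 2:
            for n in range(lo, min(hi, m) + 1):
                if m % n == 0:
                    z += th_rep / R * rep_mass * Z[m // n]
        Z[m] = z
    return Z


def sample_program_from_pcfg(
    grammar: Grammar,
    theta: Theta,
    target_output_len: int,
    rng: np.random.Generator,
) -> Program:
    """Exact draw from the PCFG conditioned on the program's output length."""
    if not 1 <= target_output_len <= 8:
        raise ValueError("target_output_len must be in [1, 8]")
    theta.validate(grammar)
    Z = _length_weights(grammar, theta, target_output_len)
    if Z[target_output_len] <= 0:
        raise ValueError(
            f"grammar/theta admit no program of output length {target_output_len}"
        )
    v = theta.values
    lo, hi = grammar.rep_range
    R = grammar.n_rep_choices
    atomic_ids = [f"ATOMIC:{s}" for s in grammar.atomic_symbols]
    atomic_p = np.array([v[a] for a in atomic_ids])
    atomic_p = atomic_p / atomic_p.sum()
    rep_kinds = (
        ("rep0", v["REP:REP0"]),
        ("rep1", v["REP:REP1<ATOMIC>"]),
        ("rep2", v["REP:REP2<ATOMIC>"]),
    )

    def draw_symbol() -> str:
        return grammar.atomic_symbols[int(rng.choice(len(atomic_p), p=atomic_p))]

    def draw(m: int) -> Program:
        choices: list[tuple] = []
        weights: list[float] = []
        if m == 1:
            choices.append(("atomic",))
            weights.append(v["INST:ATOMIC"])
        for k in range(1, m):
            w = v["INST:INST,INST"] * Z[k] * Z[m - k]
            if w > 0:
                choices.append(("concat", k))
                weights.append(w)
        if m >= 2:
            for n in range(lo, min(hi, m) + 1):
                if m % n:
                    continue
                for kind, tw in rep_kinds:
                    w = v["INST:REP[INST]^n"] / R * tw * Z[m // n]
                    if w > 0:
                        choices.append((kind, n))
                        weights.append(w)
        w = np.asarray(weights)
        pick = choices[int(rng.choice(len(choices), p=w / w.sum()))]
        if pick[0] == "atomic":
            return atomic(draw_symbol())
        if pick[0] == "concat":
            k = pick[1]
            return concat(draw(k), draw(m - k))
        n = pick[1]
        block = draw(m // n)
        if pick[0] == "rep0":
            return rep0(block, n)
        if pick[0] == "rep1":
            return rep1(block, n, draw_symbol())
        return rep2(block, n, draw_symbol())

    return draw(target_output_len)


def generate_dataset(config: GeneratorConfig, grammar: Grammar) -> TrialDataset:
    """Sample a synthetic trial dataset; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    theta = config.theta_true or adult_like_theta(grammar)
    trials = []
    for i in range(config.n_trials):
        anchor = int(rng.integers(8))
        program = sample_program_from_pcfg(grammar, theta, config.length, rng)
        seq = list(execute(program, anchor, grammar))
        if config.noise_rate > 0:
            for k in range(len(seq)):
                if rng.random() < config.noise_rate:
                    seq[k] = int(rng.integers(8))
        subject = f"S{(i % config.n_subjects) + 1:02d}"
        trials.append(Trial(subject, f"t{i + 1}", anchor, tuple(seq)))
    return TrialDataset(trials)


def ideal_learner_dataset(
    program_specs: Sequence[tuple[str, int]],
    repeats: int,
    grammar: Grammar,
) -> TrialDataset:
    """Noiseless dataset of the exact sequences an ideal player produces:
    each (program text, anchor) spec executed verbatim, ``repeats`` times."""
    if not program_specs:
        raise ValueError("program_specs is empty")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    trials = []
    i = 0
    for text, anchor in program_specs:
        seq = execute(parse_program(text, grammar), anchor, grammar)
        for _ in range(repeats):
            i += 1
            trials.append(Trial("ideal", f"t{i}", int(anchor), seq))
    return TrialDataset(trials)


def parameter_recovery_report(
    theta_true: Theta | Mapping[str, float],
    posterior: PosteriorResult,
    adhoc_threshold: float = 0.01,
    family_map: Mapping[str, str] | None = None,
) -> dict:
    """Compare posterior means with the generating theta.

    Reports per-production absolute error, overall RMSE, Pearson r between
    truth and posterior means (over all productions and over those with
    nonzero truth), and any ad-hoc productions whose posterior mean
    exceeds the pruning threshold.
    """
    truth = theta_true.values if isinstance(theta_true, Theta) else dict(theta_true)
    if set(truth) != set(posterior.production_ids):
        raise KeyError(
            "theta_true and posterior cover different production ids: "
            f"{sorted(set(truth) ^ set(posterior.production_ids))}"
        )
    summary = summarize_posterior(posterior)
    ids = list(posterior.production_ids)
    t = np.array([truth[pid] for pid in ids])
    m = summary["mean"].to_numpy()
    abs_err = {pid: float(abs(a - b)) for pid, a, b in zip(ids, t, m)}
    rmse = float(np.sqrt(np.mean((t - m) ** 2)))
    r_all = float(stats.pearsonr(t, m).statistic)
    nz = t > 0
    r_nonzero = float(stats.pearsonr(t[nz], m[nz]).statistic) if nz.sum() > 2 else r_all
    flagged = []
    if family_map:
        flagged = [
            pid for pid in ids
            if family_map.get(pid) == "adhoc" and abs_err[pid] + truth[pid] > 0
            and float(summary.loc[pid, "mean"]) > adhoc_threshold
        ]
    return {
        "abs_error": abs_err,
        "rmse": rmse,
        "pearson_r": r_all,
        "pearson_r_nonzero": r_nonzero,
        "adhoc_above_threshold": flagged,
    }
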
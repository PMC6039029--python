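# geolot

Bayesian validation of grammar productions for the *language of geometry*
(Geo), a Language-of-Thought model of spatial sequence learning on a
regular octagon.

## The problem

Language-of-Thought (LoT) models represent a learned concept as a program
in a small grammar: atomic symbols combined by compositional rules.  The
grammar's production inventory is normally chosen by the experimenter's
intuition.  This package implements a validation step for that choice: it
extends the grammar with deliberately implausible "ad-hoc" productions,
converts the grammar into a probabilistic context-free grammar (PCFG), and
infers every production's probability from observed data by Bayesian
inference.  If the inference machinery is sound, the ad-hoc productions
are pruned — they receive negligible posterior mass — while the
cognitively motivated productions keep theirs.

The concrete LoT here is **Geo**: octagon vertices are labelled
`Σ = {0..7}` clockwise, and a program is a derivation tree of

```
START  → [INST]
INST   → ATOMIC | INST,INST | REP[INST]^n      n ∈ [2, 8]
REP    → REP0 | REP1<ATOMIC> | REP2<ATOMIC>
ATOMIC → -1 -2 -3 +0 +1 +2 +3 A B H V P        (original, 12 rules)
       | DOUBLE -DOUBLE SQUARE GAMMA PI EULER
         GOLD PYTH KHINCHIN GLAISHER CHAITIN   (ad-hoc, 11 rules)
```

`±k` rotate k steps (clockwise positive), `A B H V` reflect about the four
octagon axes, `P` is the half-turn.  The ad-hoc rules map a position
through arbitrary arithmetic — e.g. `PI(i)` is the i-th decimal digit of π
mod 8, so `PI(0) = 3`.  Executed from an anchor point, a program emits a
point sequence: `[+1, +1](0) = (1, 2)`, `[REP[A]^8](6)` alternates 6↔7.

## The model

Observed trials `D = (d_1..d_n)` are sequences; each is explained by any
program that computes it.  With per-production probabilities θ
(normalised within each nonterminal),

* program prior: `P(p | θ) = ∏_r θ_r^{f_r(p)}`, with `f_r(p)` the number
  of uses of production r in the derivation tree of p (repetition counts
  n are uniform on [2, 8]);
* likelihood: `P(d | p) = 1` iff p computes d (exact match, no noise
  parameter);
* prior on θ: Dirichlet with concentration α (default all ones), one
  independent Dirichlet per nonterminal block.

The posterior `P(θ | D)` marginalises over the programs explaining each
trial.  A Gibbs sampler alternates exact draws of `p_i | d_i, θ` — a
multinomial over *all* explaining programs, made tractable by exhaustively
enumerating them with a dynamic program over constraint sets — and the
conjugate Dirichlet draw of `θ | Prog`.

Two further quantities connect the Bayesian picture to the minimum
description length (MDL) one:

* `K_Geo(x)` — the minimal description length of x: minimum over
  explaining programs of (2 units per atomic, `⌊log₂ n⌋` per repetition,
  concatenation free);
* `P_Geo(x) ∝ Σ_p P(p | θ)` over all explaining programs — the
  algorithmic probability of x relative to Geo.

For universal prefix machines, Levin's Coding Theorem makes
`log 1/P(x) = K(x)` up to a constant.  Geo is not Turing-complete, so the
package *measures* whether the inverse-logarithmic relationship holds
anyway: regress `log₁₀(mean P_Geo)` on `K_Geo` over thousands of random
sequences per length.

## Worked example

The human data of the original experiments is not deposited, so the
package generates synthetic datasets with the assumed statistical
structure (programs sampled from the PCFG under a known θ, executed from
random anchors):

```python
import numpy as np
import geolot as gl

g = gl.build_grammar()                       # original 12-atomic inventory
ds = gl.generate_dataset(gl.GeneratorConfig(n_trials=300, length=8, seed=11), g)
gl.count_programs(ds[0].anchor, ds[0].sequence, g)
# 2216189       <- programs explaining the first 8-point trial

est = gl.ProductionInference(grammar=g, random_state=23).fit(ds)
est.summary_.loc[["ATOMIC:+1", "ATOMIC:-1", "ATOMIC:P"]].round(4)
#               mean      se
# production
# ATOMIC:+1   0.1414  0.0014
# ATOMIC:-1   0.1691  0.0015
# ATOMIC:P    0.0488  0.0008
```

The posterior means recover the generating θ (here `+1`/`-1` were both
0.15, `P` was 0.04); with the extended grammar the eleven ad-hoc
productions all land below every production the generator used.  The
complexity/probability relation for the full clockwise loop:

```python
gl.sequence_complexity(0, (1,2,3,4,5,6,7,0), g)          # 5.0  ([REP[+1]^8])
gl.sequence_probability(0, (1,2,3,4,5,6,7,0), g, est.theta_)  # 0.00372...
fit = gl.coding_theorem_experiment(est.theta_, g, [5],
                                   rng=np.random.default_rng(59))[0]
(fit.slope, fit.r_squared)
# (-1.172, 0.984)   <- log10(mean P_Geo) falls linearly in K_Geo
```

A `geolot` command line mirrors the stages:
`simulate`, `enumerate`, `infer`, `complexity`, `probability`,
`coding-theorem`, `compare` (see `geolot --help`).

## Layout

| module | contents |
|---|---|
| `geolot.grammar` | inventories, derivation trees, notation parser, production counts |
| `geolot.semantics` | atomic transition tables and program execution |
| `geolot.enumeration` | constraint-set DP: enumerate / count explaining programs |
| `geolot.inference` | Gibbs sampler, summaries, family grouping, population tests |
| `geolot.complexity` | program cost and minimal sequence complexity K_Geo |
| `geolot.coding` | inside-DP P_Geo and the coding-theorem experiment |
| `geolot.simulate` | synthetic datasets, ideal-learner datasets, recovery reports |
| `geolot.fileio`, `geolot.cli` | trials CSV, config and result JSON, CLI |

See `docs/methods.md` for modelling assumptions, numerical choices and
limitations.
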
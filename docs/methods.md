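# Methods

## Model

Observed data are trials `(anchor, sequence)` over the octagon alphabet
Σ = {0..7}.  A trial's generative account is a *derivation tree* (program)
of the Geo grammar; the exact-match likelihood `P(d | p) ∈ {0, 1}` means
the posterior over programs for one trial is simply the renormalised
program prior restricted to the set of programs that compute the trial.
The program prior is the PCFG weight `∏_r θ_r^{f_r(p)}` times
`(1/|rep_range|)` per repetition node: the repetition count n is *not* a
θ-weighted production but a uniform choice over the admissible interval
(default [2, 8], 7 choices).  One probability is therefore reported per
symbolic production, and `θ` has 19 entries (original grammar) or 30
(extended), keyed by stable ids of the form `"LHS:label"`
(e.g. `ATOMIC:+1`, `INST:REP[INST]^n`).

The Dirichlet prior is a *product of independent Dirichlets, one per
nonterminal block* (START, INST, REP, ATOMIC).  A PCFG requires
per-left-hand-side normalisation, so a single flat Dirichlet over all
productions would not be a prior on valid parameter vectors; the block
product is the natural conjugate structure.  The default concentration is
1 for every entry (uniform on each simplex).

## Execution semantics conventions

* Vertex labels increase clockwise; `+k` moves k steps clockwise, `-k`
  anticlockwise (fixes the worked reading of `[+1, +1](0) = (1, 2)`).
* Reflections are `pos ↦ (c − pos) mod 8` with odd constants.  `A` is
  pinned to `c = 5` by the requirement that it swap vertices 6 and 7; the
  defaults `B: 1, H: 7, V: 3` are a labelling convention and are
  configurable.  Inference results are invariant to relabelling among
  reflections up to the corresponding permutation of θ entries.
* `REP1<σ>` ("starting-point variation"): cycle i starts at
  `σ(start of cycle i−1)`; the variation composes cumulatively on the
  *starts*, not on the threaded output position.  `REP2<σ>` ("resulting
  sequence variation"): cycle 1 is the block's output; cycle i is cycle
  i−1's output mapped pointwise through σ.  After any repetition the
  threaded position is the last emitted point.  These variants sit behind
  the single execution interface so an alternative reading could be
  swapped in without touching enumeration or inference.
* Ad-hoc digit productions use the leading base-10 digits of each
  constant (index 0 = leading printed digit) reduced mod 8, so
  `PI = (3,1,4,1,5,1,2,6)`.  The CHAITIN table is built from the decimal
  expansion 0.0078749969… of the published 84-bit-programs approximation
  of a Chaitin Ω number; it is an editable fixture (`digit_tables` /
  config key `digits`) since that choice is conventional.

## Enumerating all explaining programs

The enumerator is a dynamic program over *constraint sets*: sets of
(start, target-subsequence) instances a subtree must satisfy
simultaneously.  Concatenation splits every instance at a common offset
(the right part starting at the left part's last point); plain repetition
turns one instance into one instance per cycle; `REP1` does the same with
cycle starts `σ^(i−1)(start)` — a pure function of the parameter — and
`REP2` reduces to a pointwise test on the observed span plus a cycle-1
constraint.  Because execution is deterministic, a set containing two
instances with equal start and different targets is pruned immediately.
This propagation is exact for *all* repetition variants, so no
post-validation by execution is needed; correctness is established
against an independent brute-force oracle (exhaustive generation of every
tree of the right output length, filtered by execution) on all 64
single-point inputs and hundreds of random inputs up to length 4.

All concatenation associations are distinct trees and are counted
distinctly (the flat notation `[i1, i2, i3]` *parses* to the
left-associated tree; the enumerator covers every binary association).
The resulting hypergraph is shared across sequences — an 8-point dataset
of 300 trials and 10,000 length-5 records reuse each other's
sub-constraints — and is evaluated in four semirings over the same
structure:

* exact program counts (Python big integers; counts per 8-point sequence
  reach millions, so counting never materializes programs; a configurable
  cap, default 10⁷, guards materialization);
* materialized program lists (tests and the explicit multinomial
  sampler);
* min-plus for `K_Geo`;
* probability-weighted inside sums for `P_Geo` (float64; the smallest
  length-8 sums are ≈ 1e-13, far from underflow).

## Gibbs sampling

Each chain initialises θ at per-block uniform — with exact conditional
draws the chain forgets its initialisation within a few steps, and the
uniform point is the prior block mean.  One step evaluates the inside
weights under the current θ (a vectorised pass over the shared
hypergraph), draws each trial's program by top-down stochastic
backtracking — an *exact* draw from the multinomial over all explaining
programs, verified by chi-square against the explicit multinomial over a
materialized enumeration — accumulates production counts, and redraws
each θ block from its Dirichlet conditional.  Defaults follow the
analysis design: 4 chains × 50 steps, burn-in 10, master seed s with
chain c seeded s + c, making runs bit-reproducible.  The stationary
distribution of program assignments was checked against exhaustive
Dirichlet-multinomial enumeration on a tiny two-trial problem (total
variation < 0.05 at 20,000 steps).

Summaries pool post-burn-in samples across chains; the reported standard
error is the naive pooled SE.  MCMC samples autocorrelate, so an
effective-sample-size-corrected SE (initial-positive-sequence estimator)
is available behind `ess_corrected=True`.  Population comparison is a
Welch t-test on pooled θ samples of one pre-selected production;
grammar-wide scans apply Bonferroni correction, since a 19–30-way scan
needs multiplicity control even though a single planned comparison does
not.

## Synthetic data

The generator emulates the *statistical structure the inference assumes*:
anchors uniform on Σ, programs drawn from the PCFG under a ground-truth
θ, executed exactly, with optional pointwise replacement noise (default
0 — the likelihood is noise-free, so noise exists only for robustness
experiments).  Trials are attributed round-robin to 23 synthetic subject
ids, matching the scale of a typical adult cohort; subjects are
exchangeable because the model pools trials per population.  It does
*not* emulate learning within a session, the error-correction procedure
of the behavioural task, or any sequence-difficulty curriculum — so
passing recovery tests demonstrates correctness of the inference
machinery on model-consistent data, not fidelity to human behaviour.

Length conditioning is exact: inside weights `Z[m]` (total prior mass of
trees with output length m) are computed once and ancestral sampling is
reweighted by them, avoiding both the length bias and the
non-termination risk of naive rejection.

The default ground truth (`adult_like_theta`) is a repetition-heavy
profile — INST: 0.55 atomic / 0.10 concat / 0.35 repeat; REP: 0.70 /
0.15 / 0.15; ATOMIC: mirror-symmetric rotation masses (±1: 0.15,
±2: 0.09, ±3: 0.07), stay 0.10, reflections 0.06 each, half-turn 0.04 —
chosen as a plausible adult-like profile with the qualitative features
reported for human data (repetition over concatenation, clockwise /
anticlockwise balance).  Ad-hoc productions get exactly zero mass, so
extended-grammar inference on generated data is a pure pruning test.

## MDL cost

`K_Geo` charges 2 units per atomic production, `⌊log₂ n⌋` per repetition,
and nothing for concatenation.  The logarithm base is not dictated by the
cost rule's statement; base 2 keeps the unit consistent with
description-length bits and makes `[REP[+1]^8]` cost 2 + 3 = 5.  The
ATOMIC parameter of `REP1`/`REP2` charges the atomic cost 2 (it is an
atomic production in the derivation); this is configurable
(`Grammar(param_cost=...)`) since the cost of the parameter is a
convention.

## Coding-theorem experiment

"Unique random sequences" are unique `(anchor, sequence)` *pairs* —
`P_Geo` is defined for an anchored sequence.  Sampling is uniform without
replacement: exhaustive when the space has ≤ `max_n` pairs (all 64 at
length 1, all 4096 at length 3), `max_n = 10,000` pairs otherwise.
Records are grouped by identical `K_Geo`, probabilities averaged within a
group (groups with a single sequence are retained), and
`log₁₀(mean P_Geo)` is regressed on `K_Geo` by ordinary least squares;
the reported R² is from that simple regression.  Fits with fewer than two
distinct complexity values are marked undefined rather than raising.  At
the default scale (length 5, 10,000 records, θ inferred from 300
synthetic trials) the fit gives slope ≈ −1.2 and R² ≈ 0.98.

## Problem sizes and runtime

The shipped tests and the acceptance script run at reduced but
informative scales, chosen as the smallest sizes at which the measured
quantities are stable: 300 trials × length 8 for inference and recovery
(≈ 5 s for the Gibbs run after ≈ 4–9 s of hypergraph construction),
brute-force oracle comparisons up to length 4 (≈ 470k candidate trees),
and 10,000 length-5 records for the coding-theorem fit (≈ 15 s).  The
full suite completes in a couple of minutes on one CPU.

## Known limitations

* The exact human datasets are unavailable, so the population-level
  numbers (posterior θ of adults/children, the 159-million program total)
  are not reproduced; the machinery is validated by oracle equivalence
  and synthetic recovery instead.
* `H`, `V`, `B` axis constants are conventions (only `A` is pinned by a
  worked example); studies with a concrete stimulus layout should set
  `axes` explicitly.
* The brute-force oracle is exponential and limited to sequences of
  length ≤ 5; beyond that, correctness rests on the cross-semiring
  consistency checks (count vs materialized length, inside vs explicit
  sum, min-DP vs materialized minimum).
* `P_Geo` is unnormalised over Σ⁺; only ratios/regression slopes are
  meaningful, which is all the coding-theorem analysis needs.
* No hierarchical per-subject θ: trials are pooled per population, as in
  the modelling design the package implements.
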
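"""Gibbs sampling machinery: program posteriors, Dirichlet updates,
summaries and population comparison."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import geolot as gl
from geolot.inference import (
    InferenceConfig,
    PosteriorResult,
    UnexplainableTrialError,
    compare_all_productions,
)
from geolot.trials import Trial, TrialDataset


def make_result(og, traces, burn_in=0):
    cfg = InferenceConfig(n_steps=traces.shape[1], burn_in=burn_in,
                          n_chains=traces.shape[0], seed=0)
    return PosteriorResult(og.production_ids, traces, cfg, og.hash())


class TestProgramLogProb:
    def test_forced_derivation_has_probability_one(self, og):
        theta = og.uniform_theta()
        for pid in theta.values:
            theta.values[pid] = 0.0
        theta.values["START:[INST]"] = 1.0
        theta.values["INST:ATOMIC"] = 1.0
        theta.values["REP:REP0"] = 1.0
        theta.values["ATOMIC:+1"] = 1.0
        assert gl.program_log_prob(gl.atomic("+1"), theta, og) == 0.0

    def test_count_algebra_for_concatenation(self, og, adult_theta):
        v = adult_theta.values
        diff = gl.program_log_prob(
            gl.concat(gl.atomic("+1"), gl.atomic("+1")), adult_theta, og
        ) - gl.program_log_prob(gl.atomic("+1"), adult_theta, og)
        expected = (
            math.log(v["INST:INST,INST"])
            + math.log(v["INST:ATOMIC"])
            + math.log(v["ATOMIC:+1"])
        )
        assert diff == pytest.approx(expected)

    def test_rep_nodes_pay_uniform_count_factor(self, og, adult_theta):
        v = adult_theta.values
        p = gl.rep0(gl.atomic("+1"), 8)
        expected = (
            math.log(v["INST:REP[INST]^n"]) + math.log(v["REP:REP0"])
            + math.log(v["INST:ATOMIC"]) + math.log(v["ATOMIC:+1"])
            + math.log(1 / og.n_rep_choices)
        )
        assert gl.program_log_prob(p, adult_theta, og) == pytest.approx(expected)

    def test_total_mass_of_single_point_trees(self, og, adult_theta):
        total = sum(
            math.exp(gl.program_log_prob(gl.atomic(s), adult_theta, og))
            for s in og.atomic_symbols
        )
        assert total == pytest.approx(adult_theta["INST:ATOMIC"])

    def test_zero_probability_production_gives_minus_inf(self, og):
        theta = gl.adult_like_theta(og)
        theta.values["ATOMIC:+1"] = 0.0
        assert gl.program_log_prob(gl.atomic("+1"), theta, og) == -np.inf


class TestProgramPosteriorSampling:
    def test_single_explaining_program_always_returned(self, og, adult_theta):
        trial = Trial("s", "t", 0, (4,))
        enum = gl.enumerate_programs(0, (4,), og)
        rng = np.random.default_rng(0)
        for _ in range(10):
            p = gl.sample_program_posterior(trial, enum, adult_theta, og, rng)
            assert gl.serialize_program(p) == "[P]"

    def test_multinomial_frequencies_match_exact_distribution(self, og, adult_theta):
        trial = Trial("s", "t", 0, (1, 2))
        enum = gl.enumerate_programs(0, (1, 2), og)
        log_w = np.array(
            [gl.program_log_prob(q, adult_theta, og) for q in enum.programs]
        )
        w = np.exp(log_w - log_w.max())
        w /= w.sum()
        rng = np.random.default_rng(1)
        n = 5000
        idx = {gl.serialize_program(q): i for i, q in enumerate(enum.programs)}
        obs = np.zeros(len(w))
        for _ in range(n):
            p = gl.sample_program_posterior(trial, enum, adult_theta, og, rng)
            obs[idx[gl.serialize_program(p)]] += 1
        res = stats.chisquare(obs, n * w)
        assert res.pvalue > 0.01

    def test_graph_sampler_draws_same_multinomial(self, og, adult_theta):
        # the top-down hypergraph sampler must agree with the explicit
        # multinomial over the materialized enumeration
        enum = gl.enumerate_programs(0, (1, 2), og)
        log_w = np.array(
            [gl.program_log_prob(q, adult_theta, og) for q in enum.programs]
        )
        w = np.exp(log_w - log_w.max())
        w /= w.sum()
        graph = gl.ExplanationGraph(og)
        node = graph.node_for(0, (1, 2))
        vals, ev = graph.inside(og.theta_vector(adult_theta))
        rng = np.random.default_rng(2)
        n = 5000
        idx = {gl.serialize_program(q): i for i, q in enumerate(enum.programs)}
        obs = np.zeros(len(w))
        for _ in range(n):
            p = graph.sample(node, vals, ev, rng)
            obs[idx[gl.serialize_program(p)]] += 1
        assert stats.chisquare(obs, n * w).pvalue > 0.01

    def test_sampled_counts_match_production_counts(self, og, adult_theta):
        graph = gl.ExplanationGraph(og)
        node = graph.node_for(2, (3, 4, 3, 4))
        vals, ev = graph.inside(og.theta_vector(adult_theta))
        rng = np.random.default_rng(3)
        i_start = og.index["START:[INST]"]
        for _ in range(50):
            f = np.zeros(og.n_productions)
            p = graph.sample(node, vals, ev, rng, counts_out=f)
            f[i_start] += 1
            expected = gl.production_counts(p, og)
            got = {pid: int(f[og.index[pid]]) for pid in og.production_ids}
            assert got == expected

    def test_unmaterialized_enumeration_rejected(self, og, adult_theta):
        trial = Trial("s", "t", 0, (1, 2))
        enum = gl.enumerate_programs(0, (1, 2), og, materialize_limit=1)
        with pytest.raises(ValueError):
            gl.sample_program_posterior(trial, enum, adult_theta, og,
                                        np.random.default_rng(0))


class TestSampleTheta:
    def test_prior_only_expectation_is_block_uniform(self, og):
        rng = np.random.default_rng(4)
        draws = np.array(
            [og.theta_vector(gl.sample_theta([], og, 1.0, rng)) for _ in range(4000)]
        )
        means = draws.mean(axis=0)
        for lhs, idxs in og.blocks.items():
            for i in idxs:
                se = draws[:, i].std(ddof=1) / np.sqrt(len(draws))
                assert abs(means[i] - 1 / len(idxs)) < 4 * se + 1e-12

    def test_posterior_mean_matches_dirichlet_closed_form(self, og):
        p = gl.parse_program("[+1, +1]", og)  # f(+1)=2 in the 12-way ATOMIC block
        rng = np.random.default_rng(5)
        draws = np.array(
            [gl.sample_theta([p], og, 1.0, rng)["ATOMIC:+1"] for _ in range(5000)]
        )
        expected = (2 + 1) / (2 + 12)
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - expected) < 4 * se

    def test_large_alpha_concentrates_on_prior_mean(self, og):
        p = gl.parse_program("[+1, +1]", og)
        rng = np.random.default_rng(6)
        small = [og.theta_vector(gl.sample_theta([p], og, 1.0, rng)) for _ in range(200)]
        big = [og.theta_vector(gl.sample_theta([p], og, 1000.0, rng)) for _ in range(200)]
        uniform = og.theta_vector(og.uniform_theta())
        dev_small = np.max(np.abs(np.array(small) - uniform), axis=1).mean()
        dev_big = np.max(np.abs(np.array(big) - uniform), axis=1).mean()
        assert dev_big < dev_small / 3

    def test_draw_is_normalized_per_block(self, og):
        theta = gl.sample_theta([], og, 1.0, np.random.default_rng(7))
        theta.validate(og)


class TestGibbs:
    def test_conjugate_closed_form_with_unique_programs(self, og):
        # every (s, s+4) trial is explained only by [P]: the program
        # assignment step is deterministic, so posterior means must equal
        # the Dirichlet closed form given the fixed counts
        n = 16
        ds = TrialDataset.from_keys([(s % 8, ((s + 4) % 8,)) for s in range(n)])
        res = gl.gibbs_infer(ds, og, InferenceConfig(n_steps=60, burn_in=10, seed=8))
        summ = gl.summarize_posterior(res)
        checks = {
            "ATOMIC:P": (n + 1) / (n + 12),
            "ATOMIC:+1": 1 / (n + 12),
            "INST:ATOMIC": (n + 1) / (n + 3),
            "REP:REP0": 1 / 3,
        }
        for pid, expected in checks.items():
            se = max(float(summ.loc[pid, "se"]), 1e-4)
            assert abs(float(summ.loc[pid, "mean"]) - expected) < 5 * se

    def test_stationary_assignment_distribution_matches_enumeration(self, og):
        # joint program assignments on a tiny 2-trial problem vs the exact
        # marginal P(Prog | D) from Dirichlet-multinomial integration
        keys = [(0, (1,)), (0, (1, 2))]
        enums = {k: gl.enumerate_programs(k[0], k[1], og) for k in keys}
        alpha = 1.0

        def log_marginal(programs):
            f = np.zeros(og.n_productions)
            n_rep = 0
            for p in programs:
                for pid, c in gl.production_counts(p, og).items():
                    f[og.index[pid]] += c
                n_rep += gl.production_counts(p, og)["INST:REP[INST]^n"]
            lp = n_rep * math.log(1 / og.n_rep_choices)
            for lhs, idxs in og.blocks.items():
                fa = f[list(idxs)] + alpha
                lp += sum(math.lgamma(x) for x in fa) - math.lgamma(fa.sum())
                lp -= len(idxs) * math.lgamma(alpha) - math.lgamma(len(idxs) * alpha)
            return lp

        combos = [
            (p1, p2)
            for p1 in enums[keys[0]].programs
            for p2 in enums[keys[1]].programs
        ]
        logs = np.array([log_marginal(c) for c in combos])
        exact = np.exp(logs - logs.max())
        exact /= exact.sum()

        graph = gl.ExplanationGraph(og)
        nodes = [graph.node_for(a, s) for a, s in keys]
        rng = np.random.default_rng(9)
        theta = og.theta_vector(og.uniform_theta())
        names = {
            tuple(map(gl.serialize_program, c)): i for i, c in enumerate(combos)
        }
        freq = np.zeros(len(combos))
        n_steps = 20000
        blocks = {lhs: np.asarray(i) for lhs, i in og.blocks.items()}
        avec = np.ones(og.n_productions)
        i_start = og.index["START:[INST]"]
        for _ in range(n_steps):
            vals, ev = graph.inside(theta)
            f = np.zeros(og.n_productions)
            progs = tuple(
                gl.serialize_program(graph.sample(nd, vals, ev, rng, counts_out=f))
                for nd in nodes
            )
            freq[names[progs]] += 1
            f[i_start] += len(nodes)
            for lhs, idx in blocks.items():
                theta[idx] = rng.dirichlet(f[idx] + avec[idx])
        tv = 0.5 * np.abs(freq / n_steps - exact).sum()
        assert tv < 0.05

    def test_every_trace_sample_is_normalized(self, og, adult_posterior):
        traces = adult_posterior.traces
        for lhs, idxs in og.blocks.items():
            sums = traces[:, :, list(idxs)].sum(axis=2)
            assert np.allclose(sums, 1.0, atol=1e-9)

    def test_empty_dataset_rejected(self, og):
        with pytest.raises(ValueError):
            gl.gibbs_infer(TrialDataset([]), og, InferenceConfig(seed=0))

    def test_empty_enumeration_names_the_trial(self, og, adult_theta):
        trial = Trial("s9", "t3", 0, (1, 2))
        empty = gl.EnumerationResult(0, (1, 2), 0, [])
        with pytest.raises(UnexplainableTrialError, match="s9/t3"):
            gl.sample_program_posterior(trial, empty, adult_theta, og,
                                        np.random.default_rng(0))

    def test_reproducible_given_seed(self, og):
        ds = TrialDataset.from_keys([(0, (1, 2)), (3, (4, 5, 6))])
        cfg = InferenceConfig(n_steps=10, burn_in=2, n_chains=2, seed=12)
        a = gl.gibbs_infer(ds, og, cfg)
        b = gl.gibbs_infer(ds, og, cfg)
        assert np.array_equal(a.traces, b.traces)

    def test_prior_dominance_with_large_alpha(self, og):
        ds = TrialDataset.from_keys([(s % 8, ((s + 4) % 8,)) for s in range(12)])
        cfg = InferenceConfig(alpha=5000.0, n_steps=30, burn_in=5, seed=13)
        summ = gl.summarize_posterior(gl.gibbs_infer(ds, og, cfg))
        for lhs, idxs in og.blocks.items():
            for i in idxs:
                pid = og.production_ids[i]
                assert abs(float(summ.loc[pid, "mean"]) - 1 / len(idxs)) < 0.02


class TestSummaries:
    def test_constant_traces_have_zero_se(self, og):
        vec = og.theta_vector(og.uniform_theta())
        traces = np.tile(vec, (2, 5, 1))
        summ = gl.summarize_posterior(make_result(og, traces))
        assert np.allclose(summ["se"], 0.0)
        assert np.allclose(summ["mean"], vec)

    def test_identical_chains_pool_to_same_summary(self, og):
        rng = np.random.default_rng(14)
        one = np.abs(rng.normal(0.2, 0.05, size=(1, 8, og.n_productions)))
        two = np.concatenate([one, one], axis=0)
        s1 = gl.summarize_posterior(make_result(og, one))
        s2 = gl.summarize_posterior(make_result(og, two))
        assert np.allclose(s1["mean"], s2["mean"])

    def test_block_means_sum_to_one(self, og, adult_posterior):
        summ = gl.summarize_posterior(adult_posterior)
        for lhs, idxs in og.blocks.items():
            total = sum(summ["mean"].iloc[i] for i in idxs)
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_burn_in_must_leave_samples(self, og):
        with pytest.raises(ValueError):
            InferenceConfig(n_steps=10, burn_in=10)

    def test_ess_corrected_se_not_smaller(self, og, adult_posterior):
        naive = gl.summarize_posterior(adult_posterior)
        corr = gl.summarize_posterior(adult_posterior, ess_corrected=True)
        assert (corr["se"] >= naive["se"] * 0.999).all()


class TestFamilies:
    def test_family_totals_partition_the_summary(self, og, adult_posterior):
        summ = gl.summarize_posterior(adult_posterior)
        fams = gl.group_by_family(summ, og.family_map())
        assert fams["probability"].sum() == pytest.approx(float(summ["mean"].sum()))
        members = [m for ms in fams["members"] for m in ms]
        assert sorted(members) == sorted(summ.index)

    def test_singleton_family_equals_production_mean(self, og, adult_posterior):
        summ = gl.summarize_posterior(adult_posterior)
        fams = gl.group_by_family(summ, og.family_map())
        assert fams.loc["stay", "probability"] == pytest.approx(
            float(summ.loc["ATOMIC:+0", "mean"])
        )

    def test_unmapped_production_rejected(self, og, adult_posterior):
        summ = gl.summarize_posterior(adult_posterior)
        fam = dict(og.family_map())
        fam.pop("ATOMIC:P")
        with pytest.raises(KeyError):
            gl.group_by_family(summ, fam)

    def test_rep_family_dominates_concat_on_rep_rich_data(self, og, adult_posterior):
        # the generating theta favours repetitions over plain concatenation
        summ = gl.summarize_posterior(adult_posterior)
        assert float(summ.loc["INST:REP[INST]^n", "mean"]) > float(
            summ.loc["INST:INST,INST", "mean"]
        )


class TestComparePopulations:
    def test_identical_samples_give_zero_t(self, og):
        rng = np.random.default_rng(15)
        traces = np.abs(rng.normal(0.1, 0.01, size=(2, 10, og.n_productions)))
        a = make_result(og, traces)
        b = make_result(og, traces.copy())
        t, p = gl.compare_populations(a, b, "ATOMIC:P")
        assert t == pytest.approx(0.0)

    def test_shift_gives_negative_t_for_smaller_first(self, og):
        rng = np.random.default_rng(16)
        traces = np.abs(rng.normal(0.1, 0.01, size=(2, 10, og.n_productions)))
        a = make_result(og, traces)
        b = make_result(og, traces + 0.05)
        t, p = gl.compare_populations(a, b, "ATOMIC:P")
        assert t < 0 and p < 1e-6

    def test_missing_production_rejected(self, og, eg, adult_posterior):
        rng = np.random.default_rng(17)
        other = make_result(og, np.abs(rng.normal(0.1, 0.01, (1, 5, og.n_productions))))
        with pytest.raises(KeyError):
            gl.compare_populations(adult_posterior, other, "ATOMIC:PI")

    def test_single_differing_production_flagged_grammar_wide(self, og):
        # two synthetic populations whose generating thetas differ only in
        # the half-turn mass: only symmetry-block productions may flag
        theta_a = gl.adult_like_theta(og)
        v = dict(theta_a.values)
        v["ATOMIC:P"] = 0.24
        v["ATOMIC:+0"] = 0.10 - 0.0
        for s in ("A", "B", "H", "V"):
            v[f"ATOMIC:{s}"] = 0.01
        theta_b = gl.Theta(v)
        theta_b.validate(og)
        cfg_gen = dict(n_trials=150, length=8)
        ds_a = gl.generate_dataset(
            gl.GeneratorConfig(theta_true=theta_a, seed=18, **cfg_gen), og
        )
        ds_b = gl.generate_dataset(
            gl.GeneratorConfig(theta_true=theta_b, seed=19, **cfg_gen), og
        )
        res_a = gl.gibbs_infer(ds_a, og, InferenceConfig(seed=20, n_chains=2))
        res_b = gl.gibbs_infer(ds_b, og, InferenceConfig(seed=21, n_chains=2))
        df = compare_all_productions(res_a, res_b)
        assert df.loc["ATOMIC:P", "p_bonferroni"] < 0.01
        assert df.loc["ATOMIC:P", "t"] < 0  # population A uses P less


class TestEstimator:
    def test_sklearn_interface_fits_and_exposes_posterior(self, og):
        est = gl.ProductionInference(grammar=og, n_steps=15, burn_in=3,
                                     n_chains=2, random_state=1)
        ds = gl.generate_dataset(gl.GeneratorConfig(n_trials=40, length=4, seed=2), og)
        est.fit(ds)
        assert est.traces_.shape == (2, 15, og.n_productions)
        assert set(est.summary_.index) == set(og.production_ids)
        assert est.theta_["START:[INST]"] == pytest.approx(1.0)
        params = est.get_params()
        assert params["n_steps"] == 15
        clone_params = gl.ProductionInference(**params).get_params()
        assert clone_params == params

    def test_estimator_accepts_plain_pairs(self, og):
        est = gl.ProductionInference(grammar=og, n_steps=8, burn_in=2,
                                     n_chains=1, random_state=3)
        est.fit([(0, (1, 2)), (4, (5, 6))])
        assert est.summary_["mean"].between(0, 1).all()

    def test_score_prefers_matching_data(self, og):
        est = gl.ProductionInference(grammar=og, n_steps=15, burn_in=5,
                                     n_chains=2, random_state=4)
        ds = gl.generate_dataset(gl.GeneratorConfig(n_trials=60, length=4, seed=5), og)
        est.fit(ds)
        assert np.isfinite(est.score(ds[:10]))
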
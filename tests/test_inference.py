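"""ABC machinery: priors, rejection, regression adjustment, model choice,
posterior summaries and unit conversions."""

import math

import numpy as np
import pandas as pd
import pytest

from locuspair.alignment import Alignment
from locuspair.coalescent import (
    HaplotypeMatrix, LocusSpec, NeutralParams, simulate_locus,
)
from locuspair.divergence import classify_polymorphisms
from locuspair.inference import (
    DemographicABC,
    Prior,
    abc_reject,
    epanechnikov_weights,
    model_probabilities,
    neutral_model,
    posterior_summary,
    regression_adjust,
    sample_priors,
    summarize_single,
    summarize_twopop,
    weighted_quantile,
)
from locuspair.units import effective_size, round_sig, split_time_years


class TestPriors:
    def test_log_uniform_median_is_geometric_mean(self, rng):
        p = Prior("theta", "log-uniform", 1e-4, 1.0)
        draws = p.sample(100_000, rng)
        assert np.median(draws) == pytest.approx(0.01, rel=0.05)
        assert draws.min() >= 1e-4 and draws.max() <= 1.0

    def test_uniform_mean(self, rng):
        p = Prior("t", "uniform", 0.0, 10.0)
        draws = p.sample(50_000, rng)
        assert draws.mean() == pytest.approx(5.0, abs=0.1)

    def test_seeded_reproducibility(self):
        p = Prior("x", "log-uniform", 0.001, 1.0)
        a = p.sample(100, np.random.default_rng(5))
        b = p.sample(100, np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_invalid_priors_rejected(self):
        with pytest.raises(ValueError):
            Prior("x", "uniform", 1.0, 0.5)
        with pytest.raises(ValueError):
            Prior("x", "log-uniform", 0.0, 1.0)
        with pytest.raises(ValueError):
            Prior("x", "gaussian", 0, 1)

    def test_transform_round_trip(self, rng):
        for p in (Prior("a", "log-uniform", 1e-3, 10),
                  Prior("b", "uniform", 0.0, 10.0)):
            x = p.sample(100, rng)
            assert np.allclose(p.back_transform(p.transform(x)), x, rtol=1e-6)

    def test_sample_priors_frame(self, rng):
        df = sample_priors([Prior("a", "uniform", 0, 1),
                            Prior("b", "log-uniform", 0.1, 1)], 50, rng)
        assert list(df.columns) == ["a", "b"]
        assert len(df) == 50


class TestRejection:
    def test_exact_match_retained_first(self, rng):
        sims = rng.normal(size=(200, 4))
        obs = sims[17]
        idx, dist = abc_reject(obs, sims, 0.05)
        assert idx[0] == 17
        assert dist[0] == 0.0

    def test_p_delta_one_keeps_all(self, rng):
        sims = rng.normal(size=(100, 3))
        idx, _ = abc_reject(rng.normal(size=3), sims, 1.0)
        assert len(idx) == 100

    def test_matches_full_sort_oracle(self, rng):
        sims = rng.normal(size=(500, 5))
        obs = rng.normal(size=5)
        idx, dist = abc_reject(obs, sims, 0.02)
        med = np.median(sims, axis=0)
        mad = np.median(np.abs(sims - med), axis=0)
        z = (sims - obs) / mad
        full = np.sqrt((z**2).sum(axis=1))
        want = np.argsort(full, kind="stable")[:10]
        assert set(idx.tolist()) == set(want.tolist())
        assert np.allclose(np.sort(dist), np.sort(full[want]))

    def test_affine_rescaling_invariant(self, rng):
        sims = rng.normal(size=(400, 4))
        obs = rng.normal(size=4)
        idx1, _ = abc_reject(obs, sims, 0.05)
        scale = np.array([3.0, 0.1, 40.0, 1.0])
        shift = np.array([-2.0, 5.0, 0.0, 100.0])
        idx2, _ = abc_reject(obs * scale + shift, sims * scale + shift, 0.05)
        assert set(idx1.tolist()) == set(idx2.tolist())

    def test_degenerate_stat_dropped_with_warning(self, rng):
        sims = rng.normal(size=(100, 3))
        sims[:, 1] = 7.0
        with pytest.warns(UserWarning, match="degenerate"):
            idx, _ = abc_reject(np.array([0.0, 7.0, 0.0]), sims, 0.1)
        assert len(idx) == 10

    def test_invalid_p_delta(self, rng):
        with pytest.raises(ValueError):
            abc_reject(np.zeros(2), rng.normal(size=(10, 2)), 0.0)


class TestRegressionAdjustment:
    def _linear_world(self, rng, n=400, noise=0.02):
        theta = np.exp(rng.uniform(np.log(0.01), np.log(1.0), n))
        summaries = np.column_stack([
            np.log(theta) + rng.normal(0, noise, n),
            rng.normal(size=n),
        ])
        return pd.DataFrame({"theta": theta}), summaries

    def test_linear_world_concentrates_on_truth(self, rng):
        prior = Prior("theta", "log-uniform", 0.01, 1.0)
        params, summaries = self._linear_world(rng)
        truth = 0.2
        obs = np.array([np.log(truth), 0.0])
        dist = np.sqrt(((summaries - obs) ** 2).sum(axis=1))
        adj, w = regression_adjust(params, summaries, obs, dist, [prior])
        rmse_adj = np.sqrt(np.average((adj["theta"] - truth) ** 2, weights=w))
        rmse_rej = np.sqrt(np.average((params["theta"] - truth) ** 2, weights=w))
        assert rmse_adj < rmse_rej
        assert np.average(adj["theta"], weights=w) == pytest.approx(truth, rel=0.15)

    def test_zero_residuals_collapse_to_prediction(self, rng):
        prior = Prior("theta", "log-uniform", 0.01, 1.0)
        params, _ = self._linear_world(rng, noise=0.0)
        summaries = np.column_stack([
            np.log(params["theta"]), np.ones(len(params))])
        summaries[:, 1] += rng.normal(0, 1, len(params))  # irrelevant stat
        obs = np.array([np.log(0.1), 0.0])
        dist = np.abs(summaries[:, 0] - obs[0])
        adj, _ = regression_adjust(params, summaries, obs, dist, [prior])
        assert np.allclose(adj["theta"], 0.1, rtol=1e-6)

    def test_uninformative_summaries_leave_distribution(self, rng):
        from scipy.stats import ks_2samp

        prior = Prior("theta", "log-uniform", 0.01, 1.0)
        theta = prior.sample(500, rng)
        params = pd.DataFrame({"theta": theta})
        summaries = rng.normal(size=(500, 3))
        obs = np.zeros(3)
        dist = np.sqrt((summaries**2).sum(axis=1))
        adj, _ = regression_adjust(params, summaries, obs, dist, [prior])
        assert ks_2samp(adj["theta"], params["theta"]).pvalue > 0.01

    def test_needs_enough_draws(self, rng):
        prior = Prior("theta", "log-uniform", 0.01, 1.0)
        with pytest.raises(ValueError):
            regression_adjust(pd.DataFrame({"theta": [0.1] * 10}),
                              rng.normal(size=(10, 2)), np.zeros(2),
                              np.ones(10), [prior])


class TestModelProbabilities:
    def test_identical_models_split_evenly(self, rng):
        sims = rng.normal(size=(2000, 3))
        tables = {"m1": (None, sims),
                  "m2": (None, sims + rng.normal(0, 1e-6, sims.shape))}
        probs, rej = model_probabilities(tables, np.zeros(3), 0.05)
        assert probs["m1"] == pytest.approx(0.5, abs=0.1)
        assert sum(probs.values()) == pytest.approx(1.0)
        assert sum(rej.values()) == pytest.approx(1.0)

    def test_rejection_proportion_definition(self, rng):
        t1 = rng.normal(0, 1, size=(1000, 2))
        t2 = rng.normal(4, 1, size=(1000, 2))
        obs = np.zeros(2)
        probs, rej = model_probabilities({"near": (None, t1),
                                          "far": (None, t2)}, obs, 0.02)
        # proportions are the per-model share of the pooled accepted set
        pooled = np.vstack([t1, t2])
        idx, _ = abc_reject(obs, pooled, 0.02)
        want_near = (idx < 1000).mean()
        assert rej["near"] == pytest.approx(want_near)
        assert rej["near"] + rej["far"] == pytest.approx(1.0)
        assert probs["near"] > probs["far"]
        assert rej["near"] > rej["far"]

    def test_order_invariance(self, rng):
        t1 = rng.normal(0, 1, size=(800, 2))
        t2 = rng.normal(2, 1, size=(800, 2))
        obs = np.zeros(2)
        p_a, _ = model_probabilities({"a": (None, t1), "b": (None, t2)}, obs, 0.05)
        p_b, _ = model_probabilities({"b": (None, t2), "a": (None, t1)}, obs, 0.05)
        assert p_a["a"] == pytest.approx(p_b["a"], abs=0.05)


class TestPosteriorSummary:
    def test_gaussian_mode_near_mean(self, rng):
        x = rng.normal(3.0, 0.5, 4000)
        mode, lo, hi = posterior_summary(x)
        assert mode == pytest.approx(3.0, abs=0.1)
        assert lo == pytest.approx(3.0 - 1.96 * 0.5, abs=0.1)
        assert hi == pytest.approx(3.0 + 1.96 * 0.5, abs=0.1)

    def test_point_mass(self):
        mode, lo, hi = posterior_summary(np.full(100, 2.5))
        assert (mode, lo, hi) == (2.5, 2.5, 2.5)

    def test_uniform_weights_reduce_to_unweighted(self, rng):
        x = rng.normal(size=500)
        a = posterior_summary(x)
        b = posterior_summary(x, np.ones(500))
        assert a == b

    def test_weighted_quantile_matches_numpy_when_uniform(self, rng):
        x = rng.normal(size=2001)
        q = weighted_quantile(x, [0.025, 0.5, 0.975], np.ones_like(x))
        want = np.quantile(x, [0.025, 0.5, 0.975])
        assert np.allclose(q, want, atol=0.01)


class TestSummaries:
    def test_identical_loci_zero_variance(self, rng):
        h = simulate_locus(NeutralParams(theta=0.02), LocusSpec((10,), 300), rng)
        while h.S == 0:
            h = simulate_locus(NeutralParams(theta=0.02), LocusSpec((10,), 300), rng)
        vec = summarize_single([h] * 14)
        assert vec[1] == pytest.approx(0.0, abs=1e-20)
        assert vec[3] == pytest.approx(0.0, abs=1e-20)
        assert vec[5] == pytest.approx(0.0, abs=1e-20)

    def test_monomorphic_loci_excluded_from_D(self, rng):
        h1 = simulate_locus(NeutralParams(theta=0.05), LocusSpec((10,), 300), rng)
        empty = HaplotypeMatrix(np.zeros((10, 0), dtype=np.uint8),
                                np.zeros(0), np.zeros(10, int), 300)
        vec = summarize_single([h1, h1, empty])
        # D mean/variance computed over the two polymorphic loci only
        assert vec[3] == 0.0
        assert not math.isnan(vec[2])

    def test_needs_two_loci(self, rng):
        h = simulate_locus(NeutralParams(theta=0.02), LocusSpec((10,), 300), rng)
        with pytest.raises(ValueError):
            summarize_single([h])

    def test_twopop_counts_delegate_to_classifier(self, rng):
        from locuspair.coalescent import SplitParams, to_nucleotides

        h = simulate_locus(SplitParams(theta=0.01, t_s=1.0),
                           LocusSpec((8, 8), 400), rng)
        vec = summarize_twopop([h])
        seqs, _ = to_nucleotides(h, rng)
        ids = [f"s{i}|spp|hap1" for i in range(16)]
        a1 = Alignment(seqs[:8], ids[:8])
        a2 = Alignment(seqs[8:], ids[8:])
        d = classify_polymorphisms(a1, a2)
        assert vec[10] == d.shared
        assert vec[11] == d.fixed
        assert vec[12] == d.private1 + d.private2

    def test_identical_populations_no_divergence(self, rng):
        h = simulate_locus(NeutralParams(theta=0.02), LocusSpec((8,), 400), rng)
        while h.S == 0:
            h = simulate_locus(NeutralParams(theta=0.02), LocusSpec((8,), 400), rng)
        joint = HaplotypeMatrix(np.vstack([h.matrix, h.matrix]),
                                h.positions,
                                np.repeat([0, 1], 8), 400)
        vec = summarize_twopop([joint, joint])
        assert vec[11] == 0  # no fixed differences
        assert abs(vec[9]) < 0.2


class TestUnitConversions:
    def test_effective_size_values(self):
        assert effective_size(0.0016, 1e-9, 10) == pytest.approx(40_000)
        assert effective_size(0.0033, 1e-9, 10) == pytest.approx(82_500)
        assert effective_size(0.0032, 1e-9, 10) == pytest.approx(
            2 * effective_size(0.0016, 1e-9, 10))

    def test_split_time_values(self):
        assert split_time_years(0.32, 40_000, 10) == pytest.approx(512_000)
        assert round_sig(split_time_years(0.32, 40_000, 10)) == 510_000
        assert round_sig(split_time_years(0.44, 40_000, 10)) == 700_000
        assert split_time_years(0.0, 40_000, 10) == 0.0

    def test_round_sig(self):
        assert round_sig(5.9e-9 / 6, 2) == pytest.approx(9.8e-10)
        assert round_sig(0.0) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            effective_size(0, 1e-9, 10)
        with pytest.raises(ValueError):
            split_time_years(-1, 40_000, 10)


class TestModelResultsSurface:
    def test_fit_summary_and_determinism(self, rng):
        truth = NeutralParams(theta=0.01, rho=0.005)
        specs = [LocusSpec((12,), 200)] * 6
        obs = [simulate_locus(truth, s, rng) for s in specs]
        abc = DemographicABC(obs, [neutral_model()], specs, p_delta=0.1)
        res1 = abc.fit(n_draws=600, seed=42)
        res2 = abc.fit(n_draws=600, seed=42)
        assert res1.posteriors["neutral"]["theta"].tolist() == \
            res2.posteriors["neutral"]["theta"].tolist()
        text = res1.summary()
        assert "neutral" in text and "theta" in text
        mode, lo, hi = res1.posterior_summary("neutral", "theta")
        assert lo <= mode <= hi or lo <= hi  # CI ordered
        assert lo < hi
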
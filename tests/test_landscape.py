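"""Adaptive walks, local-maximum enumeration, random-sequence distributions
and two-environment Pareto dominance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import (
    all_sequences,
    brute_force_local_maxima,
    reciprocal_sign_pair_model,
)
from promland.codec import mutation_indicator_index
from promland.landscape import (
    adaptive_walk,
    enumerate_local_maxima,
    pareto_analysis,
    random_phenotype_sample,
    walk_census,
)
from promland.model import LandscapeModel, random_sequences
from promland.simulate import sample_landscape


class TestAdaptiveWalk:
    def test_all_deleterious_stays_at_wildtype(self):
        wt = "ACGT"
        model = LandscapeModel(2.0, -np.ones(12))
        res = adaptive_walk(model, wt, seed=0)
        assert res.endpoint == wt and res.steps == 0 and res.converged

    @pytest.mark.parametrize("seed", [0, 7, 99])
    def test_additive_landscape_single_peak(self, seed):
        rng = np.random.default_rng(5)
        wt = "ACGTA"
        model = LandscapeModel(0.0, rng.normal(size=15))
        res = adaptive_walk(model, wt, seed=seed)
        # per-site argmax endpoint, independent of the walk's randomness
        expect = []
        for i, wb in enumerate(wt):
            options = {wb: 0.0}
            for b in "ACGT":
                if b != wb:
                    options[b] = model.beta[3 * i + mutation_indicator_index(wb, b)]
            expect.append(max(options, key=options.get))
        assert res.endpoint == "".join(expect)
        assert res.converged

    def test_values_strictly_increase(self):
        model, wt = reciprocal_sign_pair_model()
        # replay the walk step by step via its seeded determinism
        r1 = adaptive_walk(model, wt, seed=3)
        r2 = adaptive_walk(model, wt, seed=3)
        assert r1.endpoint == r2.endpoint and r1.steps == r2.steps
        assert r1.value >= model.predict([wt], wt)[0]

    def test_endpoint_is_local_maximum(self, small_truth):
        res = adaptive_walk(small_truth.model, small_truth.wildtype, seed=11)
        vals = small_truth.model.predict(
            [res.endpoint], small_truth.wildtype
        )[0]
        for i in range(len(res.endpoint)):
            for b in "ACGT":
                if b == res.endpoint[i]:
                    continue
                n = res.endpoint[:i] + b + res.endpoint[i + 1 :]
                assert (
                    small_truth.model.predict([n], small_truth.wildtype)[0]
                    <= vals + 1e-9
                )

    def test_nonconvergence_flagged(self):
        rng = np.random.default_rng(6)
        model = LandscapeModel(0.0, rng.normal(size=30) + 2.0)
        res = adaptive_walk(model, "A" * 10, seed=0, max_steps=2)
        assert not res.converged

    def test_log1p_rule_also_walks_uphill(self):
        model, wt = reciprocal_sign_pair_model()
        res = adaptive_walk(model, wt, seed=1, rule="log1p")
        assert res.value >= model.predict([wt], wt)[0]


class TestWalkCensus:
    def test_additive_single_endpoint(self):
        rng = np.random.default_rng(8)
        model = LandscapeModel(0.0, rng.normal(size=12))
        df = walk_census(model, "ACGT", n_walks=50, seed=0)
        assert len(df) == 1
        assert df["count"].sum() == 50

    def test_two_peak_model_finds_both(self):
        model, wt = reciprocal_sign_pair_model()
        oracle = brute_force_local_maxima(model, wt)
        assert len(oracle) == 2  # sanity of the construction
        df = walk_census(model, wt, n_walks=200, seed=1, start="random")
        assert set(df["endpoint"]) == set(oracle)

    def test_endpoints_subset_of_enumerated_maxima(self, small_truth):
        df = walk_census(small_truth.model, small_truth.wildtype, n_walks=20, seed=2)
        # restrict enumeration to the sites the endpoints actually mutate
        for _, row in df.iterrows():
            vals = small_truth.model.predict(
                [row["endpoint"]], small_truth.wildtype
            )[0]
            assert row["value"] == pytest.approx(vals)


class TestEnumerateLocalMaxima:
    def test_additive_restriction_single_maximum(self):
        rng = np.random.default_rng(9)
        model = LandscapeModel(0.0, rng.normal(size=18))
        df = enumerate_local_maxima(model, "ACGTAC", site_subset=[0, 2, 4])
        assert len(df) == 1

    def test_reciprocal_sign_pair_two_maxima(self):
        model, wt = reciprocal_sign_pair_model()
        df = enumerate_local_maxima(model, wt, site_subset=[0, 1])
        oracle = brute_force_local_maxima(model, wt)
        assert sorted(df["sequence"]) == sorted(oracle)
        for _, row in df.iterrows():
            assert row["value"] == pytest.approx(oracle[row["sequence"]])

    def test_matches_brute_force_on_random_models(self):
        for seed in (1, 2, 3):
            truth = sample_landscape(
                4,
                region_map=__import__("promland").RegionMap({"B": (0, 4)}, 4),
                epistatic_sparsity=0.15,
                epistatic_scale=1.5,
                seed=seed,
            )
            df = enumerate_local_maxima(truth.model, truth.wildtype, [0, 1, 2, 3])
            oracle = brute_force_local_maxima(truth.model, truth.wildtype)
            assert sorted(df["sequence"]) == sorted(oracle)

    def test_walk_endpoints_appear_in_enumeration(self):
        model, wt = reciprocal_sign_pair_model()
        df = walk_census(model, wt, n_walks=100, seed=4)
        enum = set(enumerate_local_maxima(model, wt, [0, 1])["sequence"])
        assert set(df["endpoint"]) <= enum

    def test_subset_cap(self):
        model = LandscapeModel(0.0, np.zeros(36))
        with pytest.raises(ValueError):
            enumerate_local_maxima(model, "A" * 12, list(range(11)))


class TestRandomPhenotypeSample:
    def test_zero_model_degenerate(self):
        model = LandscapeModel(3.0, np.zeros(12))
        out = random_phenotype_sample(model, "ACGT", n=500, seed=0)
        assert np.ptp(out["predictions"]) == 0.0
        assert out["wildtype_value"] == 3.0

    def test_additive_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(10)
        wt = "ACGTA"
        model = LandscapeModel(0.0, rng.normal(size=15))
        out = random_phenotype_sample(model, wt, n=30_000, seed=1)
        exact = model.predict(all_sequences(5), wt)
        assert out["predictions"].mean() == pytest.approx(exact.mean(), abs=0.03)
        assert out["predictions"].var() == pytest.approx(exact.var(), rel=0.05)

    def test_wildtype_above_random_for_selected_truth(self, small_truth):
        out = random_phenotype_sample(
            small_truth.model, small_truth.wildtype, n=5000, seed=2
        )
        assert out["wildtype_percentile"] > 95.0


class TestPareto:
    def test_wildtype_alone_no_dominance(self):
        model = LandscapeModel(1.0, np.arange(12, dtype=float))
        rep = pareto_analysis(model, model, ["ACGT"], "ACGT", n_random=0)
        assert rep.fraction_dominating == 0.0

    def test_hand_built_one_of_three(self):
        wt = "AA"
        beta_a = np.zeros(6)
        beta_a[mutation_indicator_index("A", "C")] = 1.0  # site 0 A->C helps in A
        model_a = LandscapeModel(0.0, beta_a)
        beta_b = np.zeros(6)
        beta_b[mutation_indicator_index("A", "C")] = -1.0  # and hurts in B
        model_b = LandscapeModel(0.0, beta_b)
        seqs = ["CA", "AA", "AG"]  # dominator, wild type itself, neutral-in-A
        rep = pareto_analysis(model_a, model_b, seqs, wt, n_random=0)
        assert rep.fraction_dominating == pytest.approx(1 / 3)

    def test_brute_force_agreement(self, small_truth):
        rng = np.random.default_rng(11)
        other = sample_landscape(
            20, region_map=small_truth.region_map, epistatic_sparsity=0.0, seed=77,
            wildtype=small_truth.wildtype,
        )
        seqs = random_sequences(1000, 20, rng)
        rep = pareto_analysis(
            small_truth.model, other.model, seqs, small_truth.wildtype, n_random=0
        )
        wt_a = small_truth.model.predict([small_truth.wildtype], small_truth.wildtype)[0]
        wt_b = other.model.predict([small_truth.wildtype], small_truth.wildtype)[0]
        for _, row in rep.table.iterrows():
            expect = (
                small_truth.model.predict([row["sequence"]], small_truth.wildtype)[0] > wt_a
            ) and (
                other.model.predict([row["sequence"]], small_truth.wildtype)[0] < wt_b
            )
            assert row["dominates_wildtype"] == expect

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_dominance_irreflexive_antisymmetric(self, seed):
        rng = np.random.default_rng(seed)
        pa, pb = rng.normal(size=2), rng.normal(size=2)
        dom_ab = pa[0] > pa[1] and pb[0] < pb[1]
        dom_ba = pa[1] > pa[0] and pb[1] < pb[0]
        assert not (dom_ab and dom_ba)          # antisymmetric
        assert not (pa[0] == pa[0] and pa[0] > pa[0])  # irreflexive by strictness
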
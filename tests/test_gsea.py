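import numpy as np
import pytest

from dheascreen.diffexpr import GeneSet
from dheascreen.errors import DesignError, EvaluationError
from dheascreen.gsea import (RankedList, _es_from_hits, collapse_probes,
                             enrichment_score, nes_and_fdr, nominal_p,
                             permutation_null, run_gsea, signal_to_noise_rank)

from conftest import make_matrix


def naive_es(scores, hit_mask, weight):
    """Reference ES: materialize the running sum step by step."""
    n = len(scores)
    k = int(np.sum(hit_mask))
    nr = sum(abs(scores[i]) ** weight for i in range(n) if hit_mask[i])
    running = 0.0
    lo, hi = 0.0, -np.inf
    for i in range(n):
        if hit_mask[i]:
            running += (abs(scores[i]) ** weight) / nr if nr > 0 else 0.0
        else:
            running -= 1.0 / (n - k)
        hi = max(hi, running)
        lo = min(lo, running)
    # documented tie rule: positive deviation wins (1e-9 slack)
    return hi if hi + lo >= -1e-9 else lo


def ranked(scores, genes=None):
    scores = np.asarray(scores, dtype=float)
    genes = np.asarray(genes if genes is not None
                       else [f"g{i + 1}" for i in range(len(scores))],
                       dtype=object)
    return RankedList(genes=genes, scores=scores, class_a=("a1", "a2"),
                      class_b=("b1", "b2"))


def random_instance(rng, n_max=50):
    n = int(rng.integers(5, n_max + 1))
    scores = np.sort(rng.normal(0, 2, n))[::-1]
    k = int(rng.integers(1, n))
    hits = rng.choice(n, k, replace=False)
    mask = np.zeros(n, dtype=bool)
    mask[hits] = True
    return scores, mask


class TestSignalToNoise:
    def test_equal_means_score_zero(self):
        m = make_matrix([[1.0, 2.0, 1.0, 2.0]],
                        samples=["a1", "a2", "b1", "b2"])
        r = signal_to_noise_rank(m, ["a1", "a2"], ["b1", "b2"])
        assert r.scores[0] == pytest.approx(0.0)

    def test_worked_example_with_sd_floor(self):
        # A=[2,4]: sd=sqrt(2); B=[1,1]: sd floored to 0.2*|1|
        m = make_matrix([[2.0, 4.0, 1.0, 1.0]],
                        samples=["a1", "a2", "b1", "b2"])
        r = signal_to_noise_rank(m, ["a1", "a2"], ["b1", "b2"])
        expected = (3.0 - 1.0) / (np.sqrt(2.0) + 0.2)
        assert r.scores[0] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(1.239, abs=5e-4)

    def test_zero_mean_floor(self):
        # B mean 0 -> sd floor is the bare 0.2
        m = make_matrix([[1.0, 1.0, 0.0, 0.0]],
                        samples=["a1", "a2", "b1", "b2"])
        r = signal_to_noise_rank(m, ["a1", "a2"], ["b1", "b2"])
        assert r.scores[0] == pytest.approx(1.0 / (0.2 + 0.2))

    def test_negating_matrix_reverses_list(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(25, 6))
        samples = ["a1", "a2", "a3", "b1", "b2", "b3"]
        m = make_matrix(vals, samples=samples)
        m_neg = make_matrix(-vals, samples=samples)
        r = signal_to_noise_rank(m, samples[:3], samples[3:])
        r_neg = signal_to_noise_rank(m_neg, samples[:3], samples[3:])
        assert list(r.genes) == list(r_neg.genes[::-1])
        np.testing.assert_allclose(r.scores, -r_neg.scores[::-1])

    def test_descending_with_gene_id_tiebreak(self):
        m = make_matrix([[1.0, 1.0, 0.0, 0.0]] * 3,
                        genes=["gC", "gA", "gB"],
                        samples=["a1", "a2", "b1", "b2"])
        r = signal_to_noise_rank(m, ["a1", "a2"], ["b1", "b2"])
        assert list(r.genes) == ["gA", "gB", "gC"]

    def test_small_class_raises(self):
        m = make_matrix([[1.0, 2.0, 3.0]], samples=["a1", "b1", "b2"])
        with pytest.raises(DesignError):
            signal_to_noise_rank(m, ["a1"], ["b1", "b2"])


class TestCollapse:
    def test_max_mean_keeps_brightest_probe(self):
        m = make_matrix([[1.0, 2.0], [5.0, 6.0], [3.0, 3.0]],
                        genes=["p1", "p2", "p3"],
                        gene_map=["gA", "gA", "gB"])
        out = collapse_probes(m)
        assert list(out.values.index) == ["gA", "gB"]
        np.testing.assert_allclose(out.values.loc["gA"], [5.0, 6.0])

    def test_median_collapse(self):
        m = make_matrix([[1.0], [3.0], [8.0]],
                        genes=["p1", "p2", "p3"],
                        gene_map=["gA", "gA", "gA"])
        out = collapse_probes(m, how="median")
        assert out.values.loc["gA", "s1"] == pytest.approx(3.0)


class TestEnrichmentScore:
    def test_weight_zero_top_k_set_gives_one(self):
        r = ranked(np.linspace(5, -5, 20))
        profile = enrichment_score(r, ["g1", "g2", "g3"], weight=0.0)
        assert profile.es == pytest.approx(1.0)

    def test_worked_example(self):
        # scores 5..1, -1..-5; set {g1, g6}: N_R = 6, peak 5/6 after g1
        r = ranked([5, 4, 3, 2, 1, -1, -2, -3, -4, -5])
        profile = enrichment_score(r, ["g1", "g6"], weight=1.0)
        assert profile.es == pytest.approx(5.0 / 6.0)
        assert profile.running_sum[0] == pytest.approx(5.0 / 6.0)
        assert profile.running_sum[-1] == pytest.approx(0.0, abs=1e-12)
        assert list(profile.hit_positions) == [0, 5]

    def test_bottom_set_gives_negative_es(self):
        r = ranked(np.linspace(5, -5, 20))
        profile = enrichment_score(r, ["g19", "g20"])
        assert profile.es < -0.5

    @pytest.mark.parametrize("weight", [0.0, 1.0])
    def test_matches_naive_oracle(self, weight):
        rng = np.random.default_rng(42)
        for _ in range(300):
            scores, mask = random_instance(rng)
            r = ranked(scores)
            profile = enrichment_score(r, r.genes[mask], weight=weight)
            assert profile.es == pytest.approx(
                naive_es(scores, mask, weight), abs=1e-12)
            assert -1.0 <= profile.es <= 1.0

    @pytest.mark.parametrize("weight", [0.0, 1.0])
    def test_hit_based_path_matches_naive_oracle(self, weight):
        rng = np.random.default_rng(43)
        for _ in range(300):
            scores, mask = random_instance(rng)
            absw = np.abs(scores) ** weight
            es = _es_from_hits(absw, np.flatnonzero(mask), len(scores))
            assert es == pytest.approx(naive_es(scores, mask, weight),
                                       abs=1e-12)

    def test_reversal_antisymmetry(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            scores, mask = random_instance(rng, n_max=30)
            es = naive_es(scores, mask, 1.0)
            r_fwd = ranked(scores)
            profile = enrichment_score(r_fwd, r_fwd.genes[mask])
            r_rev = ranked(-scores[::-1],
                           genes=r_fwd.genes[::-1])
            profile_rev = enrichment_score(r_rev, r_fwd.genes[mask])
            assert profile.es == pytest.approx(es, abs=1e-12)
            assert profile_rev.es == pytest.approx(-es, abs=1e-12)

    def test_no_member_raises(self):
        r = ranked([3, 2, 1])
        with pytest.raises(EvaluationError):
            enrichment_score(r, ["absent"])

    def test_full_coverage_raises(self):
        r = ranked([3, 2, 1])
        with pytest.raises(EvaluationError):
            enrichment_score(r, ["g1", "g2", "g3"])


class TestPermutationNull:
    def test_seed_determinism(self):
        r = ranked(np.linspace(3, -3, 40))
        a = permutation_null(r, 5, n_perm=50, seed=7)
        b = permutation_null(r, 5, n_perm=50, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_positive_skew_shifts_small_set_null(self):
        # heavy positive scores: random small sets peak early on average
        scores = np.sort(np.abs(np.random.default_rng(1).normal(
            2, 1, 60)))[::-1]
        r = ranked(scores * np.where(np.arange(60) < 50, 1, -1))
        null = permutation_null(r, 3, n_perm=400, seed=3)
        assert null.mean() > 0

    def test_set_size_bounds(self):
        r = ranked([3, 2, 1])
        with pytest.raises(DesignError):
            permutation_null(r, 3, n_perm=10, seed=0)

    def test_null_es_in_range(self):
        r = ranked(np.random.default_rng(2).normal(size=100))
        null = permutation_null(r, 10, n_perm=200, seed=1)
        assert np.all((null >= -1) & (null <= 1))


class TestNominalP:
    def test_counting_example(self):
        assert nominal_p(0.35, np.array([0.1, 0.2, 0.3, 0.4, 0.5])) == \
            pytest.approx(2.0 / 5.0)

    def test_es_beyond_all_permutations_gives_zero(self):
        assert nominal_p(0.9, np.array([0.1, 0.2, -0.5])) == 0.0

    def test_median_es_gives_half(self):
        null = np.linspace(0.01, 0.99, 99)
        assert nominal_p(0.5, null) == pytest.approx(0.5, abs=0.02)

    def test_negative_side_mirrored(self):
        null = np.array([-0.4, -0.2, 0.3, 0.5])
        assert nominal_p(-0.3, null) == pytest.approx(0.5)

    def test_no_same_sign_scores_fallback(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            p = nominal_p(-0.2, np.array([0.1, 0.2, 0.3]))
        assert p == pytest.approx(1.0 / 4.0)
        assert "same-sign" in caplog.text


class TestNesAndFdr:
    def test_es_beyond_all_permutations_gives_zero_q(self):
        null = np.array([0.1, 0.2, 0.3, -0.1, -0.2])
        res = nes_and_fdr([("s1", ("IM", "CTR1"), 0.9, null, 0.0, 10)])
        assert res[0].fdr_q == pytest.approx(0.0)
        assert res[0].significant

    def test_observed_matching_null_gives_q_near_one(self):
        rng = np.random.default_rng(0)
        null = rng.normal(0, 0.3, 400)
        es = float(np.median(np.abs(null)))
        res = nes_and_fdr([("s1", ("IM", "CTR1"), es, null, 0.5, 10)])
        assert res[0].fdr_q > 0.5
        assert not res[0].significant

    def test_three_sets_match_counting_oracle(self):
        # hand-built nulls of size 10; raw tail ratios are monotone here so
        # the oracle is plain counting
        null = np.array([0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4, 0.45,
                         -0.2, -0.4])
        entries = [
            ("a", ("IM", "CTR1"), 0.5, null, 0.0, 5),
            ("b", ("IM", "CTR1"), 0.3, null, 0.3, 5),
            ("c", ("IM", "CTR1"), 0.2, null, 0.6, 5),
        ]
        res = nes_and_fdr(entries)
        pos = null[null >= 0]
        mpos = pos.mean()
        nes = np.array([0.5, 0.3, 0.2]) / mpos
        pooled = np.concatenate([pos / mpos] * 3 +
                                [null[null < 0] / 0.3] * 3)
        for i, r in enumerate(res):
            assert r.nes == pytest.approx(nes[i], rel=1e-12)
            frac_null = (pooled >= nes[i]).sum() / (pooled >= 0).sum()
            frac_obs = (nes >= nes[i]).sum() / 3
            assert r.fdr_q == pytest.approx(min(1.0, frac_null / frac_obs),
                                            rel=1e-12)

    def test_significance_rule(self):
        null = np.array([0.1, 0.2, 0.3, -0.1, -0.2])
        res = nes_and_fdr([
            ("sig", ("IM", "CTR1"), 0.9, null, 0.01, 5),
            ("not_sig_p", ("IM", "CTR1"), 0.9, null, 0.2, 5),
        ])
        by_name = {r.set_name: r for r in res}
        assert by_name["sig"].significant
        assert not by_name["not_sig_p"].significant

    def test_sign_consistency_of_nes(self):
        rng = np.random.default_rng(4)
        null = rng.normal(0, 0.3, 200)
        for es in (0.4, -0.4):
            res = nes_and_fdr([("s", ("IM", "CTR1"), es, null, 0.1, 5)])
            assert np.sign(res[0].nes) == np.sign(es)

    def test_degenerate_null_flagged(self):
        null = np.array([-0.1, -0.2, -0.3])
        res = nes_and_fdr([("s", ("IM", "CTR1"), 0.5, null, 0.1, 5)])
        assert res[0].degenerate
        assert not res[0].significant


class TestRunGsea:
    def test_planted_set_significant_null_set_not(self):
        rng = np.random.default_rng(10)
        n = 400
        vals = rng.normal(0, 0.3, size=(n, 7))
        vals[:25, :3] += 1.2  # planted block in class A
        samples = [f"a{i}" for i in range(3)] + [f"b{i}" for i in range(4)]
        m = make_matrix(vals, samples=samples)
        planted = GeneSet("planted", tuple(f"g{i + 1}" for i in range(25)))
        random_set = GeneSet("random", tuple(
            f"g{i}" for i in rng.choice(np.arange(26, n), 25, replace=False)))
        res = run_gsea(m, samples[:3], samples[3:], [planted, random_set],
                       n_perm=200, seed=5)
        by_name = {r.set_name: r for r in res}
        assert by_name["planted"].significant
        assert by_name["planted"].p_nominal < 0.01
        assert not by_name["random"].significant

    def test_nominal_p_calibration_light(self):
        # null data, random target sets: rejection at 0.05 stays near 0.05
        rng = np.random.default_rng(21)
        vals = rng.normal(0, 0.3, size=(300, 7))
        samples = [f"a{i}" for i in range(3)] + [f"b{i}" for i in range(4)]
        m = make_matrix(vals, samples=samples)
        ranked_list = signal_to_noise_rank(m, samples[:3], samples[3:])
        rejections = 0
        n_trials = 150
        for t in range(n_trials):
            target = rng.choice(300, 20, replace=False)
            es = _es_from_hits(np.abs(ranked_list.scores),
                               np.sort(target), 300)
            null = permutation_null(ranked_list, 20, n_perm=100,
                                    seed=rng)
            if nominal_p(es, null) < 0.05:
                rejections += 1
        # generous band around the expected 7.5 of 150 trials
        assert 1 <= rejections <= 18
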
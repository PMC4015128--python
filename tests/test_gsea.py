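import numpy as np
import pytest
from scipy import stats as sps

from pcamsea import (
    MetaboliteSetList,
    RankedList,
    enrichment_score,
    leading_edge,
    msea_sub,
    normalize_and_test,
    permutation_null,
)


def brute_force_es(metric, hits, weight):
    """O(N*N) direct recomputation of the running sum and its extremum."""
    metric = np.asarray(metric, dtype=float)
    hits = np.asarray(hits, dtype=bool)
    N = metric.size
    n_hit = hits.sum()
    w = np.abs(metric) ** weight
    denom = w[hits].sum()
    running = []
    for i in range(1, N + 1):
        if denom > 0:
            p_hit = sum(w[j] for j in range(i) if hits[j]) / denom
        else:
            p_hit = sum(1 for j in range(i) if hits[j]) / n_hit
        p_miss = sum(1 for j in range(i) if not hits[j]) / (N - n_hit)
        running.append(p_hit - p_miss)
    running = np.array(running)
    k = int(np.argmax(np.abs(running)))
    return running[k], k + 1, running


def random_instance(rng, n_max=50):
    N = int(rng.integers(3, n_max + 1))
    metric = np.sort(rng.normal(size=N))[::-1]
    ids = [f"m{i:03d}" for i in range(N)]
    size = int(rng.integers(1, N))
    members = set(rng.choice(ids, size=size, replace=False))
    return RankedList(ids, metric), members


class TestRankedList:
    def test_orders_descending_with_id_tiebreak(self):
        rl = RankedList.from_loadings(
            ["b", "a", "c"], np.array([0.5, 0.5, 0.9])
        )
        assert rl.metabolite_ids == ["c", "a", "b"]
        np.testing.assert_array_equal(rl.metric, [0.9, 0.5, 0.5])
        assert rl.rank_of("c") == 1

    def test_rejects_unsorted_metric(self):
        with pytest.raises(ValueError, match="descending"):
            RankedList(["a", "b"], [0.1, 0.9])


class TestEnrichmentScore:
    def test_single_member_at_top(self):
        rl = RankedList(["a", "b", "c"], [0.9, 0.5, 0.1])
        es, argext, _ = enrichment_score(rl, {"a"}, weight=1.0)
        assert es == 1.0 and argext == 1

    def test_single_member_at_bottom_hand_running_sum(self):
        rl = RankedList(["a", "b", "c"], [0.9, 0.5, 0.1])
        es, argext, running = enrichment_score(rl, {"c"}, weight=1.0)
        np.testing.assert_allclose(running, [-0.5, -1.0, 0.0])
        assert es == -1.0 and argext == 2

    def test_whole_or_empty_set_rejected(self):
        rl = RankedList(["a", "b", "c"], [0.9, 0.5, 0.1])
        with pytest.raises(ValueError):
            enrichment_score(rl, {"a", "b", "c"})
        with pytest.raises(ValueError):
            enrichment_score(rl, {"zzz"})

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(100):
            rl, members = random_instance(rng, n_max=30)
            for weight in (0.0, 1.0, 2.0):
                es, argext, running = enrichment_score(rl, members, weight)
                es_bf, arg_bf, run_bf = brute_force_es(
                    rl.metric,
                    [m in members for m in rl.metabolite_ids],
                    weight,
                )
                assert es == pytest.approx(es_bf, abs=1e-12)
                assert argext == arg_bf
                np.testing.assert_allclose(running, run_bf, atol=1e-12)

    def test_weight_zero_equals_ks_statistic(self, rng):
        for _ in range(50):
            rl, members = random_instance(rng, n_max=40)
            es, _, _ = enrichment_score(rl, members, weight=0.0)
            hit_ranks = [rl.rank_of(m) for m in members]
            miss_ranks = [
                rl.rank_of(m) for m in rl.metabolite_ids if m not in members
            ]
            ks = sps.ks_2samp(hit_ranks, miss_ranks).statistic
            assert abs(es) == pytest.approx(ks, abs=1e-12)

    def test_running_sum_returns_to_zero_unweighted(self, rng):
        rl, members = random_instance(rng)
        _, _, running = enrichment_score(rl, members, weight=0.0)
        assert running[-1] == pytest.approx(0.0, abs=1e-12)

    def test_es_bounded(self, rng):
        for _ in range(100):
            rl, members = random_instance(rng)
            es, _, _ = enrichment_score(rl, members, weight=1.0)
            assert -1 <= es <= 1


class TestPermutationNull:
    def test_seed_determinism(self):
        rl = RankedList([f"m{i}" for i in range(20)],
                        np.sort(np.random.default_rng(0).normal(size=20))[::-1])
        a = permutation_null(rl, 5, B=50, seed=123)
        b = permutation_null(rl, 5, B=50, seed=123)
        np.testing.assert_array_equal(a, b)
        assert a.size == 50

    def test_singleton_null_covers_exhaustive_enumeration(self):
        """With |S|=1 and flat weights the null support is the N singleton
        scores, symmetric about 0."""
        N = 8  # even: ranks k and N+1-k give exactly mirrored scores
        ids = [f"m{i}" for i in range(N)]
        rl = RankedList(ids, np.linspace(1, -1, N))
        exhaustive = np.array(
            [enrichment_score(rl, {m}, weight=0.0)[0] for m in ids]
        )
        assert exhaustive.sum() == pytest.approx(0.0, abs=1e-12)
        null = permutation_null(rl, 1, weight=0.0, B=500, seed=9)
        assert set(np.round(null, 12)) <= set(np.round(exhaustive, 12))
        assert abs(null.mean()) < 3 * exhaustive.std() / np.sqrt(500)

    def test_invalid_set_size(self):
        rl = RankedList(["a", "b"], [1.0, 0.0])
        with pytest.raises(ValueError):
            permutation_null(rl, 2, B=10, seed=0)
        with pytest.raises(ValueError):
            permutation_null(rl, 0, B=10, seed=0)


class TestNormalizeAndTest:
    def test_hand_computation(self):
        nes, p = normalize_and_test(0.5, [0.25, 0.75, -0.5])
        assert nes == pytest.approx(1.0)
        assert p == pytest.approx(2 / 3)

    def test_fixed_point_and_add_one_rule(self):
        null = np.array([0.2, 0.4, -0.1])
        nes, p = normalize_and_test(0.3, null)  # mean positive null = 0.3
        assert nes == pytest.approx(1.0)
        nes, p = normalize_and_test(0.99, null)  # beyond every null
        assert p == pytest.approx(1 / 3)  # (1+0)/(1+2 same-sign)

    def test_sign_preserved_and_p_positive(self, rng):
        null = rng.normal(scale=0.3, size=200)
        for es in (-0.7, -0.2, 0.2, 0.7):
            nes, p = normalize_and_test(es, null)
            assert np.sign(nes) == np.sign(es)
            assert 0 < p <= 1

    def test_no_same_sign_null_warns(self):
        with pytest.warns(UserWarning, match="share the sign"):
            nes, p = normalize_and_test(-0.5, [0.1, 0.2])
        assert nes < 0 and 0 < p <= 1

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            normalize_and_test(0.5, [])


class TestLeadingEdge:
    def test_single_member_at_top(self):
        rl = RankedList(["a", "b", "c"], [0.9, 0.5, 0.1])
        assert leading_edge(rl, {"a"}, 1, 1.0) == {"a"}

    def test_argext_at_end_positive_es_whole_pathway(self):
        rl = RankedList(["a", "b", "c", "d"], [0.9, 0.5, 0.2, 0.1])
        assert leading_edge(rl, {"a", "c"}, 4, 1.0) == {"a", "c"}

    def test_invariant_under_metric_negation(self, rng):
        """Flipping the ranking flips the ES sign but the leading-edge
        members are the same set (whenever the running-sum extremum is
        unambiguous; exact +/- ties are resolved by the first-position
        rule and are excluded here)."""
        checked = 0
        while checked < 30:
            rl, members = random_instance(rng, n_max=20)
            es, argext, running = enrichment_score(rl, members, weight=1.0)
            if np.sum(np.abs(np.abs(running) - abs(es)) < 1e-12) > 1:
                continue  # tied extremum: sign under negation is ambiguous
            le = leading_edge(rl, members, argext, es)
            flipped = RankedList(
                rl.metabolite_ids[::-1], -rl.metric[::-1]
            )
            es2, argext2, _ = enrichment_score(flipped, members, weight=1.0)
            le2 = leading_edge(flipped, members, argext2, es2)
            assert es2 == pytest.approx(-es, abs=1e-12)
            assert le2 == le
            checked += 1


class TestMseaSub:
    @pytest.fixture
    def ranked(self, rng):
        N = 40
        ids = [f"m{i:02d}" for i in range(N)]
        return RankedList(ids, np.sort(rng.normal(size=N))[::-1])

    def test_reproducible_under_seed(self, ranked):
        sets = MetaboliteSetList(
            [("top", ranked.metabolite_ids[:5]),
             ("mid", ranked.metabolite_ids[15:23])]
        )
        a = msea_sub(sets, ranked, B=200, seed=7)
        b = msea_sub(sets, ranked, B=200, seed=7)
        assert a.equals(b)
        c = msea_sub(sets, ranked, B=200, seed=8)
        assert not a["p_value"].equals(c["p_value"])

    def test_single_pathway_q_equals_p(self, ranked):
        sets = MetaboliteSetList([("top", ranked.metabolite_ids[:5])])
        df = msea_sub(sets, ranked, B=100, seed=0)
        assert df.loc[0, "q_value"] == df.loc[0, "p_value"]

    def test_top_pathway_positive_es_small_p(self, ranked):
        sets = MetaboliteSetList(
            [("top", ranked.metabolite_ids[:5]),
             ("bottom", ranked.metabolite_ids[-5:])]
        )
        df = msea_sub(sets, ranked, B=500, seed=1).set_index("pathway")
        assert df.loc["top", "ES"] > 0 and df.loc["top", "p_value"] < 0.05
        assert df.loc["bottom", "ES"] < 0
        assert np.sign(df.loc["top", "NES"]) == 1.0

    def test_undetected_pathway_flagged_not_dropped(self, ranked):
        sets = MetaboliteSetList(
            [("ghost", ["zzz1", "zzz2"]), ("top", ranked.metabolite_ids[:4])]
        )
        with pytest.warns(UserWarning, match="ghost"):
            df = msea_sub(sets, ranked, B=100, seed=0)
        assert list(df["pathway"]) == ["ghost", "top"]
        ghost = df.set_index("pathway").loc["ghost"]
        assert ghost["status"] == "no detected members"
        assert np.isnan(ghost["ES"]) and np.isnan(ghost["p_value"])

    def test_leading_edge_members_subset_of_pathway(self, ranked):
        sets = MetaboliteSetList([("top", ranked.metabolite_ids[:6])])
        df = msea_sub(sets, ranked, B=100, seed=2)
        le = set(df.loc[0, "leading_edge"].split(";"))
        assert le <= set(ranked.metabolite_ids[:6])
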
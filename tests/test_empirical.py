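"""Empirical resampling test: statistics, null sampling, exact oracle."""

import numpy as np
import pytest

import mirenrich as mr
from mirenrich.empirical import NullEngine, iter_null_batches


class TestObservedStatistics:
    def test_union_count_and_proportion_on_toy(self, toy_preds, toy_ann):
        lst = mr.MiRNAList(names=("a",))
        counts = mr.observed_statistic(toy_preds, toy_ann, lst, "union_count")
        props = mr.observed_statistic(toy_preds, toy_ann, lst, "union_proportion")
        assert counts["T1"] == 2
        assert props["T1"] == 1.0  # both targets annotated to T1

    def test_multihit_toy(self, multihit_preds, multihit_ann):
        lst = mr.MiRNAList(names=("a", "b"))
        stats = mr.observed_statistic(multihit_preds, multihit_ann, lst, "multihit")
        assert stats["TA"] == pytest.approx(2 / 3)  # (1+3)/6

    def test_empty_effective_target_set_errors(self, toy_ann):
        preds = mr.TargetPredictionSet({("a", "not-annotated"): 5})
        with pytest.raises(ValueError, match="universe"):
            mr.observed_statistic(preds, toy_ann, mr.MiRNAList(names=("a",)))


class TestGeneScores:
    def test_scores_sum_sites_across_mirnas(self, multihit_preds):
        scores = mr.multihit_gene_scores(multihit_preds, mr.MiRNAList(names=("a", "b")))
        assert scores.scores == {"g1": 2, "g2": 4}
        assert scores.total_score == 6

    def test_single_mirna_scores(self, multihit_preds):
        scores = mr.multihit_gene_scores(multihit_preds, mr.MiRNAList(names=("a",)))
        assert scores.scores == {"g1": 2, "g2": 1} and scores.total_score == 3

    def test_mirna_without_targets_contributes_nothing(self, multihit_preds):
        base = mr.multihit_gene_scores(multihit_preds, mr.MiRNAList(names=("a", "b")))
        preds2 = mr.TargetPredictionSet({**multihit_preds.sites, ("c", "elsewhere"): 1})
        ext = mr.multihit_gene_scores(
            preds2, mr.MiRNAList(names=("a", "b", "c")), universe={"g1", "g2", "g3"}
        )
        assert ext.scores == base.scores

    def test_universe_restriction_drops_outside_genes(self, multihit_preds):
        scores = mr.multihit_gene_scores(
            multihit_preds, mr.MiRNAList(names=("a", "b")), universe={"g2"}
        )
        assert scores.scores == {"g2": 4} and scores.total_score == 4

    def test_term_overlap_edge_cases(self, multihit_preds, multihit_ann):
        scores = mr.multihit_gene_scores(multihit_preds, mr.MiRNAList(names=("a", "b")))
        assert mr.multihit_term_overlap(scores, "TA", multihit_ann) == pytest.approx(2 / 3)
        # term disjoint from scored genes
        ann = mr.AnnotationSet({"TA": {"g2"}, "TZ": {"g9"}})
        assert mr.multihit_term_overlap(scores, "TZ", ann) == 0.0
        # term covering every scored gene
        ann_all = mr.AnnotationSet({"TALL": {"g1", "g2"}})
        assert mr.multihit_term_overlap(scores, "TALL", ann_all) == 1.0
        empty = mr.GeneScoreMap(scores={}, total_score=0)
        with pytest.raises(ValueError, match="total score"):
            mr.multihit_term_overlap(empty, "TA", multihit_ann)


class TestNullEngine:
    """The vectorised engine must agree with the set-based reference path."""

    @pytest.mark.parametrize("kind", ["union_count", "union_proportion", "multihit"])
    def test_engine_matches_set_based_statistics(self, small_random_toy, kind):
        preds, ann = small_random_toy
        eng = NullEngine(preds, ann, kind)
        rng = np.random.default_rng(3)
        for _ in range(5):
            idx = rng.choice(len(preds.mirna_ids), size=3, replace=False)
            lst = mr.MiRNAList(names=tuple(preds.mirna_ids[i] for i in idx))
            expected = mr.observed_statistic(preds, ann, lst, kind)
            got = eng.stats_for_subsets(np.sort(idx)[None, :])[0]
            for ti, t in enumerate(eng.term_ids):
                assert got[ti] == pytest.approx(expected[t], abs=1e-12)

    def test_draws_are_uniform_without_replacement(self):
        seen = set()
        for batch in iter_null_batches(n_mirnas=6, list_size=3, n_iterations=2000, seed=5):
            assert batch.shape[1] == 3
            for row in batch:
                assert len(set(row.tolist())) == 3
                seen.add(frozenset(row.tolist()))
        assert len(seen) == 20  # all C(6,3) subsets appear

    def test_prefix_stability_of_the_stream(self):
        a = np.vstack(list(iter_null_batches(10, 4, 2500, seed=9)))
        b = np.vstack(list(iter_null_batches(10, 4, 1200, seed=9)))
        assert np.array_equal(a[:1200], b)


class TestSampleNull:
    def test_degenerate_full_universe_draws(self, toy_preds, toy_ann):
        """When list_size equals the miRNA universe every draw is the full
        set, so exceedance is 0 or n exactly."""
        lst = mr.MiRNAList(names=toy_preds.mirna_ids)
        obs = mr.observed_statistic(toy_preds, toy_ann, lst, "union_count")
        summ = mr.sample_null(
            toy_preds, toy_ann, len(lst), obs, n_iterations=500, seed=1,
            statistic_kind="union_count",
        )
        assert set(summ.exceedance.tolist()) <= {0, 500}
        # observed equals the full-set statistic, so >= always holds
        assert (summ.exceedance == 500).all()
        assert summ.null_sd == pytest.approx(0.0)

    def test_same_seed_reproduces_bit_exactly(self, small_random_toy):
        preds, ann = small_random_toy
        lst = mr.MiRNAList(names=preds.mirna_ids[:3])
        obs = mr.observed_statistic(preds, ann, lst)
        kw = dict(list_size=3, observed=obs, n_iterations=3000, seed=42)
        s1 = mr.sample_null(preds, ann, **kw)
        s2 = mr.sample_null(preds, ann, **kw)
        assert np.array_equal(s1.exceedance, s2.exceedance)
        assert np.array_equal(s1.mean, s2.mean) and np.array_equal(s1.m2, s2.m2)

    def test_converges_to_pair_enumeration(self):
        """3 miRNAs, lists of 2: sampled exceedance converges to the exact
        proportion over the 3 possible pairs."""
        preds = mr.TargetPredictionSet(
            {("a", "g1"): 1, ("a", "g2"): 1, ("b", "g2"): 1, ("b", "g3"): 1, ("c", "g4"): 1}
        )
        ann = mr.AnnotationSet({"T": {"g1", "g2"}}, universe={"g1", "g2", "g3", "g4"})
        lst = mr.MiRNAList(names=("a", "b"))
        obs = mr.observed_statistic(preds, ann, lst, "union_count")  # T overlap = 2
        # pairs: {a,b} count 2; {a,c} count 2; {b,c} count 1 → exact p = 2/3
        summ = mr.sample_null(preds, ann, 2, obs, n_iterations=30000, seed=3,
                              statistic_kind="union_count")
        p = summ.p_values("plain")[summ.term_ids.index("T")]
        se = np.sqrt((2 / 3) * (1 / 3) / 30000)
        assert abs(p - 2 / 3) < 3 * se

    def test_moment_streaming_matches_direct_computation(self, small_random_toy):
        preds, ann = small_random_toy
        eng = NullEngine(preds, ann, "union_proportion")
        lst = mr.MiRNAList(names=preds.mirna_ids[:4])
        obs = mr.observed_statistic(preds, ann, lst)
        summ = mr.sample_null(preds, ann, 4, obs, n_iterations=2500, seed=8, engine=eng)
        stats = np.vstack(
            [eng.stats_for_subsets(b) for b in iter_null_batches(eng.n_mirnas, 4, 2500, 8)]
        )
        assert summ.null_mean == pytest.approx(stats.mean(axis=0))
        assert summ.null_sd == pytest.approx(stats.std(axis=0, ddof=1))

    def test_input_validation(self, toy_preds, toy_ann):
        lst = mr.MiRNAList(names=("a",))
        obs = mr.observed_statistic(toy_preds, toy_ann, lst)
        with pytest.raises(ValueError, match="list_size"):
            mr.sample_null(toy_preds, toy_ann, 99, obs, 10, 0)
        with pytest.raises(ValueError, match="n_iterations"):
            mr.sample_null(toy_preds, toy_ann, 1, obs, 0, 0)


class TestEmpiricalEnrichment:
    def test_p_rules_at_the_boundary(self, small_random_toy):
        """A list whose statistic exceeds every null draw gets p = 0 under
        the plain rule and 1/(n+1) under add_one."""
        preds, ann = small_random_toy
        # craft a dominating list: a miRNA targeting every universe gene
        sites = dict(preds.sites)
        for g in ann.universe:
            sites[("zz-super", g)] = 1
        preds2 = mr.TargetPredictionSet(sites)
        lst = mr.MiRNAList(names=("zz-super",))
        t_plain = mr.empirical_enrichment(preds2, ann, lst, n_iterations=200, seed=4,
                                          statistic_kind="union_count")
        t_add = mr.empirical_enrichment(preds2, ann, lst, n_iterations=200, seed=4,
                                        statistic_kind="union_count", p_rule="add_one")
        biggest = t_plain.frame["term_size"].idxmax()
        # the full-universe list attains the maximum count for every term,
        # so only draws tying it can match; for at least one term p is small
        assert (t_plain.frame["p_value"] <= t_add.frame["p_value"] + 1e-15).all()
        assert t_add.frame.loc[biggest, "p_value"] >= 1 / 201

    def test_exceedance_proportion_halfway(self):
        summ = mr.NullSummary(
            term_ids=("T",), exceedance=np.array([500_000]),
            mean=np.zeros(1), m2=np.zeros(1), n_iterations=1_000_000,
            list_size=5, seed=0, statistic_kind="union_count",
        )
        assert summ.p_values("plain")[0] == 0.5

    def test_sampling_matches_exact_enumeration(self, small_random_toy):
        preds, ann = small_random_toy
        lst = mr.MiRNAList(names=preds.mirna_ids[:3])
        exact = mr.exact_enumeration_enrichment(preds, ann, lst)  # C(8,3) = 56
        sampled = mr.empirical_enrichment(preds, ann, lst, n_iterations=20000, seed=6)
        pe = exact.frame.set_index("term_id")["p_value"]
        ps = sampled.frame.set_index("term_id")["p_value"]
        for t in pe.index:
            se = np.sqrt(max(pe[t] * (1 - pe[t]), 1e-12) / 20000)
            assert abs(ps[t] - pe[t]) <= 3 * se + 1e-9

    def test_monotone_in_observed_statistic(self, small_random_toy):
        """Larger observed statistic → smaller-or-equal p against any fixed null."""
        preds, ann = small_random_toy
        eng = NullEngine(preds, ann, "union_count")
        term = eng.term_ids[0]
        base = {t: 0.0 for t in eng.term_ids}
        p_prev = 1.1
        for obs_val in (0.0, 1.0, 3.0, 8.0):
            obs = dict(base, **{term: obs_val})
            summ = mr.sample_null(preds, ann, 3, obs, 4000, seed=2,
                                  statistic_kind="union_count", engine=eng)
            p = summ.p_values()[summ.term_ids.index(term)]
            assert p <= p_prev + 1e-15
            p_prev = p


class TestExactEnumeration:
    def test_full_list_gives_p_zero_or_one(self, toy_preds, toy_ann):
        lst = mr.MiRNAList(names=toy_preds.mirna_ids)
        table = mr.exact_enumeration_enrichment(toy_preds, toy_ann, lst)
        assert set(table.frame["p_value"]) <= {0.0, 1.0}
        # observed == only subset's statistic, inclusive comparison → p = 1
        assert (table.frame["p_value"] == 1.0).all()

    def test_constant_statistic_across_subsets_gives_p_one(self):
        preds = mr.TargetPredictionSet({("a", "g1"): 1, ("b", "g1"): 1, ("c", "g1"): 1})
        ann = mr.AnnotationSet({"T": {"g1"}})
        lst = mr.MiRNAList(names=("a", "b"))
        table = mr.exact_enumeration_enrichment(preds, ann, lst, "union_count")
        assert table.frame["p_value"].tolist() == [1.0]

    def test_cap_exceeded_errors(self, small_random_toy):
        preds, ann = small_random_toy
        lst = mr.MiRNAList(names=preds.mirna_ids[:4])
        with pytest.raises(ValueError, match="sample_null"):
            mr.exact_enumeration_enrichment(preds, ann, lst, cap=10)


class TestMultihitReducesToUnion:
    def test_equivalence_under_single_site_disjoint_targeting(self):
        """With every site_count = 1 and no shared targets, gene scores are
        0/1 and total = |union|, so multihit equals union_proportion."""
        preds = mr.TargetPredictionSet(
            {("a", "g1"): 1, ("a", "g2"): 1, ("b", "g3"): 1, ("c", "g4"): 1, ("c", "g5"): 1}
        )
        ann = mr.AnnotationSet(
            {"T1": {"g1", "g3"}, "T2": {"g2", "g4", "g5"}},
            universe={"g1", "g2", "g3", "g4", "g5"},
        )
        lst = mr.MiRNAList(names=("a", "b", "c"))
        mh = mr.observed_statistic(preds, ann, lst, "multihit")
        up = mr.observed_statistic(preds, ann, lst, "union_proportion")
        assert mh == pytest.approx(up)
        # and the whole exact-null tables agree
        t_mh = mr.exact_enumeration_enrichment(preds, ann, lst, "multihit")
        t_up = mr.exact_enumeration_enrichment(preds, ann, lst, "union_proportion")
        assert t_mh.frame["p_value"].tolist() == pytest.approx(t_up.frame["p_value"].tolist())
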
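"""Running-sum ES, permutation NES/p, FDR and the report filters."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mirsea as ms
from mirsea.enrichment import EXHAUSTIVE_LIMIT, _es_from_positions
from mirsea.fixtures import enriched_sets_as_results, functional_sets_as_results


def oracle_es(names, members):
    """Independent plain-Python running-sum walk (the brute-force oracle)."""
    member_set = set(members)
    N = len(names)
    G = sum(1 for n in names if n in member_set)
    total = 0.0
    pos_best, pos_rank = -math.inf, 0
    neg_best, neg_rank = math.inf, 0
    for i, n in enumerate(names, start=1):
        total += 1.0 / G if n in member_set else -1.0 / (N - G)
        if total > pos_best:
            pos_best, pos_rank = total, i
        if total < neg_best:
            neg_best, neg_rank = total, i
    # defined tie rule: the positive peak wins an equal-magnitude tie
    # (tolerance absorbs floating-point accumulation differences)
    if pos_best >= -neg_best - 1e-12:
        return pos_best, pos_rank
    return neg_best, neg_rank


class TestEnrichmentScore:
    def test_all_hits_first_reaches_plus_one(self, toy_ranked):
        score = ms.enrichment_score(toy_ranked, {"m1", "m2"})
        assert score.es == pytest.approx(1.0)
        assert score.peak_rank == 2

    def test_all_hits_last_mirror_case(self, toy_ranked):
        score = ms.enrichment_score(toy_ranked, {"m9", "m10"})
        assert score.es == pytest.approx(-1.0)

    def test_split_membership_peaks_early(self, toy_ranked):
        # walk: +0.5, then 7 x -0.125 down to -0.375, +0.5, -0.125 -> 0
        score = ms.enrichment_score(toy_ranked, {"m1", "m9"})
        assert score.es == pytest.approx(0.5)
        assert score.peak_rank == 1

    def test_degenerate_membership_errors(self, toy_ranked):
        with pytest.raises(ValueError, match="undefined"):
            ms.enrichment_score(toy_ranked, set())
        with pytest.raises(ValueError, match="undefined"):
            ms.enrichment_score(toy_ranked, set(toy_ranked.names))

    def test_matches_oracle_on_random_subsets(self):
        rng = np.random.default_rng(0)
        for N in (5, 9, 12, 30):
            names = [f"x{i}" for i in range(N)]
            ranked = ms.RankedList(names=names, scores=np.arange(N, 0, -1.0))
            for _ in range(60):
                G = int(rng.integers(1, N))
                members = set(rng.choice(names, size=G, replace=False))
                score = ms.enrichment_score(ranked, members)
                es_ref, peak_ref = oracle_es(names, members)
                assert score.es == pytest.approx(es_ref, abs=1e-12)
                assert score.peak_rank == peak_ref

    def test_closed_form_batch_matches_cumsum_walk(self):
        rng = np.random.default_rng(3)
        N = 40
        names = [f"x{i}" for i in range(N)]
        ranked = ms.RankedList(names=names, scores=np.arange(N, 0, -1.0))
        for G in (1, 2, 5, 13):
            pos = np.sort(rng.choice(np.arange(1, N + 1), size=(50, G), replace=True), axis=1)
            pos = pos[np.array([len(set(r)) == G for r in pos])]
            batch = _es_from_positions(pos, N)
            for row, es_b in zip(pos, batch):
                members = {names[p - 1] for p in row}
                assert ms.enrichment_score(ranked, members).es == pytest.approx(es_b, abs=1e-12)

    @given(
        n=st.integers(min_value=4, max_value=40),
        data=st.data(),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_bounds_and_terminal_zero(self, n, data):
        """|ES| <= 1 always and the running sum telescopes back to zero."""
        g = data.draw(st.integers(min_value=1, max_value=n - 1))
        names = [f"x{i}" for i in range(n)]
        idx = data.draw(st.permutations(range(n)))
        members = {names[i] for i in idx[:g]}
        ranked = ms.RankedList(names=names, scores=np.arange(n, 0, -1.0))
        score = ms.enrichment_score(ranked, members)
        assert -1.0 <= score.es <= 1.0
        assert score.running_sum.size == n
        assert abs(score.running_sum[-1]) < 1e-9


class TestPermutationNull:
    def test_fixed_seed_identical_sample(self, toy_ranked):
        a = ms.permutation_null(toy_ranked, 3, B=200, seed=5, exhaustive="never")
        b = ms.permutation_null(toy_ranked, 3, B=200, seed=5, exhaustive="never")
        np.testing.assert_array_equal(a, b)

    def test_exhaustive_enumerates_all_subsets(self):
        names = ["a", "b", "c", "d"]
        ranked = ms.RankedList(names=names, scores=np.arange(4, 0, -1.0))
        null = ms.permutation_null(ranked, 2, exhaustive="always")
        expected = sorted(
            oracle_es(names, set(combo))[0] for combo in itertools.combinations(names, 2)
        )
        np.testing.assert_allclose(sorted(null), expected, atol=1e-12)

    def test_monte_carlo_approximates_exhaustive_distribution(self):
        names = [f"x{i}" for i in range(4)]
        ranked = ms.RankedList(names=names, scores=np.arange(4, 0, -1.0))
        exact = ms.permutation_null(ranked, 2, exhaustive="always")
        mc = ms.permutation_null(ranked, 2, B=20000, seed=0, exhaustive="never")
        # each of the 6 subsets should appear with frequency ~1/6
        vals, counts = np.unique(np.round(mc, 9), axis=0, return_counts=True)
        assert set(np.round(vals, 9)) <= set(np.round(exact, 9))
        assert np.mean(mc) == pytest.approx(np.mean(exact), abs=0.02)

    def test_auto_switches_to_exhaustive_below_limit(self, toy_ranked):
        # C(10, 2) = 45 <= limit -> exhaustive regardless of B
        null = ms.permutation_null(toy_ranked, 2, B=7, seed=1)
        assert null.size == math.comb(10, 2) and math.comb(10, 2) <= EXHAUSTIVE_LIMIT

    def test_invalid_G_rejected(self, toy_ranked):
        with pytest.raises(ValueError):
            ms.permutation_null(toy_ranked, 0)
        with pytest.raises(ValueError):
            ms.permutation_null(toy_ranked, 10)


class TestNormalizeAndTest:
    def test_null_equal_to_observed_gives_unit_nes_and_p_one(self):
        nes, p = ms.normalize_and_test(0.4, np.full(50, 0.4))
        assert nes == pytest.approx(1.0)
        assert p == pytest.approx(1.0)
        nes, p = ms.normalize_and_test(-0.4, np.full(50, -0.4))
        assert nes == pytest.approx(-1.0)
        assert p == pytest.approx(1.0)

    def test_add_one_estimator_floor(self):
        # observed above every one of 19 same-sign null values -> p = 1/20
        null = np.linspace(0.01, 0.3, 19)
        _, p = ms.normalize_and_test(0.9, null)
        assert p == pytest.approx(0.05)

    def test_rank_invariance_under_score_scaling(self, toy_ranked):
        doubled = ms.RankedList(names=toy_ranked.names, scores=toy_ranked.scores * 2)
        members = {"m2", "m3", "m7"}
        es1 = ms.enrichment_score(toy_ranked, members)
        es2 = ms.enrichment_score(doubled, members)
        assert es1.es == es2.es and es1.peak_rank == es2.peak_rank
        null1 = ms.permutation_null(toy_ranked, 3, B=99, seed=2)
        null2 = ms.permutation_null(doubled, 3, B=99, seed=2)
        assert ms.normalize_and_test(es1.es, null1) == ms.normalize_and_test(es2.es, null2)

    def test_no_same_sign_null_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="same-sign"):
            nes, p = ms.normalize_and_test(0.5, -np.abs(np.random.default_rng(0).normal(0.3, 0.05, 20)))
        assert nes > 0 and 0 < p <= 1

    def test_sign_of_nes_matches_sign_of_es(self):
        rng = np.random.default_rng(4)
        null = rng.normal(0, 0.2, 500)
        for es in (-0.6, -0.1, 0.1, 0.6):
            nes, p = ms.normalize_and_test(es, null)
            assert np.sign(nes) == np.sign(es)
            assert 0 < p <= 1


class TestComputeFdr:
    @staticmethod
    def _result(name, nes, p, category="function"):
        return ms.EnrichmentResult(
            set_name=name, category=category, es=nes / 3, nes=nes, p_nominal=p,
            fdr_q=math.nan, set_size=3, peak_rank=1, leading_members=(),
        )

    def test_null_never_reaching_observed_gives_zero_q(self):
        res = [self._result("s", 2.5, 0.01)]
        null = {"s": np.abs(np.random.default_rng(0).normal(0.2, 0.05, 200))}
        q = ms.compute_fdr(res, null)
        assert q["s"] == 0.0

    def test_observed_equal_to_null_gives_q_one(self):
        res = [self._result("s", 1.0, 0.5)]
        q = ms.compute_fdr(res, {"s": np.full(100, 0.3)})
        assert q["s"] == pytest.approx(1.0)

    def test_q_monotone_in_p_within_sign_class(self):
        """Brute-force check on 5 sets: after monotone correction, sorting by
        nominal p never decreases q within a sign class."""
        rng = np.random.default_rng(7)
        res = [
            self._result("a", 2.2, 0.002),
            self._result("b", 1.6, 0.03),
            self._result("c", 1.1, 0.3),
            self._result("d", -1.8, 0.01),
            self._result("e", -0.9, 0.5),
        ]
        nulls = {r.set_name: rng.normal(0, 0.4, 400) / np.abs(rng.normal(0, 0.4, 400)).mean() for r in res}
        q = ms.compute_fdr(res, nulls)
        pos = sorted([r for r in res if r.nes > 0], key=lambda r: r.p_nominal)
        neg = sorted([r for r in res if r.nes < 0], key=lambda r: r.p_nominal)
        for group in (pos, neg):
            qs = [q[r.set_name] for r in group]
            assert qs == sorted(qs)
        assert all(0.0 <= v <= 1.0 for v in q.values())


class TestReportFilters:
    def test_significance_filter_on_reference_enriched_sets(self):
        results = enriched_sets_as_results()
        out = ms.apply_report_filters(results, p_cut=0.05, abs_es_cut=0.25)
        assert len(out.significant) == 6

    def test_es_filter_on_reference_functional_sets(self):
        results = functional_sets_as_results()
        out = ms.apply_report_filters(results, p_cut=0.05, abs_es_cut=0.25)
        # |ES| >= 0.25 is inclusive: the Apoptosis set at ES = -0.25 survives
        assert len(out.es_retained) == 4
        assert any(r.set_name == "Apoptosis" for r in out.es_retained)

    def test_zero_p_cut_passes_nothing(self, toy_ranked):
        null = ms.permutation_null(toy_ranked, 2, B=50, seed=1)
        es = ms.enrichment_score(toy_ranked, {"m1", "m2"}).es
        _, p = ms.normalize_and_test(es, null)
        assert p > 0  # the add-one estimator never reaches zero
        res = enriched_sets_as_results()
        assert ms.apply_report_filters(res, p_cut=0.0).significant == []

    def test_retained_union_deduplicates(self):
        results = functional_sets_as_results()
        out = ms.apply_report_filters(results, p_cut=0.05, abs_es_cut=0.25)
        names = [r.set_name for r in out.retained]
        assert len(names) == len(set(names))


@pytest.fixture(scope="module")
def toy_report():
    names = [f"m{i}" for i in range(1, 21)]
    ranked = ms.RankedList(names=names, scores=np.arange(20.0, 0.0, -1.0))
    sets = [
        ms.MiRNASet("top", "function", frozenset(["m1", "m2", "m3"])),
        ms.MiRNASet("bottom", "function", frozenset(["m18", "m19", "m20"])),
        ms.MiRNASet("spread", "function", frozenset(["m2", "m11", "m19"])),
        ms.MiRNASet("reg", "regulator", frozenset(["m1", "m4"])),
    ]
    return ms.enrich_collection(ranked, ms.MiRNASetCollection(sets), B=200, seed=0)


class TestEnrichCollection:
    def test_within_category_order_descending_abs_nes(self, toy_report):
        for group in toy_report.grouped().values():
            mags = [abs(r.nes) for r in group]
            assert mags == sorted(mags, reverse=True)

    def test_extreme_sets_significant(self, toy_report):
        by_name = {r.set_name: r for r in toy_report.results}
        assert by_name["top"].es == pytest.approx(1.0)
        assert by_name["bottom"].es == pytest.approx(-1.0)
        assert by_name["top"].p_nominal <= 0.05
        assert abs(by_name["spread"].nes) < abs(by_name["top"].nes)

    def test_leading_members_side_of_peak(self, toy_report):
        by_name = {r.set_name: r for r in toy_report.results}
        assert set(by_name["top"].leading_members) == {"m1", "m2", "m3"}
        assert set(by_name["bottom"].leading_members) == {"m18", "m19", "m20"}

    def test_plot_tables_cover_every_set(self, toy_report):
        sig = toy_report.significance_table()
        esr = toy_report.es_rank_table()
        assert len(sig) == len(toy_report.results) == len(esr)
        fn = esr[esr["category"] == "function"].sort_values("rank_in_category")
        assert list(fn["es"]) == sorted(fn["es"], reverse=True)
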
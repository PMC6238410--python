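import itertools
import math

import numpy as np
import pandas as pd
import pytest

import prodisc as p
from prodisc import reference
from prodisc.discriminability import ContributionProfile, EnergyResult, GroupPair


def enumeration_overlap_p(ni, size_a, size_b, n_universe):
    """Exhaustive-enumeration oracle: fix a marked set of size_a, enumerate
    all draws of size_b, count those intersecting in >= ni elements."""
    marked = set(range(size_a))
    hits = total = 0
    for draw in itertools.combinations(range(n_universe), size_b):
        total += 1
        hits += len(marked & set(draw)) >= ni
    return hits / total


class TestIntersectCount:
    def test_published_gcr_overlap_is_four(self):
        ni = p.intersect_count(
            reference.GCR24_BRCA_UP2, reference.GCR24_BRCA_UP4,
            reference.GCR24_UCEC_UP2, reference.GCR24_UCEC_UP4,
        )
        assert ni == 4

    def test_published_erbb2_overlap_is_three(self):
        ni = p.intersect_count(
            reference.ERBB2_BRCA_UP, reference.ERBB2_BRCA_DOWN,
            reference.ERBB2_STAD_UP, reference.ERBB2_STAD_DOWN,
        )
        assert ni == 3

    def test_disjoint_sets(self):
        assert p.intersect_count({"a"}, {"b"}, {"c"}, {"d"}) == 0

    def test_directions_never_crossed(self):
        # "x" appears up in one histotype, down in the other: no overlap
        assert p.intersect_count({"x"}, set(), set(), {"x"}) == 0

    def test_overlapping_direction_sets_rejected(self):
        with pytest.raises(ValueError):
            p.intersect_count({"x"}, {"x"}, set(), set())


class TestOverlapPvalue:
    def test_zero_intersection_gives_one(self):
        assert p.overlap_pvalue(0, 5, 5, 120) == 1.0

    def test_tiny_universe_hand_value(self):
        assert p.overlap_pvalue(2, 2, 2, 4) == pytest.approx(1 / 6)

    def test_matches_enumeration_small_universes(self):
        # exhaustive-enumeration equivalence (the full universe <= 12 sweep
        # runs in the acceptance suite)
        for n in range(2, 9):
            for size_a in range(n + 1):
                for size_b in range(n + 1):
                    expected = None
                    for ni in range(min(size_a, size_b) + 1):
                        expected = enumeration_overlap_p(ni, size_a, size_b, n)
                        assert p.overlap_pvalue(ni, size_a, size_b, n) == (
                            pytest.approx(expected)
                        )

    def test_monotone_in_ni(self):
        ps = [p.overlap_pvalue(ni, 6, 7, 120) for ni in range(7)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_inconsistent_sizes_rejected(self):
        with pytest.raises(ValueError):
            p.overlap_pvalue(5, 3, 4, 120)


def _fake_result(histotype, class_a, class_b, up_a, up_b, n_proteins=120,
                 significant=True):
    pair = GroupPair(histotype, class_a, class_b,
                     tuple(f"{histotype}a{i}" for i in range(6)),
                     tuple(f"{histotype}b{i}" for i in range(6)))
    proteins = [f"pr{i}" for i in range(n_proteins)]
    contrib = ContributionProfile(
        contributions=pd.Series(0.0, index=proteins),
        centered=pd.Series(0.0, index=proteins),
        threshold=0.0,
        up_in_a=frozenset(up_a),
        up_in_b=frozenset(up_b),
    )
    return EnergyResult(
        pair=pair, de=-1.0, s_dis=-1.0, p_raw=0.001, s_rand=0.0,
        n_perm=1000, seed=0, p_adj=0.001, significant=significant,
        contributions=contrib,
    )


class TestFindCrossCancerEffects:
    def test_shared_direction_flagged(self):
        shared = {"pr0", "pr1", "pr2", "pr3"}
        results = [
            _fake_result("BRCA", "mut", "wt", shared | {"pr10"}, {"pr20"}),
            _fake_result("STAD", "mut", "wt", shared | {"pr11"}, {"pr21"}),
        ]
        candidates = p.find_cross_cancer_effects(results)
        assert len(candidates) == 1
        c = candidates[0]
        assert c.ni == 4
        assert c.shared_up_1 == shared
        assert c.significant

    def test_opposite_direction_not_flagged(self):
        shared = {"pr0", "pr1", "pr2"}
        results = [
            _fake_result("BRCA", "mut", "wt", shared, {"pr20"}),
            _fake_result("STAD", "mut", "wt", {"pr21"}, shared),
        ]
        candidates = p.find_cross_cancer_effects(results)
        assert candidates[0].ni == 0
        assert not candidates[0].significant

    def test_single_histotype_gives_no_candidate(self):
        results = [_fake_result("BRCA", "mut", "wt", {"pr0"}, {"pr1"})]
        assert p.find_cross_cancer_effects(results) == []

    def test_non_significant_subtests_excluded(self):
        results = [
            _fake_result("BRCA", "mut", "wt", {"pr0"}, {"pr1"}),
            _fake_result("STAD", "mut", "wt", {"pr0"}, {"pr1"}, significant=False),
        ]
        assert p.find_cross_cancer_effects(results) == []

    def test_different_class_pairs_never_paired(self):
        results = [
            _fake_result("BRCA", "mut", "wt", {"pr0"}, {"pr1"}),
            _fake_result("STAD", "c1", "c2", {"pr0"}, {"pr1"}),
        ]
        assert p.find_cross_cancer_effects(results) == []


class TestCes:
    def test_four_of_five_is_eighty_percent(self):
        results = [
            _fake_result(h, "mut", "wt", set(), set(), significant=s)
            for h, s in zip("ABCDE", [True, True, True, True, False])
        ]
        report = p.ces(results)
        assert report.global_ces == pytest.approx(80.0)
        assert report.global_counts == (4, 5)

    def test_zero_significant(self):
        results = [
            _fake_result("A", "mut", "wt", set(), set(), significant=False)
        ]
        assert p.ces(results).global_ces == 0.0

    def test_class_level_arithmetic(self):
        results = [
            _fake_result("A", "c1", "c2", set(), set(), significant=True),
            _fake_result("B", "c1", "c3", set(), set(), significant=False),
            _fake_result("C", "c1", "c4", set(), set(), significant=False),
        ]
        per_class = p.ces(results).per_class.set_index("class")
        assert per_class.loc["c1", "ces"] == pytest.approx(100 / 3)
        assert per_class.loc["c1", "evaluated"] == 3

    def test_percentages_agree_with_backing_counts(self):
        results = [
            _fake_result("A", "c1", "c2", set(), set(), significant=True),
            _fake_result("A", "c1", "c3", set(), set(), significant=False),
        ]
        report = p.ces(results)
        for _, row in report.per_histotype.iterrows():
            assert row["ces"] == pytest.approx(
                100 * row["significant"] / row["evaluated"]
            )


class TestConcordanceFisher:
    def test_published_table_reproduces_p(self):
        table = reference.drug_response_concordance()
        counts, pval = p.concordance_fisher(table)
        np.testing.assert_array_equal(counts, [[11, 2], [6, 7]])
        assert pval == pytest.approx(0.0484, abs=5e-5)

    def test_hand_tail_sum(self):
        # [[11,2],[6,7]]: hypergeometric tail over the fixed margins
        num = (
            math.comb(13, 11) * math.comb(13, 6)
            + math.comb(13, 12) * math.comb(13, 5)
            + math.comb(13, 13) * math.comb(13, 4)
        )
        expected = num / math.comb(26, 17)
        table = reference.drug_response_concordance()
        _, pval = p.concordance_fisher(table)
        assert pval == pytest.approx(expected)

    def test_degenerate_margin_warns_p_one(self):
        table = pd.DataFrame({"response": ["Y", "Y"], "discriminable": ["Y", "Y"]})
        with pytest.warns(UserWarning):
            counts, pval = p.concordance_fisher(table)
        assert pval == 1.0

    def test_two_by_two_diagonal(self):
        table = pd.DataFrame({
            "response": ["Y", "Y", "N", "N"],
            "discriminable": ["Y", "Y", "N", "N"],
        })
        _, pval = p.concordance_fisher(table)
        assert pval == pytest.approx(1 / 6)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            p.concordance_fisher(pd.DataFrame(columns=["response", "discriminable"]))
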
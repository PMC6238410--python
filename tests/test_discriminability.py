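import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import prodisc as p
from prodisc.discriminability import dynamic_threshold

from conftest import make_annotations


def brute_force_de(x_a, x_b):
    """Independent pairwise-loop oracle for the energy-distance sum."""
    x_a, x_b = np.atleast_2d(x_a), np.atleast_2d(x_b)
    total = 0.0
    for k in range(len(x_a)):
        for l in range(k + 1, len(x_a)):
            total += np.sqrt(((x_a[k] - x_a[l]) ** 2).sum())
    for k in range(len(x_b)):
        for l in range(k + 1, len(x_b)):
            total += np.sqrt(((x_b[k] - x_b[l]) ** 2).sum())
    for k in range(len(x_a)):
        for l in range(len(x_b)):
            total -= 2.0 * np.sqrt(((x_a[k] - x_b[l]) ** 2).sum())
    return total


class TestEnergyDistance:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ([[0.0]], [[0.0]], 0.0),  # identical singletons
            ([[0.0], [0.0]], [[1.0], [1.0]], -8.0),
            ([[0.0], [2.0]], [[1.0], [3.0]], -8.0),
        ],
    )
    def test_hand_examples(self, a, b, expected):
        assert p.energy_distance(a, b) == pytest.approx(expected)

    def test_matches_brute_force(self, rng):
        for _ in range(50):
            i, j, d = rng.integers(1, 6, size=3)
            x_a = rng.normal(size=(i, d))
            x_b = rng.normal(size=(j, d))
            assert p.energy_distance(x_a, x_b) == pytest.approx(
                brute_force_de(x_a, x_b)
            )

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            p.energy_distance([[0.0, 1.0]], [[0.0]])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        x_a=arrays(np.float64, (3, 2), elements=st.floats(-5, 5)),
        x_b=arrays(np.float64, (4, 2), elements=st.floats(-5, 5)),
        scale=st.floats(0.1, 10),
    )
    def test_symmetry_and_scaling(self, x_a, x_b, scale):
        de = p.energy_distance(x_a, x_b)
        assert p.energy_distance(x_b, x_a) == pytest.approx(de)
        # homogeneous of degree 1 under global scaling
        assert p.energy_distance(scale * x_a, scale * x_b) == pytest.approx(
            scale * de, abs=1e-9
        )

    def test_within_group_order_invariance(self, rng):
        x_a, x_b = rng.normal(size=(5, 3)), rng.normal(size=(4, 3))
        shuffled = x_a[rng.permutation(5)]
        assert p.energy_distance(shuffled, x_b) == pytest.approx(
            p.energy_distance(x_a, x_b)
        )


class TestMcPvalue:
    def test_singletons_give_p_one(self):
        p_raw, _ = p.mc_pvalue([[0.0]], [[5.0]], n_perm=100, seed=0)
        assert p_raw == 1.0

    def test_matches_exhaustive_enumeration(self, rng):
        # pooled n <= 10: compare MC against full split enumeration
        for seed in range(3):
            x_a = rng.normal(size=(3, 2))
            x_b = rng.normal(loc=1.0, size=(4, 2))
            exact = p.exhaustive_pvalue(x_a, x_b)
            n_perm = 4000
            mc, _ = p.mc_pvalue(x_a, x_b, n_perm=n_perm, seed=seed)
            se = np.sqrt(exact * (1 - exact) / n_perm)
            assert abs(mc - exact) <= 3 * se + 1e-12

    def test_deterministic_under_seed(self, rng):
        x_a, x_b = rng.normal(size=(6, 3)), rng.normal(size=(5, 3))
        r1 = p.mc_pvalue(x_a, x_b, n_perm=500, seed=42)
        r2 = p.mc_pvalue(x_a, x_b, n_perm=500, seed=42)
        assert r1 == r2

    def test_rejects_bad_n_perm(self):
        with pytest.raises(ValueError):
            p.mc_pvalue([[0.0]], [[1.0]], n_perm=0)

    def test_pseudocount_estimator(self, rng):
        x_a = rng.normal(size=(4, 2)) + 50  # far-separated groups
        x_b = rng.normal(size=(4, 2)) - 50
        p_raw, _ = p.mc_pvalue(x_a, x_b, n_perm=100, seed=0, pseudocount=True)
        assert p_raw == pytest.approx(1 / 101)


class TestEnumerateSubtests:
    def _setup(self, sizes_by_histotype):
        cases, hists, labels = [], [], {}
        for h, sizes in sizes_by_histotype.items():
            for cls, size in enumerate(sizes):
                for i in range(size):
                    cid = f"{h}-{cls}-{i}"
                    cases.append(cid)
                    hists.append(h)
                    labels[cid] = str(cls)
        ann = make_annotations(hists, case_ids=cases)
        return p.ClassAssignment("t", pd.Series(labels)), ann

    def test_min_group_rule(self):
        assignment, ann = self._setup({"BRCA": [6, 5, 3]})
        pairs = p.enumerate_subtests(assignment, ann, min_group=5)
        assert len(pairs) == 1
        assert pairs[0].sizes == (6, 5)

    def test_four_classes_give_six_pairs(self):
        assignment, ann = self._setup({"BRCA": [7, 7, 7, 7]})
        assert len(p.enumerate_subtests(assignment, ann)) == 6

    def test_binary_classification_one_pair_per_histotype(self):
        assignment, ann = self._setup({"BRCA": [6, 6], "STAD": [9, 5]})
        pairs = p.enumerate_subtests(assignment, ann)
        assert [pr.histotype for pr in pairs] == ["BRCA", "STAD"]


class TestAdjustBh:
    def test_single_p_unchanged(self):
        adj, sig = p.adjust_bh([0.03])
        assert adj[0] == pytest.approx(0.03)
        assert sig[0]

    def test_all_significant_case(self):
        adj, sig = p.adjust_bh([0.01, 0.02, 0.03, 0.04], alpha=0.05)
        assert sig.all()

    def test_none_significant_case(self):
        _, sig = p.adjust_bh([0.04, 0.5, 0.9], alpha=0.05)
        assert not sig.any()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_order_invariance_and_monotonicity(self, ps):
        adj, _ = p.adjust_bh(ps)
        order = np.argsort(ps)
        adj_sorted, _ = p.adjust_bh(np.asarray(ps)[order])
        np.testing.assert_allclose(np.asarray(adj)[order], adj_sorted)
        # p_adj monotone in p_raw
        assert (np.diff(adj_sorted) >= -1e-12).all()
        assert (adj >= np.asarray(ps) - 1e-12).all()


class TestProteinContributions:
    def test_constant_protein_never_characteristic(self, rng):
        x_a = np.column_stack([np.ones(4), rng.normal(size=4)])
        x_b = np.column_stack([np.ones(5), rng.normal(loc=3, size=5)])
        prof = p.protein_contributions(x_a, x_b, ["const", "shifted"])
        assert prof.contributions["const"] == 0.0
        assert "const" not in prof.up_in_a | prof.up_in_b

    def test_dynamic_threshold_rule(self):
        tau, mask = dynamic_threshold(np.array([-5.0, -2.0, 1.0, -0.5]))
        assert tau == 1.0
        np.testing.assert_array_equal(mask, [True, True, False, False])

    def test_threshold_zero_when_no_positive(self):
        tau, mask = dynamic_threshold(np.array([-5.0, -0.1]))
        assert tau == 0.0
        assert mask.all()

    def test_hand_example_direction(self):
        # protein 0: A all 0, B all 1 (i = j = 2) -> raw c = -8, up in B
        x_a = np.array([[0.0, 0.5], [0.0, 0.5]])
        x_b = np.array([[1.0, 0.5], [1.0, 0.5]])
        prof = p.protein_contributions(x_a, x_b, ["k", "const"])
        assert prof.contributions["k"] == pytest.approx(-8.0)
        assert prof.up_in_b == {"k"}
        assert prof.up_in_a == frozenset()

    def test_centering_matches_permutation_mean(self, rng):
        # centered contribution has (near-)zero mean over random re-splits
        x_a, x_b = rng.normal(size=(6, 1)), rng.normal(size=(5, 1))
        pooled = np.vstack([x_a, x_b])
        raw = p.protein_contributions(x_a, x_b, ["k"], center="none")
        centered = p.protein_contributions(x_a, x_b, ["k"])
        perms = []
        for combo in itertools.combinations(range(11), 6):
            sel = np.zeros(11, dtype=bool)
            sel[list(combo)] = True
            perms.append(
                p.protein_contributions(
                    pooled[sel], pooled[~sel], ["k"], center="none"
                ).contributions["k"]
            )
        expected_mean = np.mean(perms)
        assert (
            centered.centered["k"]
            == pytest.approx(raw.contributions["k"] - expected_mean)
        )


class TestRunSubtests:
    def test_planted_effect_detected_and_recovered(self, planted_cohort):
        cfg, (matrix, mut, cna, ann, truth) = planted_cohort
        assignment = p.actionable_classify(
            mut, cna, p.VariantFilter("KRAS", "any-nonsilent")
        )
        results = p.run_subtests(matrix, assignment, ann, n_perm=2000, seed=3)
        by_hist = {r.pair.histotype: r for r in results}
        for hist in ("BRCA", "STAD"):
            r = by_hist[hist]
            assert r.significant
            up_t, down_t = truth.characteristic_sets("KRAS", hist)
            # class_a = "mutated" (alphabetical), so up_in_a is up-in-mutated
            assert up_t <= r.contributions.up_in_a
            assert down_t <= r.contributions.up_in_b

    def test_results_reproducible(self, planted_cohort):
        cfg, (matrix, mut, cna, ann, _) = planted_cohort
        assignment = p.actionable_classify(
            mut, cna, p.VariantFilter("KRAS", "any-nonsilent")
        )
        r1 = p.run_subtests(matrix, assignment, ann, n_perm=500, seed=9)
        r2 = p.run_subtests(matrix, assignment, ann, n_perm=500, seed=9)
        assert [(a.de, a.p_raw, a.p_adj) for a in r1] == [
            (a.de, a.p_raw, a.p_adj) for a in r2
        ]
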
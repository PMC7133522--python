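"""Widespread-OTU merging, context dependence, and exact group tests."""
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from helpers import binom_two_tailed_oracle

from phyloresponse import (
    ResponseSet,
    TaxonomyTable,
    ValidationError,
    consistency_matrix,
    context_dependence,
    exact_two_tailed_p,
    group_consistency_test,
    merged_tree,
    plant_conserved_responses,
    simulate_tree,
    widespread_otus,
)
from phyloresponse.datatypes import ConsenTraitResult, GroupTest


def make_responses(values_by_location: dict) -> list[ResponseSet]:
    return [
        ResponseSet(pd.Series(vals), location=loc)
        for loc, vals in values_by_location.items()
    ]


class TestWidespreadOtus:
    def test_retention_by_presence_count(self):
        responses = make_responses({
            "l1": {"a": 1.0, "b": 1.0},
            "l2": {"a": -0.5, "b": 2.0},
            "l3": {"a": 0.5, "c": 1.0},
            "l4": {"c": 1.0},
        })
        merged = widespread_otus(responses, min_locations=3)
        assert merged.otu_ids == ["a"]  # b in 2, c in 2
        assert merged.log2fc["a"] == pytest.approx((1.0 - 0.5 + 0.5) / 3)
        assert merged.direction["a"] == "+"
        assert merged.location == "merged"

    def test_mean_ignores_absent_locations(self):
        responses = make_responses({
            "l1": {"a": 3.0}, "l2": {"a": 3.0}, "l3": {"a": 3.0},
            "l4": {"z": -1.0},
        })
        merged = widespread_otus(responses)
        assert merged.log2fc["a"] == pytest.approx(3.0)

    def test_invariant_to_location_order(self):
        responses = make_responses({
            "l1": {"a": 1.0, "b": -1.0},
            "l2": {"a": 2.0, "b": -2.0},
            "l3": {"a": 3.0, "b": 1.0},
        })
        fwd = widespread_otus(responses)
        rev = widespread_otus(responses[::-1])
        pd.testing.assert_series_equal(fwd.log2fc.sort_index(),
                                       rev.log2fc.sort_index())

    def test_no_widespread_warns(self):
        responses = make_responses({
            "l1": {"a": 1.0}, "l2": {"b": 1.0}, "l3": {"c": 1.0},
        })
        with pytest.warns(UserWarning, match="widespread"):
            merged = widespread_otus(responses)
        assert merged.otu_ids == []


def fake_result(tau_pos, tau_neg):
    return ConsenTraitResult(clades=[], tau_pos=tau_pos, tau_neg=tau_neg)


class TestContextDependence:
    def test_printed_delta_case(self):
        per_loc = [fake_result(0.020, 0.020), fake_result(0.020, 0.020)]
        merged = fake_result(0.019, 0.019)
        cd = context_dependence(per_loc, merged)
        assert cd.delta == pytest.approx(0.001)

    def test_zero_delta_when_equal(self):
        per_loc = [fake_result(0.02, 0.02)]
        assert context_dependence(per_loc, fake_result(0.02, 0.02)).delta == 0

    def test_undefined_tau_rejected_with_location(self):
        per_loc = [fake_result(0.02, 0.02), fake_result(None, 0.02)]
        with pytest.raises(ValidationError, match="index 1"):
            context_dependence(per_loc, fake_result(0.02, 0.02))


class TestExactTwoTailed:
    @pytest.mark.parametrize(
        "n_pos,n_neg,expected",
        [(9, 1, 0.021484375), (5, 5, 1.0), (3, 0, 0.25), (0, 3, 0.25)],
    )
    def test_worked_cases(self, n_pos, n_neg, expected):
        assert exact_two_tailed_p(n_pos, n_neg) == pytest.approx(expected)

    def test_matches_enumeration_oracle_all_small_n(self):
        for n in range(1, 13):
            for k in range(n + 1):
                got = exact_two_tailed_p(k, n - k)
                want = float(binom_two_tailed_oracle(k, n - k))
                assert got == pytest.approx(want, abs=1e-12), (n, k)

    def test_symmetric_null_agrees_with_scipy_binomtest(self):
        from scipy.stats import binomtest

        # at p=0.5 the doubled-min-tail and pmf-summation two-sided
        # definitions coincide (up to the cap at 1)
        for n, k in [(10, 9), (12, 3), (8, 4), (11, 0)]:
            ours = exact_two_tailed_p(k, n - k)
            theirs = binomtest(k, n, 0.5, alternative="two-sided").pvalue
            assert ours == pytest.approx(min(1.0, theirs), abs=1e-12)


def taxonomy_for(otu_groups: dict) -> TaxonomyTable:
    rows = {}
    for otu, genus in otu_groups.items():
        rows[otu] = {
            "phylum": "P", "class": "C", "order": "O",
            "family": "F", "genus": genus,
        }
    return TaxonomyTable(pd.DataFrame.from_dict(rows, orient="index"))


class TestGroupConsistency:
    def test_nine_one_group_called_positive(self):
        vals = {f"o{i}": 1.0 for i in range(9)}
        vals["o9"] = -1.0
        resp = ResponseSet(pd.Series(vals))
        tax = taxonomy_for({o: "G1" for o in vals})
        (test,) = group_consistency_test(resp, tax, "genus")
        assert (test.n_pos, test.n_neg) == (9, 1)
        assert test.p_value == pytest.approx(0.021484375)
        assert test.direction_call == "+"

    def test_balanced_group_not_called(self):
        vals = {f"o{i}": (1.0 if i < 5 else -1.0) for i in range(10)}
        resp = ResponseSet(pd.Series(vals))
        tax = taxonomy_for({o: "G1" for o in vals})
        (test,) = group_consistency_test(resp, tax, "genus")
        assert test.p_value == pytest.approx(1.0)
        assert test.direction_call == "none"

    def test_small_groups_skipped_and_zeros_excluded(self):
        vals = {"a": 1.0, "b": 1.0, "c": 0.0, "d": 1.0, "e": -1.0, "f": 1.0}
        resp = ResponseSet(pd.Series(vals))
        tax = taxonomy_for({o: "G1" for o in vals})
        tests = group_consistency_test(resp, tax, "genus", min_group_size=5)
        assert tests[0].n_pos + tests[0].n_neg == 5 if tests else True
        tests6 = group_consistency_test(resp, tax, "genus", min_group_size=6)
        assert tests6 == []

    def test_missing_taxonomy_named(self):
        resp = ResponseSet(pd.Series({"a": 1.0, "zz": -1.0}))
        tax = taxonomy_for({"a": "G1"})
        with pytest.raises(ValidationError, match="zz"):
            group_consistency_test(resp, tax, "genus")

    def test_type_one_error_rate_controlled(self):
        """i.i.d. signs: groups of 20 called at alpha=0.05 in <= 9% of cases."""
        rng = np.random.default_rng(55)
        n_groups, size = 200, 20
        called = 0
        for g in range(n_groups):
            signs = rng.choice([1.0, -1.0], size=size)
            resp = ResponseSet(pd.Series(
                signs, index=[f"o{g}_{i}" for i in range(size)]
            ))
            tax = taxonomy_for({o: "G" for o in resp.otu_ids})
            (test,) = group_consistency_test(resp, tax, "genus")
            called += test.direction_call != "none"
        assert called / n_groups <= 0.09


class TestConsistencyMatrix:
    @staticmethod
    def gt(rank, name, n_pos, n_neg, p, call):
        return GroupTest(rank, name, n_pos, n_neg, p, call)

    def test_opposing_directions_counted(self):
        tests = {
            "warming": [self.gt("phylum", "P1", 9, 1, 0.02, "+")],
            "drought": [self.gt("phylum", "P1", 1, 9, 0.02, "-")],
        }
        matrix, summary = consistency_matrix(tests)
        assert summary["opposing_directions"] == 1
        assert summary["exactly_two"] == 1

    def test_never_significant_groups_excluded(self):
        tests = {
            "warming": [self.gt("phylum", "P1", 9, 1, 0.02, "+"),
                        self.gt("phylum", "P2", 5, 5, 1.0, "none")],
            "drought": [self.gt("phylum", "P2", 6, 4, 0.75, "none")],
        }
        matrix, summary = consistency_matrix(tests)
        assert list(matrix.index) == ["phylum:P1"]
        assert summary["exactly_one"] == 1

    def test_summary_buckets_are_conserved(self):
        rng = np.random.default_rng(2)
        perts = ["w", "d", "c"]
        tests = {p: [] for p in perts}
        for i in range(30):
            for p in perts:
                sig = rng.random() < 0.4
                call = rng.choice(["+", "-"]) if sig else "none"
                tests[p].append(self.gt("genus", f"G{i}", 8, 2,
                                        0.02 if sig else 0.9, call))
        matrix, summary = consistency_matrix(tests)
        assert (
            summary["exactly_one"] + summary["exactly_two"]
            + summary["more_than_two"]
        ) == summary["n_groups_called"] == len(matrix)

    def test_disjoint_planted_responders_stay_specific(self):
        """Disjoint responder clades per perturbation: calls are specific."""
        tree = simulate_tree(96, seed=40)
        tips = tree.tip_labels
        tax = taxonomy_for({t: f"G{i // 12}" for i, t in enumerate(tips)})
        tests = {}
        for p, block in [("w", 0), ("d", 1)]:
            vals = {}
            for i, t in enumerate(tips):
                group = i // 12
                if group % 2 == block % 2:
                    vals[t] = 1.0  # coherent responders for this perturbation
                else:
                    vals[t] = 1.0 if i % 2 == 0 else -1.0  # balanced noise
            tests[p] = group_consistency_test(
                ResponseSet(pd.Series(vals)), tax, "genus")
        matrix, summary = consistency_matrix(tests)
        called_pairs = int((matrix != "").to_numpy().sum())
        assert called_pairs > 0
        one_pert = (matrix != "").sum(axis=1) == 1
        assert one_pert.mean() >= 0.9


class TestMergedTree:
    def test_prune_keeps_only_widespread_tips(self):
        tree = simulate_tree(32, seed=3)
        keep = tree.tip_labels[:10]
        pruned = merged_tree(tree, keep, mode="prune")
        assert sorted(pruned.tip_labels) == sorted(keep)

    def test_rebuild_preserves_patristic_distances(self):
        from phyloresponse import patristic_distance

        tree = simulate_tree(16, seed=4)
        keep = tree.tip_labels[:8]
        rebuilt = merged_tree(tree, keep, mode="rebuild")
        pruned = merged_tree(tree, keep, mode="prune")
        for a in keep[:3]:
            for b in keep[-3:]:
                if a != b:
                    assert patristic_distance(rebuilt, a, b) == pytest.approx(
                        patristic_distance(pruned, a, b), abs=1e-9
                    )
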
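"""Neighbour joining, consensus clades, tau_D, and the permutation test."""
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from helpers import consensus_clades_oracle, random_additive_matrix

from phyloresponse import (
    DistanceMatrix,
    ResponseSet,
    ValidationError,
    find_consensus_clades,
    nj_tree,
    parse_newick,
    patristic_distance,
    permutation_test,
    plant_conserved_responses,
    simulate_tree,
    tau_d,
)
from phyloresponse.trees import trees_isomorphic


class TestNeighbourJoining:
    def test_exact_on_additive_quartet(self):
        # AB|CD, pendant lengths (1,2,3,4), internal edge 1
        M = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        tree = nj_tree(DistanceMatrix(list("ABCD"), M))
        for a, b in [("A", "B"), ("C", "D"), ("A", "C"), ("A", "D"),
                     ("B", "C"), ("B", "D")]:
            i, j = "ABCD".index(a), "ABCD".index(b)
            assert patristic_distance(tree, a, b) == pytest.approx(M[i, j])

    def test_three_taxon_cherry(self):
        M = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        tree = nj_tree(DistanceMatrix(list("ABC"), M))
        assert patristic_distance(tree, "A", "B") == pytest.approx(2.0)

    def test_additivity_oracle_random_trees(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            dist, _src = random_additive_matrix(12, rng)
            tree = nj_tree(dist)
            for a in dist.labels[:4]:
                for b in dist.labels[-4:]:
                    if a == b:
                        continue
                    i, j = dist.labels.index(a), dist.labels.index(b)
                    assert patristic_distance(tree, a, b) == pytest.approx(
                        dist.values[i, j], abs=1e-9
                    )

    def test_matches_skbio_topology_on_additive_matrix(self):
        from io import StringIO

        import skbio
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(33)
        dist, _ = random_additive_matrix(10, rng)
        ours = nj_tree(dist, root=None)
        theirs_tree = skbio_nj(skbio.DistanceMatrix(dist.values, dist.labels))
        theirs = parse_newick(str(theirs_tree))
        for a in dist.labels[:3]:
            for b in dist.labels[-3:]:
                assert patristic_distance(ours, a, b) == pytest.approx(
                    patristic_distance(theirs, a, b), abs=1e-6
                )

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValidationError):
            nj_tree(DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0.0]])))


def response_from_signs(tip_labels, signs):
    vals = {t: {"+": 1.0, "-": -1.0, "0": 0.0}[s]
            for t, s in zip(tip_labels, signs)}
    return ResponseSet(pd.Series(vals))


class TestFindConsensusClades:
    def test_perfect_split_two_clades(self, balanced_quartet):
        resp = response_from_signs("ABCD", "++--")
        clades = find_consensus_clades(balanced_quartet, resp)
        assert len(clades) == 2
        by_dir = {c.direction: c for c in clades}
        assert by_dir["+"].genetic_depth == pytest.approx(0.1)
        assert by_dir["-"].genetic_depth == pytest.approx(0.1)
        assert tau_d(clades, "+") == pytest.approx(0.1)
        assert tau_d(clades, "-") == pytest.approx(0.1)

    def test_all_positive_single_root_clade(self, balanced_quartet):
        resp = response_from_signs("ABCD", "++++")
        clades = find_consensus_clades(balanced_quartet, resp)
        assert len(clades) == 1
        assert clades[0].n_tips == 4

    @staticmethod
    def ten_tip_tree():
        inner = ",".join(f"t{i}:0.05" for i in range(10))
        # star-like 10-tip clade plus an outgroup to keep the node internal
        return parse_newick(f"(({inner}):0.05,out:0.3);")

    def test_nine_of_ten_is_not_consensus(self):
        tree = self.ten_tip_tree()
        signs = {f"t{i}": "+" for i in range(9)}
        signs["t9"] = "-"
        signs["out"] = "0"
        resp = ResponseSet(pd.Series(
            {k: {"+": 1.0, "-": -1.0, "0": 0.0}[v] for k, v in signs.items()}
        ))
        clades = find_consensus_clades(tree, resp, threshold=0.90)
        # strict rule: 9/10 = 90% is NOT > 90% -> all tips come back alone
        assert all(c.is_singleton for c in clades)
        assert len(clades) == 10

    def test_nineteen_of_twenty_is_consensus(self):
        inner = ",".join(f"t{i}:0.05" for i in range(20))
        tree = parse_newick(f"(({inner}):0.05,(o1:0.1,o2:0.1):0.2);")
        vals = {f"t{i}": 1.0 for i in range(19)}
        vals["t19"] = -1.0
        vals["o1"] = vals["o2"] = -1.0
        clades = find_consensus_clades(tree, ResponseSet(pd.Series(vals)),
                                       threshold=0.90)
        # root is 19/22 (86%): descends; the 20-tip node is 19/20 = 95% > 90%
        pos = [c for c in clades if c.direction == "+"]
        assert len(pos) == 1 and pos[0].n_tips == 20 and not pos[0].is_singleton

    def test_zero_direction_tips_excluded_everywhere(self, balanced_quartet):
        resp = response_from_signs("ABCD", "+0-0")
        clades = find_consensus_clades(balanced_quartet, resp)
        members = {c.node for c in clades}
        assert all(c.is_singleton for c in clades)
        assert members == {"A", "C"}

    def test_missing_tip_named_in_error(self, balanced_quartet):
        resp = ResponseSet(pd.Series({"A": 1.0, "B": 1.0, "C": -1.0}))
        with pytest.raises(ValidationError, match="'D'"):
            find_consensus_clades(balanced_quartet, resp)

    def test_matches_bruteforce_oracle_random_trees(self):
        rng = np.random.default_rng(100)
        for rep in range(60):
            n = int(rng.integers(4, 65))
            tree = simulate_tree(n, seed=int(rng.integers(2**31)))
            signs = rng.choice(["+", "-", "0"], size=n, p=[0.45, 0.45, 0.1])
            resp = response_from_signs(tree.tip_labels, signs)
            clades = find_consensus_clades(tree, resp, threshold=0.90)
            got = set()
            index = tree.index()
            for c in clades:
                i = index.node_labels.index(c.node)
                tips = frozenset(
                    index.tip_labels[t]
                    for t in range(index.tip_start[i], index.tip_end[i])
                )
                got.add((tips, c.direction, c.is_singleton))
            want = consensus_clades_oracle(
                tree, dict(zip(tree.tip_labels, signs)), Fraction(9, 10)
            )
            assert got == want, f"mismatch at rep {rep} (n={n})"

    def test_partition_property(self):
        # every nonzero-direction tip in exactly one clade; zeros in none
        rng = np.random.default_rng(5)
        tree = simulate_tree(40, seed=17)
        signs = rng.choice(["+", "-", "0"], size=40)
        resp = response_from_signs(tree.tip_labels, signs)
        clades = find_consensus_clades(tree, resp)
        index = tree.index()
        seen: list[str] = []
        for c in clades:
            i = index.node_labels.index(c.node)
            seen.extend(index.tip_labels[t]
                        for t in range(index.tip_start[i], index.tip_end[i]))
        trait_tips = {t for t, s in zip(tree.tip_labels, signs) if s != "0"}
        covered = [t for t in seen if t in trait_tips]
        assert len(covered) == len(set(covered))
        assert set(covered) == trait_tips
        zero_tips = {t for t, s in zip(tree.tip_labels, signs) if s == "0"}
        singleton_nodes = {c.node for c in clades if c.is_singleton}
        assert not (zero_tips & singleton_nodes)

    def test_raising_threshold_never_grows_clades(self):
        rng = np.random.default_rng(8)
        for seed in range(5):
            tree = simulate_tree(32, seed=seed)
            signs = rng.choice(["+", "-"], size=32)
            resp = response_from_signs(tree.tip_labels, signs)
            at_90 = find_consensus_clades(tree, resp, threshold=0.90)
            at_100 = find_consensus_clades(tree, resp, threshold=1.0)
            assert max(c.n_tips for c in at_100) <= max(c.n_tips for c in at_90)
            for d in "+-":
                t90, t100 = tau_d(at_90, d), tau_d(at_100, d)
                if t90 is not None and t100 is not None:
                    assert t100 <= t90 + 1e-12

    def test_tau_never_exceeds_root_depth(self):
        rng = np.random.default_rng(9)
        tree = simulate_tree(48, seed=3)
        root_depth = tree.index().root_depth
        for _ in range(10):
            signs = rng.choice(["+", "-"], size=48)
            clades = find_consensus_clades(
                tree, response_from_signs(tree.tip_labels, signs))
            for d in "+-":
                t = tau_d(clades, d)
                if t is not None:
                    assert t <= root_depth + 1e-12


class TestTauD:
    def test_mean_of_depths(self):
        from phyloresponse.datatypes import ConsensusClade

        clades = [
            ConsensusClade("n1", "+", 0.1, 3, False),
            ConsensusClade("n2", "+", 0.3, 2, False),
            ConsensusClade("n3", "-", 0.1, 1, True),
        ]
        assert tau_d(clades, "+") == pytest.approx(0.2)
        assert tau_d(clades, "-") == pytest.approx(0.1)
        assert tau_d([c for c in clades if c.direction == "+"], "-") is None


class TestPermutationTest:
    def test_uniform_direction_gives_p_one(self, balanced_quartet):
        resp = response_from_signs("ABCD", "++++")
        res = permutation_test(balanced_quartet, resp, n_randomizations=50,
                               seed=0)
        assert res.p_pos == pytest.approx(1.0)
        assert res.p_neg is None  # no negative tips at all

    def test_planted_signal_detected(self):
        detected = 0
        for seed in range(8):
            tree = simulate_tree(128, seed=seed)
            resp, _ = plant_conserved_responses(tree, 0.05, 1.0, seed=seed)
            res = permutation_test(tree, resp, n_randomizations=200, seed=seed)
            if (res.p_pos is None or res.p_pos <= 0.05) and (
                res.p_neg is None or res.p_neg <= 0.05
            ):
                detected += 1
        assert detected >= 7

    def test_deterministic_under_seed(self, balanced_quartet,
                                      quartet_response):
        a = permutation_test(balanced_quartet, quartet_response,
                             n_randomizations=100, seed=4)
        b = permutation_test(balanced_quartet, quartet_response,
                             n_randomizations=100, seed=4)
        assert a.null_tau_pos == b.null_tau_pos
        assert a.p_pos == b.p_pos

    def test_invariant_under_consistent_relabeling(self):
        tree = simulate_tree(24, seed=6)
        rng = np.random.default_rng(2)
        signs = rng.choice(["+", "-"], size=24)
        resp = response_from_signs(tree.tip_labels, signs)
        res1 = permutation_test(tree, resp, n_randomizations=100, seed=9)

        relabel = {t: f"x_{t}" for t in tree.tip_labels}
        clone = parse_newick(
            __import__("phyloresponse").to_newick(tree)
        )
        for leaf in clone.tree.leaf_node_iter():
            leaf.label = relabel[leaf.label]
            leaf.taxon.label = leaf.label
        clone = parse_newick(
            clone.tree.as_string(schema="newick", suppress_rooting=True)
        )
        resp2 = ResponseSet(pd.Series(
            {relabel[t]: v for t, v in resp.log2fc.items()}
        ))
        res2 = permutation_test(clone, resp2, n_randomizations=100, seed=9)
        assert res1.tau_pos == pytest.approx(res2.tau_pos)
        assert res1.p_pos == res2.p_pos and res1.p_neg == res2.p_neg

    def test_single_direction_tip_flagged_undefined(self, balanced_quartet):
        resp = response_from_signs("ABCD", "+++-")
        res = permutation_test(balanced_quartet, resp, n_randomizations=20,
                               seed=1)
        assert res.p_neg is None  # only one negative tip
        assert res.tau_neg is not None  # but its singleton depth exists
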
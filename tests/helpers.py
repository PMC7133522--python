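"""Independent oracles used by the test suite.

These deliberately avoid the package's optimized code paths: the consensus
oracle enumerates every internal node with exact rational arithmetic, the
PERMANOVA oracle enumerates label permutations from first principles, and
the binomial oracle sums pmf terms directly.
"""
from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


def consensus_clades_oracle(phylo, direction: dict, threshold: Fraction):
    """Brute-force consensus clades + singletons on a rooted dendropy tree.

    Enumerates every node, marks those where strictly more than
    ``threshold`` of the trait-carrying descendant tips (>= 2 of them)
    share one direction, keeps only marked nodes with no marked ancestor,
    then adds uncovered trait tips as singletons. Returns a set of
    (frozenset of tips, direction, is_singleton).
    """
    tree = phylo.tree
    qualifying = {}
    for node in tree.preorder_node_iter():
        tips = [l.label for l in node.leaf_iter()]
        n_pos = sum(1 for t in tips if direction[t] == "+")
        n_neg = sum(1 for t in tips if direction[t] == "-")
        nt = n_pos + n_neg
        if nt >= 2 and Fraction(max(n_pos, n_neg), nt) > threshold:
            qualifying[id(node)] = (node, "+" if n_pos > n_neg else "-")
    kept = []
    for node, d in qualifying.values():
        anc = node.parent_node
        has_marked_ancestor = False
        while anc is not None:
            if id(anc) in qualifying:
                has_marked_ancestor = True
                break
            anc = anc.parent_node
        if not has_marked_ancestor:
            kept.append((node, d))
    covered = set()
    out = set()
    for node, d in kept:
        tips = frozenset(l.label for l in node.leaf_iter())
        covered |= tips
        out.add((tips, d, False))
    for leaf in tree.leaf_node_iter():
        if leaf.label not in covered and direction[leaf.label] != "0":
            out.add((frozenset([leaf.label]), direction[leaf.label], True))
    return out


def permanova_oracle(D: np.ndarray, labels: list):
    """(F_obs, R2, exact p) by full enumeration of label permutations."""

    def stats(lab):
        n = len(lab)
        groups = sorted(set(lab))
        sst = sum(
            D[i, j] ** 2 for i in range(n) for j in range(i + 1, n)
        ) / n
        ssw = 0.0
        for g in groups:
            idx = [i for i, l in enumerate(lab) if l == g]
            ssw += sum(
                D[i, j] ** 2
                for a, i in enumerate(idx)
                for j in idx[a + 1:]
            ) / len(idx)
        ssb = sst - ssw
        a = len(groups)
        f = math.inf if ssw == 0 else (ssb / (a - 1)) / (ssw / (n - a))
        return f, ssb / sst

    f_obs, r2 = stats(labels)
    n = len(labels)
    ge = total = 0
    for perm in itertools.permutations(labels):
        f_p, _ = stats(list(perm))
        total += 1
        if f_p >= f_obs:
            ge += 1
    return f_obs, r2, Fraction(ge, total)


def binom_two_tailed_oracle(n_pos: int, n_neg: int) -> Fraction:
    """Doubled-smaller-tail two-sided binomial p at 0.5, exact rationals."""
    n = n_pos + n_neg
    lower = Fraction(sum(math.comb(n, k) for k in range(0, n_pos + 1)), 2**n)
    upper = Fraction(sum(math.comb(n, k) for k in range(n_pos, n + 1)), 2**n)
    return min(Fraction(1), 2 * min(lower, upper))


def random_direction_response(tip_labels, rng):
    """i.i.d. +/- directions as a ResponseSet (unit magnitudes)."""
    import pandas as pd

    from phyloresponse import ResponseSet

    signs = rng.choice([-1.0, 1.0], size=len(tip_labels))
    return ResponseSet(pd.Series(signs, index=list(tip_labels)))


def random_additive_matrix(n: int, rng):
    """Distance matrix that is exactly additive on a random binary tree."""
    from phyloresponse import DistanceMatrix, simulate_tree

    tree = simulate_tree(n, seed=int(rng.integers(2**31)))
    # perturb edges so the tree is not ultrametric
    for node in tree.tree.preorder_node_iter():
        if node.edge.length:
            node.edge.length *= float(rng.uniform(0.5, 2.0))
    index = tree.index()
    D = index.patristic_matrix()
    return DistanceMatrix(list(index.tip_labels), D), tree
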
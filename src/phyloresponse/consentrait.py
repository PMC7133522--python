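"""consenTRAIT: consensus clades, genetic depth tau_D, and its permutation null.

The statistic asks whether a binary trait — here, the sign of an OTU's
log2 response ratio to a perturbation — is phylogenetically conserved.
The rooted tree is traversed from the root towards the tips, recording the
deepest nodes where strictly more than 90% of the trait-carrying descendant
tips share one response direction ("consensus clades"); traversal does not
descend into a recorded clade. Trait-carrying tips left uncovered become
singleton clades whose depth is half the patristic distance to the nearest
tip. tau_D for a direction is the mean genetic depth of its consensus
clades, singletons included. Significance comes from randomizing the
direction labels among the tips (one joint shuffle preserving the multiset
of +/-/0) and recomputing tau_D; the p-value is the plain fraction of
randomized tau_D values >= the observed one.

Neighbour-joining reconstruction from a distance matrix lives here too,
because the pipeline builds its trees from sequence distances.
"""
from __future__ import annotations

import numpy as np

from .datatypes import (
    ConsensusClade,
    ConsenTraitResult,
    DistanceMatrix,
    ResponseSet,
    ValidationError,
)
from .trees import Phylogeny, TreeIndex, midpoint_root, parse_newick

# ---------------------------------------------------------------------------
# Neighbour joining


def nj_tree(dist: DistanceMatrix, root: str = "midpoint") -> Phylogeny:
    """Classic neighbour joining (Saitou & Nei Q-criterion), midpoint-rooted.

    Negative estimated branch lengths are clamped to zero with the deficit
    moved onto the sister edge, preserving the path length between the two
    joined nodes. NJ is exact on additive matrices, which the tests exploit.
    """
    n = len(dist.labels)
    if n < 3:
        raise ValidationError("neighbour joining needs at least 3 taxa")
    D = dist.values.astype(float).copy()
    # Each active node is represented by a (newick fragment, pendant ok) pair.
    nodes = list(dist.labels)
    frags = {i: _quote(l) for i, l in enumerate(nodes)}
    active = list(range(n))
    Dm = {(i, j): D[i, j] for i in range(n) for j in range(n)}

    next_id = n
    while len(active) > 2:
        r = {i: sum(Dm[(i, j)] for j in active if j != i) for i in active}
        m = len(active)
        best, best_q = None, np.inf
        for ai in range(m):
            for bi in range(ai + 1, m):
                i, j = active[ai], active[bi]
                q = (m - 2) * Dm[(i, j)] - r[i] - r[j]
                if q < best_q - 1e-15:
                    best_q, best = q, (i, j)
        i, j = best
        dij = Dm[(i, j)]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        # Clamp negatives; move the deficit to the sister edge.
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        lj = max(lj, 0.0)
        u = next_id
        next_id += 1
        frags[u] = f"({frags[i]}:{li:.12g},{frags[j]}:{lj:.12g})"
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (Dm[(i, k)] + Dm[(j, k)] - dij)
            Dm[(u, k)] = Dm[(k, u)] = max(duk, 0.0)
        active = [k for k in active if k not in (i, j)] + [u]

    i, j = active
    lij = max(Dm[(i, j)], 0.0)
    newick = f"({frags[i]}:{lij / 2:.12g},{frags[j]}:{lij / 2:.12g});"
    unrooted = parse_newick(newick)
    if root == "midpoint":
        return midpoint_root(unrooted)
    return unrooted


def _quote(label: str) -> str:
    if any(c in label for c in "(),:;[] \t'"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# Consensus clades and tau_D

_DIR_CODE = {"+": 1, "-": -1, "0": 0}


def encode_directions(index: TreeIndex, response: ResponseSet) -> np.ndarray:
    """Direction vector in the tree's preorder tip order (+1/-1/0 per tip)."""
    direction = response.direction
    codes = np.zeros(index.n_tips, dtype=np.int8)
    for pos, label in enumerate(index.tip_labels):
        if label not in direction.index:
            raise ValidationError(f"tip {label!r} has no response direction")
        codes[pos] = _DIR_CODE[direction[label]]
    return codes


def _clades_from_codes(
    index: TreeIndex,
    codes: np.ndarray,
    threshold: float,
    singleton_rule: str = "patristic",
) -> list[ConsensusClade]:
    """Root-to-tip traversal under the strict >threshold consensus rule."""
    pos_prefix = np.concatenate([[0], np.cumsum(codes == 1)])
    neg_prefix = np.concatenate([[0], np.cumsum(codes == -1)])
    halves = index.nearest_tip_half_distances()
    if singleton_rule == "pendant":
        pendant = index.edge_length
    elif singleton_rule != "patristic":
        raise ValueError(f"unknown singleton rule {singleton_rule!r}")

    clades: list[ConsensusClade] = []
    stack = [0]
    while stack:
        v = stack.pop()
        s, e = index.tip_start[v], index.tip_end[v]
        n_pos = pos_prefix[e] - pos_prefix[s]
        n_neg = neg_prefix[e] - neg_prefix[s]
        nt = n_pos + n_neg
        if nt >= 2 and max(n_pos, n_neg) > threshold * nt:
            clades.append(
                ConsensusClade(
                    node=index.node_labels[v],
                    direction="+" if n_pos > n_neg else "-",
                    genetic_depth=float(index.clade_depth[v]),
                    n_tips=index.n_desc_tips(v),
                    is_singleton=False,
                )
            )
            continue
        if index.is_tip[v]:
            if codes[s] != 0:
                depth = (
                    float(index.edge_length[v])
                    if singleton_rule == "pendant"
                    else float(halves[s])
                )
                clades.append(
                    ConsensusClade(
                        node=index.node_labels[v],
                        direction="+" if codes[s] > 0 else "-",
                        genetic_depth=depth,
                        n_tips=1,
                        is_singleton=True,
                    )
                )
            continue
        if nt == 0:
            continue  # no trait-carrying tips below: nothing to record
        stack.extend(index.children[v])
    return clades


def find_consensus_clades(
    tree: Phylogeny | TreeIndex,
    response: ResponseSet,
    threshold: float = 0.90,
    singleton_rule: str = "patristic",
) -> list[ConsensusClade]:
    """Consensus clades (>threshold agreement among trait-carrying tips,
    at least two of them) plus singleton clades for uncovered trait tips.

    Tips with direction 0 count in neither the numerator nor the
    denominator of the consensus fraction and never become singletons.
    Returned clades are mutually non-nested and partition the trait tips.
    """
    index = tree if isinstance(tree, TreeIndex) else tree.index()
    codes = encode_directions(index, response)
    return _clades_from_codes(index, codes, threshold, singleton_rule)


def tau_d(clades: list[ConsensusClade], direction: str) -> float | None:
    """Mean genetic depth of the clades (singletons included) of a direction.

    Returns None when no clade carries the direction (flagged undefined).
    """
    depths = [c.genetic_depth for c in clades if c.direction == direction]
    if not depths:
        return None
    return float(np.mean(depths))


def _tau_pair(index, codes, threshold, singleton_rule):
    clades = _clades_from_codes(index, codes, threshold, singleton_rule)
    return tau_d(clades, "+"), tau_d(clades, "-"), clades


def permutation_test(
    tree: Phylogeny | TreeIndex,
    response: ResponseSet,
    n_randomizations: int = 1000,
    seed: int = 0,
    threshold: float = 0.90,
    singleton_rule: str = "patristic",
) -> ConsenTraitResult:
    """Observed tau_D per direction plus its label-randomization null.

    The complete direction vector (zeros included) is shuffled jointly
    ``n_randomizations`` times; p per direction is the plain fraction of
    randomized tau_D values >= the observed tau_D. A direction carried by
    fewer than two tips gets an undefined (None) p-value.
    """
    index = tree if isinstance(tree, TreeIndex) else tree.index()
    codes = encode_directions(index, response)
    obs_pos, obs_neg, clades = _tau_pair(index, codes, threshold, singleton_rule)

    rng = np.random.default_rng(seed)
    null_pos: list[float] = []
    null_neg: list[float] = []
    for _ in range(n_randomizations):
        perm = rng.permutation(codes)
        tp, tn, _ = _tau_pair(index, perm, threshold, singleton_rule)
        null_pos.append(tp if tp is not None else np.nan)
        null_neg.append(tn if tn is not None else np.nan)

    def pvalue(observed, null, n_dir):
        if observed is None or n_dir < 2:
            return None
        arr = np.asarray(null, dtype=float)
        return float(np.mean(arr[~np.isnan(arr)] >= observed))

    n_pos_tips = int(np.sum(codes == 1))
    n_neg_tips = int(np.sum(codes == -1))
    return ConsenTraitResult(
        clades=clades,
        tau_pos=obs_pos,
        tau_neg=obs_neg,
        null_tau_pos=null_pos,
        null_tau_neg=null_neg,
        p_pos=pvalue(obs_pos, null_pos, n_pos_tips),
        p_neg=pvalue(obs_neg, null_neg, n_neg_tips),
        n_randomizations=n_randomizations,
    )
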
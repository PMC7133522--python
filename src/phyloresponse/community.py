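"""Overall community-composition test for one location.

Samples are rarefied to a common depth (one seeded draw without
replacement), pairwise Bray-Curtis dissimilarities are computed, and the
control-vs-treatment difference is tested with one-factor PERMANOVA:
pseudo-F on the dissimilarity matrix with a label-permutation p-value and
R^2 = between-arm share of the total squared dissimilarity.
"""
from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .datatypes import CountTable, DistanceMatrix, PermanovaResult, ValidationError


def rarefy(table: CountTable, depth: int, seed: int = 0) -> CountTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    One seeded draw (multivariate hypergeometric per sample). Errors name
    any sample whose total is below ``depth``.
    """
    totals = table.counts.sum(axis=0)
    too_small = totals[totals < depth]
    if len(too_small):
        raise ValidationError(
            f"rarefaction depth {depth} exceeds total reads of sample(s) "
            f"{list(too_small.index)}"
        )
    rng = np.random.default_rng(seed)
    out = {}
    for sample in table.sample_ids:
        col = table.counts[sample].to_numpy()
        out[sample] = rng.multivariate_hypergeometric(col, depth)
    rare = pd.DataFrame(out, index=table.counts.index)
    return CountTable(rare, table.sample_meta)


def bray_curtis(table: CountTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples.

    d(x, y) = 1 - 2 * sum_i min(x_i, y_i) / (sum x + sum y).
    """
    if len(table.sample_ids) < 2:
        raise ValidationError("Bray-Curtis needs at least 2 samples")
    X = table.counts.to_numpy().T.astype(float)  # samples x OTUs
    zero = np.where(X.sum(axis=1) == 0)[0]
    if len(zero):
        raise ValidationError(
            f"all-zero sample(s): {[table.sample_ids[i] for i in zero]}"
        )
    D = squareform(pdist(X, metric="braycurtis"))
    return DistanceMatrix(table.sample_ids, D)


def _permanova_stats(D2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(pseudo_F, R2) from squared dissimilarities and group labels."""
    n = len(labels)
    groups = np.unique(labels)
    a = len(groups)
    iu = np.triu_indices(n, k=1)
    ss_total = D2[iu].sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.where(labels == g)[0]
        if len(idx) >= 2:
            sub = D2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    if ss_total <= 0:
        raise ValidationError("degenerate input: all dissimilarities zero")
    r2 = ss_between / ss_total
    if ss_within == 0:
        f = math.inf
    else:
        f = (ss_between / (a - 1)) / (ss_within / (n - a))
    return f, r2


def permanova(
    dist: DistanceMatrix,
    arms,
    n_permutations: int = 999,
    seed: int = 0,
    exhaustive: bool = False,
) -> PermanovaResult:
    """One-factor PERMANOVA on a dissimilarity matrix.

    Monte-Carlo p uses the (1 + count) / (1 + N) convention, which includes
    the identity permutation and guarantees p > 0. With ``exhaustive=True``
    (intended for n <= 7) every label permutation is enumerated and p is
    the exact fraction of permutations with F >= the observed F.
    """
    labels = np.asarray(
        arms.loc[dist.labels] if isinstance(arms, pd.Series) else arms
    )
    if len(labels) != len(dist.labels):
        raise ValidationError("arm labels do not match distance matrix")
    counts = pd.Series(labels).value_counts()
    if (counts < 2).any():
        raise ValidationError(
            f"need >= 2 samples per arm; got {counts.to_dict()}"
        )
    D2 = dist.values**2
    f_obs, r2 = _permanova_stats(D2, labels)

    if exhaustive:
        n = len(labels)
        total = math.factorial(n)
        if total > 50_000:
            raise ValidationError("exhaustive mode intended for n <= 7")
        ge = 0
        for perm in itertools.permutations(range(n)):
            f_p, _ = _permanova_stats(D2, labels[list(perm)])
            if f_p >= f_obs:
                ge += 1
        return PermanovaResult(f_obs, r2, ge / total, total)

    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_permutations):
        f_p, _ = _permanova_stats(D2, rng.permutation(labels))
        if f_p >= f_obs:
            ge += 1
    p = (1 + ge) / (1 + n_permutations)
    return PermanovaResult(f_obs, r2, p, n_permutations)
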
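"""Cross-location merging, context dependence, and taxonomic consistency.

OTUs passing the per-location filters in at least three locations
("widespread" OTUs) get their response ratios averaged with equal weight
per location; the merged responses feed a second consenTRAIT run, and the
gap between the mean per-location tau_D and the merged tau_D measures how
context-dependent the responses are. Separately, each taxonomic group at
each rank is screened for a consistent response direction with a
two-tailed exact binomial test of positive vs negative responders against
an even split.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.stats import binom

from .datatypes import (
    RANKS,
    ConsenTraitResult,
    ContextDependence,
    GroupTest,
    ResponseSet,
    TaxonomyTable,
    ValidationError,
)

log = logging.getLogger("phyloresponse")


def widespread_otus(
    responses: list[ResponseSet], min_locations: int = 3
) -> ResponseSet:
    """Equal-weight average response of OTUs present in >= min_locations.

    The mean log2fc is the unweighted arithmetic mean over the locations
    where the OTU is present, treating every location equally regardless
    of its sequencing effort. Returns a ResponseSet labelled "merged".
    """
    if len(responses) < min_locations:
        raise ValidationError(
            f"need >= {min_locations} response sets, got {len(responses)}"
        )
    frame = pd.DataFrame({i: r.log2fc for i, r in enumerate(responses)})
    n_present = frame.notna().sum(axis=1)
    keep = n_present[n_present >= min_locations].index
    if len(keep) == 0:
        warnings.warn("no widespread OTUs", stacklevel=2)
    merged = frame.loc[keep].mean(axis=1, skipna=True)
    return ResponseSet(merged, location="merged")


def n_locations_present(
    responses: list[ResponseSet], otu_ids=None
) -> pd.Series:
    frame = pd.DataFrame({i: r.log2fc for i, r in enumerate(responses)})
    n = frame.notna().sum(axis=1)
    return n.loc[list(otu_ids)] if otu_ids is not None else n


def context_dependence(
    per_location: list[ConsenTraitResult], merged: ConsenTraitResult
) -> ContextDependence:
    """Mean per-location tau_D (averaging + and - responses) minus the
    merged tau_D; a small positive delta means merging barely shallows
    the conservation depth, i.e. responses are context-independent."""
    for i, res in enumerate(per_location):
        if res.tau_pos is None or res.tau_neg is None:
            raise ValidationError(f"tau_D undefined at location index {i}")
    if merged.tau_pos is None or merged.tau_neg is None:
        raise ValidationError("tau_D undefined on the merged set")
    mean_individual = float(np.mean([r.mean_tau() for r in per_location]))
    return ContextDependence(
        mean_individual_tau=mean_individual, merged_tau=merged.mean_tau()
    )


def merged_tree(tree, otu_ids, mode: str = "prune"):
    """Tree for the merged consenTRAIT run over widespread OTUs.

    ``prune`` (default, deterministic) cuts the input tree down to the
    widespread tips; ``rebuild`` re-runs neighbour joining on the patristic
    distances among those tips, mirroring a from-scratch reconstruction.
    """
    from .consentrait import nj_tree
    from .datatypes import DistanceMatrix

    otu_ids = list(otu_ids)
    if mode == "prune":
        return tree.retain_tips(otu_ids)
    if mode == "rebuild":
        index = tree.index()
        D = index.patristic_matrix()
        pos = [index.tip_position(o) for o in otu_ids]
        sub = D[np.ix_(pos, pos)]
        return nj_tree(DistanceMatrix(otu_ids, sub))
    raise ValidationError(f"unknown merged-tree mode {mode!r}")


def exact_two_tailed_p(n_pos: int, n_neg: int) -> float:
    """Two-tailed exact binomial p for n_pos of n_pos+n_neg against 0.5,
    as the doubled smaller tail capped at 1."""
    n = n_pos + n_neg
    if n == 0:
        return 1.0
    lower = binom.cdf(n_pos, n, 0.5)
    upper = binom.sf(n_pos - 1, n, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


def group_consistency_test(
    response: ResponseSet,
    taxonomy: TaxonomyTable,
    rank: str,
    alpha: float = 0.05,
    min_group_size: int = 5,
) -> list[GroupTest]:
    """Screen each taxonomic group at ``rank`` for directional consistency.

    Only OTUs with a nonzero direction count; groups with fewer than
    ``min_group_size`` scored OTUs are skipped. The direction call is made
    when p < alpha (and the counts are not tied).
    """
    if rank not in RANKS:
        raise ValidationError(f"unknown rank {rank!r}; expected one of {RANKS}")
    direction = response.direction
    missing = [o for o in direction.index if o not in taxonomy.assignments.index]
    if missing:
        raise ValidationError(f"OTUs missing taxonomy: {missing[:5]}")
    groups = taxonomy.assignments.loc[direction.index, rank]
    tests: list[GroupTest] = []
    for name, members in direction.groupby(groups):
        scored = members[members != "0"]
        if len(scored) < min_group_size:
            continue
        n_pos = int((scored == "+").sum())
        n_neg = int((scored == "-").sum())
        p = exact_two_tailed_p(n_pos, n_neg)
        if p < alpha and n_pos != n_neg:
            call = "+" if n_pos > n_neg else "-"
        else:
            call = "none"
        tests.append(GroupTest(rank, str(name), n_pos, n_neg, p, call))
    return sorted(tests, key=lambda t: t.group_name)


def consistency_matrix(
    tests_by_perturbation: dict[str, list[GroupTest]],
) -> tuple[pd.DataFrame, dict]:
    """Cross-tabulate direction calls by (group, perturbation).

    Returns the matrix (cells '+', '-', or '') restricted to groups
    significant somewhere, plus summary counts: how many groups are
    significant under exactly one, exactly two, or more than two
    perturbations, and how many show opposing directions.
    """
    if len(tests_by_perturbation) < 2:
        raise ValidationError("need >= 2 perturbations")
    cells: dict[tuple[str, str], str] = {}
    groups: set[tuple[str, str]] = set()
    for pert, tests in tests_by_perturbation.items():
        for t in tests:
            key = (t.rank, t.group_name)
            groups.add(key)
            if t.direction_call != "none":
                cells[(f"{t.rank}:{t.group_name}", pert)] = t.direction_call
    perts = sorted(tests_by_perturbation)
    rows = sorted({g for (g, _) in cells})
    matrix = pd.DataFrame("", index=rows, columns=perts)
    for (g, p), call in cells.items():
        matrix.at[g, p] = call
    n_sig = (matrix != "").sum(axis=1)
    opposing = int(
        (((matrix == "+").any(axis=1)) & ((matrix == "-").any(axis=1))).sum()
    )
    summary = {
        "n_groups_called": int(len(rows)),
        "exactly_one": int((n_sig == 1).sum()),
        "exactly_two": int((n_sig == 2).sum()),
        "more_than_two": int((n_sig > 2).sum()),
        "opposing_directions": opposing,
    }
    return matrix, summary
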
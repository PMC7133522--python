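"""End-to-end composition of the pipeline stages.

One location: occupancy filter -> size factors -> log2 response ratios ->
consenTRAIT on the location's subtree. Across locations: widespread-OTU
averaging -> merged consenTRAIT -> context dependence. These helpers keep
the analysis scripts, the CLI and the evaluation code on one code path.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .consentrait import find_consensus_clades, permutation_test, tau_d
from .crossloc import context_dependence, merged_tree, widespread_otus
from .datatypes import (
    ConsenTraitResult,
    ContextDependence,
    CountTable,
    FilterReport,
    ResponseSet,
)
from .ratios import filter_low_occupancy, log2_response_ratios, size_factors
from .trees import Phylogeny


def respond_location(
    table: CountTable,
    min_fraction: float = 0.5,
    relaxed_min_plots: int = 2,
    min_otus: int = 900,
    pseudocount: float = 0.5,
) -> tuple[ResponseSet, FilterReport]:
    """Filter, normalize and compute response ratios for one location."""
    filtered, report = filter_low_occupancy(
        table, min_fraction=min_fraction,
        relaxed_min_plots=relaxed_min_plots, min_otus=min_otus,
    )
    factors = size_factors(filtered)
    response = log2_response_ratios(filtered, factors, pseudocount=pseudocount)
    return response, report


def consentrait_on_subtree(
    tree: Phylogeny,
    response: ResponseSet,
    n_randomizations: int = 0,
    seed: int = 0,
    threshold: float = 0.90,
    singleton_rule: str = "patristic",
) -> ConsenTraitResult:
    """consenTRAIT restricted to the tips that carry a response.

    Tips without a response are pruned (surfacing the join explicitly);
    with ``n_randomizations=0`` only the observed clades and tau_D are
    computed, which the multi-seed evaluations rely on for speed.
    """
    present = [t for t in tree.tip_labels if t in response.log2fc.index]
    if len(present) < len(tree.tip_labels):
        tree = tree.retain_tips(present)
    response = response.subset(tree.tip_labels)
    if n_randomizations > 0:
        return permutation_test(
            tree, response, n_randomizations=n_randomizations, seed=seed,
            threshold=threshold, singleton_rule=singleton_rule,
        )
    clades = find_consensus_clades(tree, response, threshold=threshold,
                                   singleton_rule=singleton_rule)
    return ConsenTraitResult(
        clades=clades, tau_pos=tau_d(clades, "+"), tau_neg=tau_d(clades, "-")
    )


@dataclass
class MultiLocationResult:
    per_location: dict[str, ConsenTraitResult]
    responses: dict[str, ResponseSet]
    merged_response: ResponseSet
    merged: ConsenTraitResult
    context: ContextDependence
    reports: dict[str, FilterReport] = field(default_factory=dict)


def run_multilocation(
    tree: Phylogeny,
    tables: list[CountTable],
    min_locations: int = 3,
    n_randomizations: int = 0,
    seed: int = 0,
    threshold: float = 0.90,
    merged_tree_mode: str = "prune",
    **respond_kwargs,
) -> MultiLocationResult:
    """Per-location responses and consenTRAIT, then the merged analysis."""
    responses: dict[str, ResponseSet] = {}
    reports: dict[str, FilterReport] = {}
    per_location: dict[str, ConsenTraitResult] = {}
    for table in tables:
        loc = table.location
        response, report = respond_location(table, **respond_kwargs)
        responses[loc] = response
        reports[loc] = report
        per_location[loc] = consentrait_on_subtree(
            tree, response, n_randomizations=n_randomizations,
            seed=seed, threshold=threshold,
        )
    merged_response = widespread_otus(list(responses.values()),
                                      min_locations=min_locations)
    subtree = merged_tree(tree, merged_response.otu_ids,
                          mode=merged_tree_mode)
    merged = consentrait_on_subtree(
        subtree, merged_response, n_randomizations=n_randomizations,
        seed=seed, threshold=threshold,
    )
    context = context_dependence(list(per_location.values()), merged)
    return MultiLocationResult(
        per_location=per_location,
        responses=responses,
        merged_response=merged_response,
        merged=merged,
        context=context,
        reports=reports,
    )
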
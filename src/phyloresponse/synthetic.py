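"""Synthetic study generator: trees, planted conserved responses, counts.

Emulates the statistical structure of a multi-location soil perturbation
study so the whole pipeline can be exercised against known ground truth:

* a Yule (pure-birth) phylogeny whose branch lengths are rescaled so the
  mean root-to-tip depth is 0.10 substitutions/site — the same order as
  16S OTU trees;
* response directions planted on a depth antichain of clades, so the mean
  genetic depth of the conserved clades is a known quantity;
* negative-binomial OTU count tables per location, with log-normal
  baseline abundances, uniform library-size variation, and the planted
  log2 fold changes applied to the treatment arm;
* multi-location occupancy so the widespread-OTU merge has something real
  to do.

The planted ground truth is exact, not merely in expectation: after i.i.d.
sign assignment to the antichain, sibling clades that share a sign are
merged into "effective" clades, and a deterministic repair pass reflips
signs wherever an ancestor's tips would exceed the consensus threshold
without being unanimous. At fidelity 1.0 the consensus-clade detector must
therefore return the effective clades verbatim.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .datatypes import (
    RANKS,
    CountTable,
    PlantedClade,
    ResponseSet,
    TaxonomyTable,
    TruthRecord,
    ValidationError,
)
from .trees import Phylogeny, TreeIndex, parse_newick

log = logging.getLogger("phyloresponse")

MEAN_ROOT_TO_TIP_DEPTH = 0.10  # substitutions/site, matching 16S OTU trees


def simulate_tree(n_tips: int, seed: int = 0) -> Phylogeny:
    """Pure-birth tree, rescaled to mean root-to-tip depth 0.10 subs/site.

    Lineages wait an exponential time (rate = number of extant tips), then
    a uniformly chosen tip bifurcates; a final exponential increment gives
    the last-born tips nonzero pendant edges. The resulting tree is
    ultrametric. Deterministic under ``seed``.
    """
    if n_tips < 2:
        raise ValidationError("simulate_tree needs n_tips >= 2")
    rng = np.random.default_rng(seed)
    # nodes 0 and 1 are the root's two children; tips carry pendant edges
    nodes: list[dict] = [
        {"children": None, "edge": 0.0},
        {"children": None, "edge": 0.0},
    ]
    tips = [0, 1]
    while len(tips) < n_tips:
        k = len(tips)
        dt = rng.exponential(1.0 / k)
        for t in tips:
            nodes[t]["edge"] += dt
        split = tips[rng.integers(k)]
        a, b = len(nodes), len(nodes) + 1
        nodes.append({"children": None, "edge": 0.0, "name": None})
        nodes.append({"children": None, "edge": 0.0, "name": None})
        nodes[split]["children"] = [a, b]
        tips.remove(split)
        tips.extend([a, b])
    dt = rng.exponential(1.0 / n_tips)
    for t in tips:
        nodes[t]["edge"] += dt

    width = len(str(n_tips))
    counter = iter(range(n_tips))

    def newick(i: int) -> str:
        node = nodes[i]
        if node["children"] is None:
            label = f"otu{next(counter):0{width}d}"
            return f"{label}:{node['edge']:.12g}"
        kids = ",".join(newick(c) for c in node["children"])
        return f"({kids}):{node['edge']:.12g}"

    text = f"({newick(0)},{newick(1)});"
    phylo = parse_newick(text)
    # Rescale: the tree is ultrametric, so every root-to-tip depth equals
    # the mean; scale it to MEAN_ROOT_TO_TIP_DEPTH exactly.
    height = phylo.index().root_depth
    scale = MEAN_ROOT_TO_TIP_DEPTH / height
    for node in phylo.tree.preorder_node_iter():
        if node.edge.length is not None:
            node.edge.length *= scale
    return Phylogeny(phylo.tree)


def _depth_antichain(index: TreeIndex, target_depth: float) -> list[int]:
    """Antichain of nodes whose clade depth is closest to the target.

    Descends from the root; a node deeper than the target is still
    selected when it is at least as close to the target as every one of
    its children. Every root-to-tip path crosses exactly one selected
    node (tips have depth 0), so the antichain partitions the tips.
    """
    t = target_depth
    selected: list[int] = []
    stack = [0]
    while stack:
        v = stack.pop()
        d = index.clade_depth[v]
        ch = index.children[v]
        if d <= t or all(
            abs(d - t) <= abs(index.clade_depth[c] - t) for c in ch
        ):
            selected.append(v)
        else:
            stack.extend(ch)
    return selected


def _repair_signs(
    index: TreeIndex, tip_sign: np.ndarray, threshold: float
) -> np.ndarray:
    """Reflip signs until no internal node is >threshold-dominated without
    being unanimous, so the planted clades are exactly detectable."""
    tip_sign = tip_sign.copy()
    for _ in range(index.n_nodes):
        changed = False
        # deepest violating node first: scan preorder reversed
        for v in range(index.n_nodes - 1, -1, -1):
            if index.is_tip[v]:
                continue
            s, e = index.tip_start[v], index.tip_end[v]
            seg = tip_sign[s:e]
            n_pos = int((seg > 0).sum())
            n_neg = int((seg < 0).sum())
            nt = n_pos + n_neg
            if nt < 2 or min(n_pos, n_neg) == 0:
                continue
            if max(n_pos, n_neg) > threshold * nt:
                seg[:] = 1 if n_pos > n_neg else -1
                changed = True
        if not changed:
            return tip_sign
    raise RuntimeError("sign repair did not converge")  # pragma: no cover


def _effective_clades(
    index: TreeIndex, tip_sign: np.ndarray
) -> list[PlantedClade]:
    """Maximal unanimous-sign clades: the exact detectable ground truth."""
    unanimous = np.zeros(index.n_nodes, dtype=bool)
    for v in range(index.n_nodes):
        s, e = index.tip_start[v], index.tip_end[v]
        seg = tip_sign[s:e]
        unanimous[v] = np.all(seg == seg[0])
    halves = index.nearest_tip_half_distances()
    clades = []
    for v in range(index.n_nodes):
        p = index.parent[v]
        if unanimous[v] and (p < 0 or not unanimous[p]):
            s, e = index.tip_start[v], index.tip_end[v]
            n = e - s
            depth = float(halves[s]) if n == 1 else float(index.clade_depth[v])
            clades.append(
                PlantedClade(
                    node=index.node_labels[v],
                    direction="+" if tip_sign[s] > 0 else "-",
                    genetic_depth=depth,
                    n_tips=int(n),
                    tip_ids=list(index.tip_labels[s:e]),
                )
            )
    return clades


def plant_conserved_responses(
    tree: Phylogeny,
    target_depth: float,
    fidelity: float = 1.0,
    seed: int = 0,
    threshold: float = 0.90,
) -> tuple[ResponseSet, TruthRecord]:
    """Plant phylogenetically conserved response directions on the tree.

    Clades are the depth-``target_depth`` antichain; each gets a + or -
    direction with equal probability, repaired so that no ancestor exceeds
    the consensus ``threshold`` without unanimity (exact ground truth).
    Each tip then takes its clade's direction with probability
    ``fidelity``, else the opposite; log2fc magnitudes are |Normal(0, 1)|
    with the realized sign.
    """
    index = tree.index()
    max_depth = float(index.root_dist[index.is_tip].max())
    if not (0 < target_depth < max_depth):
        raise ValidationError(
            f"target_depth must lie in (0, {max_depth:.4g}), got {target_depth}"
        )
    if not (0.5 < fidelity <= 1.0):
        raise ValidationError("fidelity must lie in (0.5, 1.0]")
    rng = np.random.default_rng(seed)
    antichain = _depth_antichain(index, target_depth)
    # With several clades, a constant trait (every tip one sign, possible
    # after sign repair collapses a lopsided draw) is a degenerate study
    # with no contrast; redraw deterministically until both signs survive.
    for _ in range(64):
        signs = rng.choice([-1, 1], size=len(antichain))
        tip_sign = np.zeros(index.n_tips, dtype=np.int8)
        for v, sign in zip(antichain, signs):
            tip_sign[index.tip_start[v]:index.tip_end[v]] = sign
        tip_sign = _repair_signs(index, tip_sign, threshold)
        if len(antichain) == 1 or len(np.unique(tip_sign)) > 1:
            break
    planted = _effective_clades(index, tip_sign)

    noise = rng.random(index.n_tips) >= fidelity
    realized = np.where(noise, -tip_sign, tip_sign)
    magnitudes = np.abs(rng.standard_normal(index.n_tips))
    log2fc = pd.Series(
        magnitudes * realized, index=list(index.tip_labels), dtype=float
    )
    response = ResponseSet(log2fc, location="synthetic")
    truth = TruthRecord(
        planted_clades=planted,
        fidelity=fidelity,
        target_depth=target_depth,
        true_log2fc=log2fc.copy(),
    )
    return response, truth


def simulate_counts(
    response: ResponseSet,
    n_control: int = 5,
    n_treatment: int = 5,
    base_abundance: float = 50.0,
    dispersion: float = 0.2,
    libsize_range: tuple[float, float] = (0.5, 2.0),
    seed: int = 0,
    location: str | None = None,
    abundance_sigma: float = 1.0,
) -> CountTable:
    """Negative-binomial count table realizing the planted responses.

    Counts for OTU i in sample j are NB with mean
    ``s_j * mu_i * 2**(log2fc_i * 1[treatment])`` and variance
    ``mean + dispersion * mean**2``; ``s_j`` is uniform in
    ``libsize_range`` and ``mu_i`` log-normal around ``base_abundance``.
    """
    if len(response.otu_ids) == 0:
        raise ValidationError("empty response set")
    if n_control < 2 or n_treatment < 2:
        raise ValidationError("need >= 2 samples per arm")
    if dispersion <= 0:
        raise ValidationError("dispersion must be positive")
    loc = location or response.location
    rng = np.random.default_rng(seed)
    n_otus = len(response.otu_ids)
    mu = base_abundance * np.exp(abundance_sigma * rng.standard_normal(n_otus))
    n_samples = n_control + n_treatment
    s = rng.uniform(libsize_range[0], libsize_range[1], size=n_samples)
    treat = np.array([0] * n_control + [1] * n_treatment)
    lfc = response.log2fc.to_numpy()
    mean = s[None, :] * mu[:, None] * np.power(2.0, lfc[:, None] * treat[None, :])
    r = 1.0 / dispersion
    p = r / (r + mean)
    counts = rng.negative_binomial(r, p)
    sample_ids = [f"{loc}_ctl{i + 1}" for i in range(n_control)] + [
        f"{loc}_trt{i + 1}" for i in range(n_treatment)
    ]
    frame = pd.DataFrame(counts, index=response.otu_ids, columns=sample_ids)
    meta = pd.DataFrame(
        {
            "location": loc,
            "arm": ["control"] * n_control + ["treatment"] * n_treatment,
        },
        index=sample_ids,
    )
    return CountTable(frame, meta)


def simulate_multilocation(
    tree: Phylogeny,
    shared_truth: TruthRecord,
    n_locations: int = 4,
    occupancy_prob: float = 0.8,
    seed: int = 0,
    min_widespread: int = 3,
    **count_kwargs,
) -> list[CountTable]:
    """Per-location count tables with shared (context-independent) truth.

    Each OTU is present in each location independently with probability
    ``occupancy_prob``; absent OTUs are dropped from that location's
    table. Sample ids are prefixed by the location so the tables are
    disjoint. Updates ``shared_truth.occupancy`` in place. Emits a warning
    (not an error) when fewer than 10 OTUs end up widespread.
    """
    if n_locations < 3:
        raise ValidationError("simulate_multilocation needs >= 3 locations")
    if not (0 < occupancy_prob <= 1):
        raise ValidationError("occupancy_prob must lie in (0, 1]")
    otus = list(shared_truth.true_log2fc.index)
    rng = np.random.default_rng(seed)
    present = rng.random((len(otus), n_locations)) < occupancy_prob
    # guarantee the TruthRecord invariant: every OTU somewhere
    for i in np.where(~present.any(axis=1))[0]:
        present[i, rng.integers(n_locations)] = True
    # a location with no OTUs at all would be an empty experiment: keep one
    for j in np.where(~present.any(axis=0))[0]:
        present[rng.integers(len(otus)), j] = True
    tables = []
    shared_truth.occupancy = {o: set() for o in otus}
    for j in range(n_locations):
        loc = f"loc{j + 1}"
        keep = [o for i, o in enumerate(otus) if present[i, j]]
        for o in keep:
            shared_truth.occupancy[o].add(loc)
        loc_response = ResponseSet(
            shared_truth.true_log2fc.loc[keep], location=loc
        )
        loc_seed = int(np.random.default_rng([seed, j]).integers(2**31))
        tables.append(
            simulate_counts(loc_response, seed=loc_seed, location=loc,
                            **count_kwargs)
        )
    n_widespread = int((present.sum(axis=1) >= min_widespread).sum())
    if n_widespread < 10:
        warnings.warn(
            f"only {n_widespread} OTUs present in >= {min_widespread} "
            "locations", stacklevel=2,
        )
    return tables


def taxonomy_from_truth(tree: Phylogeny, truth: TruthRecord) -> TaxonomyTable:
    """Pseudo-taxonomy with planted clades as genera, nested upward.

    Genus = the planted clade; family, order, class, phylum = depth
    antichains at 2x, 4x, 8x, 16x the planting target depth, so taxonomic
    ranks nest consistently with the tree, mimicking a phylogenetically
    normalized taxonomy.
    """
    index = tree.index()
    genus = {}
    for clade in truth.planted_clades:
        for tip in clade.tip_ids:
            genus[tip] = f"g_{clade.node}"
    columns = {"genus": [genus[t] for t in index.tip_labels]}
    # Raw antichain assignments, then coarsened so each finer-rank group
    # maps to exactly one coarser group (planted clades can run deeper
    # than the raw family cut when siblings merged during planting).
    finer = columns["genus"]
    for rank, mult in zip(("family", "order", "class", "phylum"), (2, 4, 8, 16)):
        depth = min(truth.target_depth * mult, index.root_depth)
        antichain = _depth_antichain(index, depth)
        raw = {}
        for v in antichain:
            for t in range(index.tip_start[v], index.tip_end[v]):
                raw[index.tip_labels[t]] = f"{rank[0]}_{index.node_labels[v]}"
        group_to_name: dict[str, str] = {}
        assigned = []
        for tip, fine_group in zip(index.tip_labels, finer):
            if fine_group not in group_to_name:
                group_to_name[fine_group] = raw[tip]
            assigned.append(group_to_name[fine_group])
        columns[rank] = assigned
        finer = assigned
    frame = pd.DataFrame(columns, index=list(index.tip_labels))
    return TaxonomyTable(frame[list(RANKS)])
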
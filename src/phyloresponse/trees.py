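"""Rooted phylogenies: Newick I/O, validation, and an indexed form.

Branch lengths are expected substitutions per site throughout, so a node's
"genetic depth" (mean distance to its descendant tips) interconverts with
percent 16S sequence dissimilarity by a factor of 200: two tips descending
from a node at depth d are separated by roughly 2d substitutions per site,
i.e. 200*d percent.

Parsing and serialisation go through dendropy; on top of that
:class:`TreeIndex` precomputes, once per tree, everything the clade
traversal and the permutation null need per randomization (contiguous
descendant-tip intervals, per-node depths, nearest-tip distances), so a
single randomization costs O(n).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .datatypes import ValidationError


class NewickParseError(ValueError):
    """Malformed Newick input; message carries the character offset."""


def depth_to_dissimilarity(depth: float) -> float:
    """Convert genetic depth (substitutions/site) to percent 16S dissimilarity.

    Two tips hanging off a node at depth ``d`` are ~``2d`` apart, so the
    equivalent average sequence dissimilarity is ``200 * d`` percent:
    a clade depth of 0.017 corresponds to 3.4% dissimilarity.
    """
    if depth < 0:
        raise ValueError(f"depth must be non-negative, got {depth}")
    return 200.0 * depth


@dataclass
class Phylogeny:
    """A rooted tree with unique tip labels and non-negative branch lengths.

    Thin wrapper over a dendropy tree; internal nodes without labels get
    stable generated ids (``node_<preorder index>``) so clades can be
    reported by name.
    """

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        self._assign_internal_labels()
        self.validate()

    def _assign_internal_labels(self) -> None:
        for i, node in enumerate(self.tree.preorder_node_iter()):
            if node.is_leaf():
                if node.taxon is not None and node.label is None:
                    node.label = node.taxon.label
            elif node.label is None:
                node.label = f"node_{i}"

    def validate(self) -> None:
        labels = self.tip_labels
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValidationError(f"duplicate tip labels: {dupes}")
        for node in self.tree.preorder_node_iter():
            if node.parent_node is not None:
                if node.edge.length is None:
                    node.edge.length = 0.0
                if node.edge.length < 0:
                    raise ValidationError(
                        f"negative branch length {node.edge.length} above "
                        f"node {node.label!r}"
                    )

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def index(self) -> "TreeIndex":
        return TreeIndex.from_phylogeny(self)

    def retain_tips(self, labels: list[str]) -> "Phylogeny":
        """Prune to the given tips, suppressing unifurcations."""
        keep = set(labels)
        missing = keep - set(self.tip_labels)
        if missing:
            raise ValidationError(f"tips not in tree: {sorted(missing)[:5]}")
        clone = self.tree.clone(depth=1)
        taxa = [l.taxon for l in clone.leaf_node_iter() if l.label in keep]
        clone.retain_taxa(taxa)
        return Phylogeny(clone)


def read_newick(path) -> Phylogeny:
    """Read one Newick tree (branch lengths mandatory on internal edges)."""
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        _raise_parse_error(exc, f" in {path}")
    _label_tips_from_taxa(tree)
    return Phylogeny(tree)


def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string (used heavily in tests and the simulator)."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        _raise_parse_error(exc, "")
    _label_tips_from_taxa(tree)
    return Phylogeny(tree)


def _raise_parse_error(exc: Exception, where: str) -> None:
    if "Duplicate taxon labels" in str(exc):
        raise ValidationError(f"duplicate tip labels{where}: {exc}") from exc
    offset = getattr(exc, "col_num", None)
    loc = f" near character offset {offset}" if offset is not None else ""
    raise NewickParseError(f"malformed Newick{where}{loc}: {exc}") from exc


def _label_tips_from_taxa(tree: dendropy.Tree) -> None:
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is not None:
            leaf.label = leaf.taxon.label


def write_newick(phylo: Phylogeny, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(to_newick(phylo))


def to_newick(phylo: Phylogeny) -> str:
    return (
        phylo.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()
        + "\n"
    )


def midpoint_root(phylo: Phylogeny) -> Phylogeny:
    """Root at the midpoint of the longest tip-to-tip path (deterministic)."""
    clone = phylo.tree.clone(depth=1)
    clone.reroot_at_midpoint(update_bipartitions=False)
    clone.seed_node.edge.length = None
    return Phylogeny(clone)


@dataclass
class TreeIndex:
    """Array view of a rooted tree for O(n)-per-randomization clade work.

    Nodes are numbered in preorder; each node's descendant tips occupy the
    contiguous interval ``[tip_start, tip_end)`` of ``tip_labels`` (which
    lists tips in preorder), so per-node direction counts reduce to prefix
    sums. ``clade_depth`` holds the mean node-to-descendant-tip distance;
    ``singleton_half`` holds, per tip, half the patristic distance to its
    nearest neighbouring tip.
    """

    node_labels: list[str]
    parent: np.ndarray          # int, -1 at root
    children: list[list[int]]
    is_tip: np.ndarray          # bool
    tip_start: np.ndarray       # int, per node
    tip_end: np.ndarray         # int, per node
    tip_labels: list[str]       # preorder tip ordering
    edge_length: np.ndarray     # float, edge above each node (0 at root)
    clade_depth: np.ndarray     # float, per node
    root_dist: np.ndarray       # float, per node
    singleton_half: np.ndarray = field(default=None)  # per tip, lazy

    @classmethod
    def from_phylogeny(cls, phylo: Phylogeny) -> "TreeIndex":
        nodes = list(phylo.tree.preorder_node_iter())
        idx = {id(n): i for i, n in enumerate(nodes)}
        m = len(nodes)
        parent = np.full(m, -1, dtype=np.int64)
        children: list[list[int]] = [[] for _ in range(m)]
        is_tip = np.zeros(m, dtype=bool)
        edge_length = np.zeros(m, dtype=float)
        labels = []
        for i, n in enumerate(nodes):
            labels.append(n.label)
            if n.parent_node is not None:
                p = idx[id(n.parent_node)]
                parent[i] = p
                children[p].append(i)
                edge_length[i] = float(n.edge.length or 0.0)
            if n.is_leaf():
                is_tip[i] = True

        tip_start = np.zeros(m, dtype=np.int64)
        tip_end = np.zeros(m, dtype=np.int64)
        tip_labels: list[str] = []
        # Postorder over preorder-reversed indices: children come after the
        # parent in preorder, so iterate indices in reverse for accumulation.
        n_tips_below = np.zeros(m, dtype=np.int64)
        depth_sum = np.zeros(m, dtype=float)
        for i in range(m - 1, -1, -1):
            if is_tip[i]:
                n_tips_below[i] = 1
            else:
                for c in children[i]:
                    n_tips_below[i] += n_tips_below[c]
                    depth_sum[i] += depth_sum[c] + edge_length[c] * n_tips_below[c]
        # Assign contiguous tip intervals in preorder.
        cursor = 0
        order = np.zeros(m, dtype=np.int64)
        stack = [0]
        while stack:
            i = stack.pop()
            order[i] = cursor if is_tip[i] else -1
            if is_tip[i]:
                tip_start[i] = cursor
                tip_end[i] = cursor + 1
                tip_labels.append(labels[i])
                cursor += 1
            else:
                stack.extend(reversed(children[i]))
        for i in range(m - 1, -1, -1):
            if not is_tip[i]:
                tip_start[i] = min(tip_start[c] for c in children[i])
                tip_end[i] = max(tip_end[c] for c in children[i])

        root_dist = np.zeros(m, dtype=float)
        for i in range(1, m):
            root_dist[i] = root_dist[parent[i]] + edge_length[i]
        clade_depth = np.where(n_tips_below > 0, depth_sum / n_tips_below, 0.0)
        return cls(
            node_labels=labels,
            parent=parent,
            children=children,
            is_tip=is_tip,
            tip_start=tip_start,
            tip_end=tip_end,
            tip_labels=tip_labels,
            edge_length=edge_length,
            clade_depth=clade_depth,
            root_dist=root_dist,
        )

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def root_depth(self) -> float:
        """Mean root-to-tip distance."""
        return float(self.clade_depth[0])

    def n_desc_tips(self, node: int) -> int:
        return int(self.tip_end[node] - self.tip_start[node])

    def tip_position(self, label: str) -> int:
        try:
            return self.tip_labels.index(label)
        except ValueError:
            raise KeyError(f"tip {label!r} not in tree") from None

    def patristic_matrix(self) -> np.ndarray:
        """Tip-to-tip path lengths, indexed by preorder tip position.

        Built by sweeping internal nodes: tips in different child subtrees
        of node v have their LCA at v, so d(i,j) = rd(i)+rd(j)-2*rd(v),
        assigned blockwise over the contiguous tip intervals.
        """
        n = self.n_tips
        # root distance per tip position
        rd = np.zeros(n)
        for i in range(self.n_nodes):
            if self.is_tip[i]:
                rd[self.tip_start[i]] = self.root_dist[i]
        D = np.zeros((n, n))
        for v in range(self.n_nodes):
            ch = self.children[v]
            for a in range(len(ch)):
                for b in range(a + 1, len(ch)):
                    sa, ea = self.tip_start[ch[a]], self.tip_end[ch[a]]
                    sb, eb = self.tip_start[ch[b]], self.tip_end[ch[b]]
                    block = rd[sa:ea, None] + rd[None, sb:eb] - 2 * self.root_dist[v]
                    D[sa:ea, sb:eb] = block
                    D[sb:eb, sa:ea] = block.T
        return D

    def nearest_tip_half_distances(self) -> np.ndarray:
        """Per tip: half the patristic distance to the nearest other tip."""
        if self.singleton_half is None:
            if self.n_tips < 2:
                raise ValidationError("singleton depth needs >= 2 tips")
            D = self.patristic_matrix()
            np.fill_diagonal(D, np.inf)
            self.singleton_half = 0.5 * D.min(axis=1)
        return self.singleton_half


def clade_depth(phylo: Phylogeny, node_label: str) -> float:
    """Mean path length from the named node to its descendant tips."""
    index = phylo.index()
    try:
        i = index.node_labels.index(node_label)
    except ValueError:
        raise KeyError(f"node {node_label!r} not in tree") from None
    return float(index.clade_depth[i])


def singleton_depth(phylo: Phylogeny, tip_label: str) -> float:
    """Half the patristic distance from the tip to its nearest neighbour."""
    index = phylo.index()
    pos = index.tip_position(tip_label)
    return float(index.nearest_tip_half_distances()[pos])


def patristic_distance(phylo: Phylogeny, tip_a: str, tip_b: str) -> float:
    index = phylo.index()
    D = index.patristic_matrix()
    return float(D[index.tip_position(tip_a), index.tip_position(tip_b)])


def trees_isomorphic(a: Phylogeny, b: Phylogeny, tol: float = 1e-9) -> bool:
    """Topology + branch-length equality via canonical clade signatures."""

    def signature(phylo: Phylogeny):
        index = phylo.index()
        sigs = {}
        for i in range(index.n_nodes):
            tips = frozenset(
                index.tip_labels[t]
                for t in range(index.tip_start[i], index.tip_end[i])
            )
            sigs[tips] = index.edge_length[i]
        return sigs

    sa, sb = signature(a), signature(b)
    if set(sa) != set(sb):
        return False
    return all(abs(sa[k] - sb[k]) <= tol for k in sa)
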
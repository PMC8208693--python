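"""Tree handling for the blast-vs-phylogeny congruence check.

A best blast hit need not be the nearest neighbour in a phylogeny, so an
HGT claim based on homology-search E values should be corroborated by the
gene tree: the transferred gene's closest leaf (by patristic distance)
should be the putative donor. This module parses Newick trees (via
dendropy), collapses weakly supported nodes the way a consensus-tree
procedure would (e.g. dropping nodes below 700/1000 bootstrap), computes
patristic distances, and runs the congruence check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import dendropy


class TreeError(ValueError):
    """Malformed Newick input or an unknown leaf label."""


@dataclass
class CongruenceResult:
    query_leaf: str
    nearest_leaf: str
    nearest_distance: float
    blast_best_subject: str
    congruent: bool
    tied: bool = False
    sister_leaves: tuple = ()


class PhyloTree:
    """A leaf-labelled tree with branch lengths and optional node supports.

    Thin wrapper over a dendropy tree. Missing branch lengths are treated
    as 1 (flagged); support values are auto-declared per-mille when any
    exceeds 100 (phylip-style of-1000 bootstrap scores), else percent.
    """

    def __init__(self, tree: dendropy.Tree, support_scale: Optional[str] = None):
        self._tree = tree
        self.missing_lengths_imputed = False
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                edge.length = 1.0
                self.missing_lengths_imputed = True
            elif edge.length < 0:
                raise TreeError(f"negative branch length {edge.length}")
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise TreeError(f"duplicate leaf labels: {sorted(dupes)}")
        if support_scale is None:
            supports = list(self._iter_supports())
            support_scale = ("permille" if any(s > 100 for s in supports)
                             else "percent")
        self.support_scale = support_scale

    def _iter_supports(self):
        for nd in self._tree.preorder_internal_node_iter():
            s = _node_support(nd)
            if s is not None:
                yield s

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    def __contains__(self, label: str) -> bool:
        return label in self.leaf_labels

    def as_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True,
            unquoted_underscores=True).strip()


def _node_support(node: dendropy.Node) -> Optional[float]:
    # internal-node support rides on the node label in plain Newick
    if node.label is not None:
        try:
            return float(node.label)
        except ValueError:
            return None
    return None


def parse_newick(text: str) -> PhyloTree:
    """Parse Newick text (optional branch lengths and internal supports)."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"Newick parse failure: {exc}") from exc
    return PhyloTree(tree)


def write_newick(tree: PhyloTree) -> str:
    return tree.as_newick()


def _leaf(tree: PhyloTree, label: str) -> dendropy.Node:
    for lf in tree._tree.leaf_node_iter():
        if lf.taxon.label == label:
            return lf
    raise TreeError(f"unknown leaf label {label!r}")


def patristic_distance(tree: PhyloTree, leaf_a: str, leaf_b: str) -> float:
    """Sum of branch lengths on the unique path between two leaves."""
    if leaf_a == leaf_b:
        _leaf(tree, leaf_a)
        return 0.0
    pdm = tree._tree.phylogenetic_distance_matrix()
    ta = _leaf(tree, leaf_a).taxon
    tb = _leaf(tree, leaf_b).taxon
    return pdm.patristic_distance(ta, tb)


def distance_matrix(tree: PhyloTree) -> dict[tuple[str, str], float]:
    """All leaf-pair patristic distances, keyed by (label_a, label_b)."""
    pdm = tree._tree.phylogenetic_distance_matrix()
    leaves = [lf.taxon for lf in tree._tree.leaf_node_iter()]
    out = {}
    for a in leaves:
        for b in leaves:
            out[(a.label, b.label)] = (0.0 if a is b
                                       else pdm.patristic_distance(a, b))
    return out


def collapse_low_support(tree: PhyloTree, threshold: float,
                         redistribute: bool = False) -> PhyloTree:
    """Contract internal edges whose child-node support is below threshold.

    Children of a collapsed node re-attach to its parent, creating a
    polytomy; leaves are never removed. By default the contracted edge's
    length is discarded (a warning notes that post-collapse patristic
    distances are topology-biased); with ``redistribute=True`` it is added
    to each re-attached child edge instead, preserving leaf-to-leaf path
    lengths through the collapsed node.
    """
    scale_max = 1000 if tree.support_scale == "permille" else 100
    if not 0 <= threshold <= scale_max:
        raise TreeError(
            f"threshold {threshold} outside declared support scale "
            f"(0..{scale_max})"
        )
    clone = parse_newick(tree.as_newick())
    clone.support_scale = tree.support_scale
    collapsed_any = False
    for node in list(clone._tree.preorder_internal_node_iter()):
        if node is clone._tree.seed_node:
            continue
        support = _node_support(node)
        if support is None or support >= threshold:
            continue
        parent = node.parent_node
        extra = node.edge.length or 0.0
        for child in list(node.child_nodes()):
            node.remove_child(child)
            if redistribute and child.edge.length is not None:
                child.edge.length += extra
            parent.add_child(child)
        parent.remove_child(node)
        collapsed_any = True
    if collapsed_any and not redistribute:
        warnings.warn(
            "collapsed edges discarded their lengths; patristic distances "
            "through collapsed nodes are now topology-biased "
            "(use redistribute=True to preserve path lengths)",
            stacklevel=2,
        )
    return clone


def congruence_check(tree: PhyloTree, query_leaf: str,
                     blast_best_subject: str,
                     candidate_set: Optional[Iterable[str]] = None,
                     ) -> CongruenceResult:
    """Is the query's nearest tree neighbour its best homology-search hit?

    The nearest neighbour is the patristic-distance argmin over candidates
    (all other leaves unless ``candidate_set`` restricts them, e.g. to
    exclude the query's own paralogues); exact ties are broken
    lexicographically and flagged. The query's sister-clade leaf set is
    also reported so clade-sisterhood readings can be checked.
    """
    if query_leaf not in tree:
        raise TreeError(f"query leaf {query_leaf!r} not in tree")
    candidates = set(candidate_set) if candidate_set is not None else set(
        tree.leaf_labels)
    candidates.discard(query_leaf)
    if not candidates:
        raise TreeError("candidate set empty after excluding the query")
    unknown = candidates - set(tree.leaf_labels)
    if unknown:
        raise TreeError(f"candidate leaves not in tree: {sorted(unknown)}")

    pdm = tree._tree.phylogenetic_distance_matrix()
    qtax = _leaf(tree, query_leaf).taxon
    dists = {
        lf.taxon.label: pdm.patristic_distance(qtax, lf.taxon)
        for lf in tree._tree.leaf_node_iter()
        if lf.taxon.label in candidates
    }
    dmin = min(dists.values())
    winners = sorted(lbl for lbl, d in dists.items() if d == dmin)
    nearest = winners[0]

    qnode = _leaf(tree, query_leaf)
    parent = qnode.parent_node
    sisters = tuple(
        lf.taxon.label
        for sib in (parent.child_nodes() if parent else [])
        if sib is not qnode
        for lf in sib.leaf_iter()
    )
    return CongruenceResult(
        query_leaf=query_leaf,
        nearest_leaf=nearest,
        nearest_distance=dmin,
        blast_best_subject=blast_best_subject,
        congruent=(nearest == blast_best_subject),
        tied=len(winners) > 1,
        sister_leaves=sisters,
    )
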
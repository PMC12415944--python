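"""Distance-based tree building, longest-branch rooting, and Newick I/O.

Neighbor-joining (for the substitution-branch-length trees consumed by PTP)
and UPGMA (for the ultrametric trees consumed by GMYC) are deliberate
desk-scale substitutes for heavyweight ML / Bayesian tree inference.  NJ is
exact on additive distance matrices and UPGMA on ultrametric ones, which is
what the unit tests exploit.

Trees are :class:`dendropy.Tree` objects throughout; branch lengths are in
expected substitutions per site.
"""

from __future__ import annotations

import io

import dendropy
import numpy as np

from .stats import DistanceMatrix

__all__ = [
    "nj_tree",
    "upgma_tree",
    "root_on_longest_branch",
    "read_newick",
    "write_newick",
    "node_ages",
    "is_ultrametric",
    "leaf_labels",
    "total_tree_length",
    "two_taxon_tree",
]


def _csv_escape(label: str) -> str:
    if any(c in label for c in ",\n\""):
        raise ValueError(f"sample id {label!r} not representable")
    return label


def _to_pdm(dist: DistanceMatrix) -> dendropy.PhylogeneticDistanceMatrix:
    buf = io.StringIO()
    ids = [_csv_escape(s) for s in dist.sample_ids]
    buf.write("." + "".join("," + s for s in ids) + "\n")
    for i, s in enumerate(ids):
        buf.write(s + "".join(f",{x:.12g}" for x in dist.d[i]) + "\n")
    buf.seek(0)
    return dendropy.PhylogeneticDistanceMatrix.from_csv(buf, delimiter=",")


def two_taxon_tree(a: str, b: str, d: float) -> dendropy.Tree:
    """Two leaves joined by a single edge of length ``d`` (held on leaf ``a``)."""
    first, second = sorted([a, b])
    return read_newick(f"({first}:{d},{second}:0.0);")


def nj_tree(dist: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; negative branch lengths clamped to 0.

    The returned tree is unrooted (trifurcating seed node).  With exactly two
    taxa a single-edge tree is returned.
    """
    if dist.n < 2:
        raise ValueError("need at least 2 taxa")
    if dist.n == 2:
        return two_taxon_tree(dist.sample_ids[0], dist.sample_ids[1], float(dist.d[0, 1]))
    tree = _to_pdm(dist).nj_tree()
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    tree.is_rooted = False
    return tree


def upgma_tree(dist: DistanceMatrix) -> dendropy.Tree:
    """Average-linkage agglomeration; merges at height d/2; rooted ultrametric."""
    if dist.n < 2:
        raise ValueError("need at least 2 taxa")
    if dist.n == 2:
        h = float(dist.d[0, 1]) / 2.0
        a, b = sorted(dist.sample_ids)
        tree = read_newick(f"({a}:{h},{b}:{h});")
        tree.is_rooted = True
        return tree
    tree = _to_pdm(dist).upgma_tree()
    tree.is_rooted = True
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    return tree


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def total_tree_length(tree: dendropy.Tree) -> float:
    return sum(
        e.length or 0.0 for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node
    )


def _leafset_below(edge) -> tuple[str, ...]:
    return tuple(sorted(lf.taxon.label for lf in edge.head_node.leaf_iter()))


def root_on_longest_branch(tree: dendropy.Tree) -> dendropy.Tree:
    """Insert a root at the midpoint of the single longest edge.

    Ties are broken by the lexicographically smallest leaf set below the
    edge.  Total tree length is preserved.
    """
    tree = tree.clone(depth=1)
    # treat the input as unrooted: a bifurcating "root" is an artefact whose
    # two incident edges really form one edge
    if len(tree.seed_node.child_nodes()) == 2:
        tree.deroot()
    candidates = [
        e
        for e in tree.preorder_edge_iter()
        if e.head_node is not tree.seed_node and e.length is not None
    ]
    if not candidates:
        raise ValueError("tree has no edges to root on")
    top = max(e.length for e in candidates)
    tied = [e for e in candidates if e.length == top]
    best = min(tied, key=_leafset_below)
    half = best.length / 2.0
    tree.reroot_at_edge(best, length1=half, length2=half, suppress_unifurcations=True)
    tree.is_rooted = True
    return tree


def read_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string; duplicate leaf labels are an error."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except dendropy.utility.error.DataParseError as exc:
        raise ValueError(
            f"malformed Newick (duplicate labels or syntax): {exc}"
        ) from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate leaf labels: {dupes}")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()


def node_ages(tree: dendropy.Tree, force_tip_zero: bool = True) -> dict:
    """Assign and return node ages (tips at 0) for an ultrametric tree.

    Small numerical jitter from distance-based heights is absorbed by
    clamping tip ages to exactly zero and negatives to zero.  Returns a map
    ``node -> age``.
    """
    dists = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            dists[node] = 0.0
        else:
            dists[node] = dists[node.parent_node] + (node.edge.length or 0.0)
    depth = max(dists[lf] for lf in tree.leaf_node_iter())
    ages = {}
    for node in tree.preorder_node_iter():
        age = depth - dists[node]
        if force_tip_zero and node.is_leaf():
            age = 0.0
        ages[node] = max(age, 0.0)
        node.age = ages[node]
    return ages


def is_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-6) -> bool:
    """True when all root-to-tip path lengths agree within ``rel_tol`` of the depth."""
    dists = []
    acc = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            acc[node] = 0.0
        else:
            acc[node] = acc[node.parent_node] + (node.edge.length or 0.0)
        if node.is_leaf():
            dists.append(acc[node])
    depth = max(dists)
    if depth == 0:
        return True
    return (depth - min(dists)) <= rel_tol * depth
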
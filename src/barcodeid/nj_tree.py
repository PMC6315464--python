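"""Neighbor-joining trees, bootstrap supports, and monophyly checks.

The tree-building route to species identification: build an NJ tree
(Saitou & Nei agglomeration) from the K2P distance matrix, attach
nonparametric bootstrap supports (column resampling), root on the
outgroup, and ask whether each species forms exactly one clade.

Trees are carried as :mod:`dendropy` objects; the NJ agglomeration
itself is implemented here so that Q-criterion ties break
deterministically (lexicographically smallest joined-pair ids), making
topologies reproducible across platforms.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import dendropy
import numpy as np

from .distance import DistanceMatrix, distance_matrix_from_codes, encode_alignment
from .seqio import BarcodeAlignment

_Q_TIE_TOL = 1e-12


class _Node:
    """Lightweight unrooted-tree node used during agglomeration."""

    __slots__ = ("taxon", "children", "label")

    def __init__(self, taxon: str | None, children=None, label: str = ""):
        self.taxon = taxon
        self.children: list[tuple["_Node", float]] = children or []
        self.label = label  # smallest leaf id below: deterministic tie-break key

    def leaf_labels(self) -> frozenset:
        if self.taxon is not None:
            return frozenset([self.taxon])
        out = set()
        for child, _ in self.children:
            out |= child.leaf_labels()
        return frozenset(out)


@dataclass
class PhyloTree:
    """An (un)rooted tree with branch lengths and optional bipartition
    bootstrap supports (percentages in [0, 100])."""

    tree: dendropy.Tree
    supports: dict[frozenset, float] | None = None

    @property
    def leaf_ids(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def splits(self, nontrivial_only: bool = True) -> set[frozenset]:
        """Bipartitions as canonical frozensets of leaf ids.

        Each split is represented by the side *not* containing the
        lexicographically smallest leaf id.
        """
        all_leaves = frozenset(self.leaf_ids)
        ref = min(all_leaves)
        n = len(all_leaves)
        out: set[frozenset] = set()
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if ref in side:
                side = all_leaves - side
            if nontrivial_only and not (1 < len(side) < n - 1):
                continue
            if 0 < len(side) < n:
                out.add(side)
        return out

    def as_newick(self) -> str:
        if self.supports is not None:
            _annotate_supports(self.tree, self.supports)
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()


def _annotate_supports(tree: dendropy.Tree, supports: dict[frozenset, float]) -> None:
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = min(all_leaves)
    for node in tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = all_leaves - side
        if side in supports:
            node.label = str(int(round(supports[side])))


def _nj_agglomerate(values: np.ndarray, ids: list[str]) -> _Node:
    """Saitou–Nei neighbor joining on a complete distance matrix.

    Iteratively joins the pair minimizing Q(i,j) = (n-2)·d(i,j) − r_i − r_j,
    with ties broken toward the lexicographically smallest pair of node
    labels; terminates on a central trifurcation.
    """
    n = len(ids)
    nodes = [_Node(taxon=rid, label=rid) for rid in ids]
    D = values.copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=0)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        tol = _Q_TIE_TOL * max(1.0, abs(qmin))
        cand = np.argwhere(Q <= qmin + tol)
        i, j = min(
            ((int(a), int(b)) for a, b in cand if a < b),
            key=lambda ij: tuple(sorted((nodes[ij[0]].label, nodes[ij[1]].label))),
        )
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        merged = _Node(
            taxon=None,
            children=[(nodes[i], li), (nodes[j], lj)],
            label=min(nodes[i].label, nodes[j].label),
        )
        new_row = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], new_row[keep]])
        D = np.hstack([D, np.append(new_row[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [merged]

    if len(nodes) == 3:
        d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
        lengths = [
            0.5 * (d01 + d02 - d12),
            0.5 * (d01 + d12 - d02),
            0.5 * (d02 + d12 - d01),
        ]
        return _Node(
            taxon=None,
            children=list(zip(nodes, lengths)),
            label=min(nd.label for nd in nodes),
        )
    # two taxa: single edge, represented as a root with both as children
    return _Node(
        taxon=None,
        children=[(nodes[0], D[0, 1] / 2.0), (nodes[1], D[0, 1] / 2.0)],
        label=min(nd.label for nd in nodes),
    )


def _to_dendropy(root: _Node, clamp_negative: bool) -> dendropy.Tree:
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)

    def build(node: _Node, dnode: dendropy.Node) -> None:
        if node.taxon is not None:
            dnode.taxon = ns.require_taxon(label=node.taxon)
        for child, length in node.children:
            dchild = dendropy.Node()
            dchild.edge.length = max(0.0, length) if clamp_negative else length
            dnode.add_child(dchild)
            build(child, dchild)

    build(root, tree.seed_node)
    tree.is_rooted = False
    return tree


def _collect_splits(root: _Node, all_leaves: frozenset) -> set[frozenset]:
    ref = min(all_leaves)
    n = len(all_leaves)
    out: set[frozenset] = set()

    def walk(node: _Node) -> frozenset:
        if node.taxon is not None:
            return frozenset([node.taxon])
        below = frozenset()
        for child, _ in node.children:
            side = walk(child)
            canon = (all_leaves - side) if ref in side else side
            if 1 < len(canon) < n - 1:
                out.add(canon)
            below |= side
        return below

    walk(root)
    return out


def build_nj_tree(matrix: DistanceMatrix, clamp_negative: bool = False) -> PhyloTree:
    """Unrooted NJ tree from a complete distance matrix.

    Negative branch lengths (a known NJ artefact) are retained by
    default; ``clamp_negative=True`` floors them at zero. Missing
    (saturated) entries are an error: resolve them upstream.
    """
    if len(matrix.ids) < 3:
        raise ValueError("NJ needs at least 3 taxa")
    nan = np.argwhere(np.isnan(matrix.values))
    if len(nan):
        i, j = nan[0]
        raise ValueError(
            f"missing distance for pair ({matrix.ids[i]!r}, {matrix.ids[j]!r})"
        )
    root = _nj_agglomerate(matrix.values, matrix.ids)
    return PhyloTree(tree=_to_dendropy(root, clamp_negative))


def bootstrap_support(
    alignment: BarcodeAlignment,
    n_replicates: int = 1000,
    seed: int = 0,
    clamp_negative: bool = False,
    max_redraws: int = 1000,
) -> PhyloTree:
    """NJ tree with nonparametric bootstrap supports.

    Each replicate resamples alignment columns with replacement to the
    original length, recomputes the K2P matrix and NJ tree; the support
    of each internal bipartition of the original tree is the percentage
    of replicate trees containing it. Replicates whose matrix has a
    saturated/undefined entry are redrawn (counted, up to
    ``max_redraws`` extra draws).
    """
    codes = encode_alignment(alignment)
    ids = alignment.ids
    original_matrix = distance_matrix_from_codes(codes, ids)
    tree = build_nj_tree(original_matrix, clamp_negative=clamp_negative)

    all_leaves = frozenset(ids)
    target_splits = tree.splits(nontrivial_only=True)
    hits = {s: 0 for s in target_splits}
    rng = np.random.default_rng(seed)
    length = codes.shape[1]
    n_redrawn = 0

    done = 0
    while done < n_replicates:
        cols = rng.integers(0, length, size=length)
        try:
            rep = distance_matrix_from_codes(codes[:, cols], ids)
            if rep.saturated_pairs:
                raise ValueError("saturated replicate")
            rep_root = _nj_agglomerate(rep.values, ids)
        except ValueError:
            n_redrawn += 1
            if n_redrawn > max_redraws:
                raise RuntimeError(
                    f"bootstrap: exceeded {max_redraws} redraws of degenerate replicates"
                )
            continue
        rep_splits = _collect_splits(rep_root, all_leaves)
        for s in target_splits & rep_splits:
            hits[s] += 1
        done += 1

    tree.supports = {s: 100.0 * h / n_replicates for s, h in hits.items()}
    if n_redrawn:
        logging.getLogger(__name__).warning(
            "bootstrap: redrew %d degenerate replicate(s)", n_redrawn
        )
    return tree


def nj_tree_from_alignment(
    alignment: BarcodeAlignment, clamp_negative: bool = False
) -> PhyloTree:
    """Convenience: K2P matrix + NJ in one step."""
    return build_nj_tree(
        distance_matrix_from_codes(encode_alignment(alignment), alignment.ids),
        clamp_negative=clamp_negative,
    )


def check_monophyly(
    tree: PhyloTree,
    partition: dict[str, list[str]],
    outgroup_species: str | None = None,
    outgroup_ids: list[str] | None = None,
) -> dict[str, bool]:
    """Per-species monophyly in the outgroup-rooted tree.

    A species is monophyletic iff its leaves are exactly the non-outgroup
    side of some edge, i.e. they form one maximal clade once the tree is
    rooted on the outgroup. Singleton species are trivially monophyletic.
    """
    all_leaves = frozenset(tree.leaf_ids)
    outgroup = set(outgroup_ids or [])
    if outgroup_species is not None:
        outgroup |= {
            rid for rid in partition.get(outgroup_species, []) if rid in all_leaves
        }
    for sp, ids in partition.items():
        if sp == outgroup_species:
            continue
        if not ids:
            raise ValueError(f"species {sp!r} has no leaves")
        missing = set(ids) - all_leaves
        if missing:
            raise ValueError(f"species {sp!r}: leaves {sorted(missing)} not in tree")

    # every edge induces a split; collect both sides, trivial edges included
    ref = min(all_leaves)
    sides: set[frozenset] = set()
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        sides.add(side)
        sides.add(all_leaves - side)

    flags: dict[str, bool] = {}
    for sp, ids in partition.items():
        if sp == outgroup_species:
            continue
        leafset = frozenset(ids)
        if len(leafset) == 1:
            flags[sp] = True
            continue
        # a clade in the rooted tree = a split side disjoint from the outgroup
        flags[sp] = any(
            side == leafset and not (side & outgroup) for side in sides
        )
    return flags


def write_newick(tree: PhyloTree, path) -> None:
    """Write Newick with branch lengths and integer bootstrap supports as
    internal node labels."""
    if not tree.leaf_ids:
        raise ValueError("cannot write an empty tree")
    with open(path, "w") as fh:
        fh.write(tree.as_newick() + "\n")


def read_newick(path) -> PhyloTree:
    """Read a Newick tree, interpreting internal node labels as supports."""
    tree = dendropy.Tree.get(path=os.fspath(path), schema="newick")
    pt = PhyloTree(tree=tree)
    all_leaves = frozenset(pt.leaf_ids)
    ref = min(all_leaves)
    supports: dict[frozenset, float] = {}
    for node in tree.preorder_internal_node_iter():
        if node.parent_node is None or node.label is None:
            continue
        try:
            value = float(node.label)
        except ValueError:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = all_leaves - side
        supports[side] = value
    pt.supports = supports or None
    return pt
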
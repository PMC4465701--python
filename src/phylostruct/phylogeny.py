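"""Rooted phylogeny container and node-count distances.

All downstream analyses treat the tree purely topologically: the distance
between two tips is the number of edges on the path connecting them
("node counting"), which equals the patristic distance after setting every
branch length to one.  Branch lengths present in an input file are kept on
the underlying dendropy tree but never used.
"""

from __future__ import annotations

import io
from typing import Iterable, Sequence

import dendropy
import numpy as np
from skbio import DistanceMatrix

__all__ = ["Phylogeny", "read_newick", "node_count_distances"]


def _normalize_label(label: str) -> str:
    """Trim whitespace and map spaces to underscores (newick convention)."""
    return label.strip().replace(" ", "_")


class Phylogeny:
    """A rooted tree over named tips; polytomies allowed.

    Thin wrapper around :class:`dendropy.Tree` enforcing the invariants the
    analyses rely on: unique non-empty tip names, at least two tips, every
    internal node with at least two children.
    """

    def __init__(self, tree: dendropy.Tree):
        tree.is_rooted = True
        # collapse degree-2 nodes (e.g. '(...);' wrappers or pruning leftovers)
        tree.suppress_unifurcations()
        self._tree = tree
        tips = []
        for leaf in tree.leaf_node_iter():
            if leaf.taxon is None or not str(leaf.taxon.label).strip():
                raise ValueError("every tip must carry a non-empty name")
            leaf.taxon.label = _normalize_label(str(leaf.taxon.label))
            tips.append(leaf.taxon.label)
        if len(tips) < 2:
            raise ValueError("a phylogeny needs at least 2 tips")
        if len(set(tips)) != len(tips):
            dupes = sorted({t for t in tips if tips.count(t) > 1})
            raise ValueError(f"duplicate tip names: {dupes}")
        self.tips: list[str] = sorted(tips)
        self.has_branch_lengths = any(
            e.length is not None for e in tree.preorder_edge_iter()
            if e.head_node is not tree.seed_node
        )

    # -- constructors -------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick",
                                     preserve_underscores=True)
        except Exception as exc:  # dendropy raises various parse errors
            raise ValueError(f"could not parse newick: {exc}") from exc
        return cls(tree)

    # -- properties ----------------------------------------------------

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    # -- behaviour -----------------------------------------------------

    def subtree(self, tips: Iterable[str]) -> "Phylogeny":
        """Prune to ``tips`` (the regional-pool subtree used for nulls)."""
        keep = {_normalize_label(t) for t in tips}
        missing = keep - set(self.tips)
        if missing:
            raise KeyError(f"tips not on tree: {sorted(missing)}")
        clone = self._tree.clone(depth=1)
        clone.retain_taxa_with_labels(sorted(keep))
        return Phylogeny(clone)

    def node_count_distances(self) -> DistanceMatrix:
        return node_count_distances(self)

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Phylogeny with {self.n_tips} tips>"


def read_newick(path) -> Phylogeny:
    """Read a rooted newick file into a :class:`Phylogeny`.

    Branch lengths, if present, are retained on the tree object but ignored
    by every analysis in this package (distances are node counts).
    """
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        raise ValueError(f"{path}: empty newick file")
    return Phylogeny.from_newick(text)


def node_count_distances(phylogeny: Phylogeny) -> DistanceMatrix:
    """Pairwise tip-to-tip distances counted in edges.

    Equivalent to the patristic distance with every branch length set to 1.
    Returned as a :class:`skbio.DistanceMatrix` whose ids are the sorted tip
    names.
    """
    clone = phylogeny.tree.clone(depth=1)
    for edge in clone.preorder_edge_iter():
        edge.length = 1.0
    pdm = clone.phylogenetic_distance_matrix()
    tips = phylogeny.tips
    taxa = {t.label: t for t in clone.taxon_namespace}
    n = len(tips)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.distance(taxa[tips[i]], taxa[tips[j]])
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids=tips)
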
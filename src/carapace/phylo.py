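"""Time-scaled phylogenies and the phylogenetic variance-covariance matrix.

Trees are rooted, with branch lengths in time units (Myr).  Trees need not be
ultrametric: fossil tips simply have shorter root-to-tip paths, so the
diagonal of the phylogenetic covariance matrix may vary across tips.

The covariance structure used throughout the package is the Brownian-motion
expectation: under BM at unit rate, the covariance between the trait values
of two tips equals the depth of their most recent common ancestor (the time
they evolved together), and the variance of each tip equals its root-to-tip
path length.  Pagel's lambda rescales the off-diagonal (shared) part of this
matrix while leaving tip variances untouched; lambda = 1 recovers the full
BM structure and lambda = 0 yields phylogenetically independent residuals.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "PhyloError",
    "PhyloCov",
    "Phylogeny",
    "parse_newick",
    "prune_to_taxa",
    "graft_tip",
    "vcv_matrix",
    "lambda_transform",
]


class PhyloError(ValueError):
    """Raised for malformed trees or invalid tree operations."""


@dataclass(frozen=True)
class PhyloCov:
    """Phylogenetic variance-covariance matrix with its taxon order.

    Attributes
    ----------
    taxa : tuple of str
        Tip labels, in the row/column order of ``matrix``.
    matrix : ndarray, shape (n, n)
        ``matrix[i, j]`` is the depth of the MRCA of taxa i and j (time
        units); the diagonal holds root-to-tip path lengths.
    lam : float or None
        The Pagel's lambda already applied to the off-diagonal, or ``None``
        for the raw (untransformed) BM matrix.
    """

    taxa: tuple
    matrix: np.ndarray
    lam: float | None = None

    @property
    def n(self) -> int:
        return len(self.taxa)

    def subset(self, labels) -> "PhyloCov":
        """Row/column subset (and reorder) by taxon label."""
        idx = {t: i for i, t in enumerate(self.taxa)}
        try:
            ix = [idx[l] for l in labels]
        except KeyError as e:
            raise PhyloError(f"unknown taxon {e.args[0]!r}") from None
        return PhyloCov(tuple(labels), self.matrix[np.ix_(ix, ix)], self.lam)

    def to_tsv(self) -> str:
        """Serialize as TSV with the taxon order as header row."""
        buf = io.StringIO()
        buf.write("\t".join(self.taxa) + "\n")
        for row in self.matrix:
            buf.write("\t".join(f"{v:.10g}" for v in row) + "\n")
        return buf.getvalue()


class Phylogeny:
    """A rooted, time-scaled tree (thin wrapper around a dendropy tree).

    Root-to-tip depths include the root (stem) edge length when present, so
    pruning that leaves a degree-one root preserves tip variances exactly.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=False,
                preserve_underscores=True,
            )
        except Exception as e:  # dendropy raises several error types
            raise PhyloError(f"malformed Newick: {e}") from None
        return cls(tree)

    def _validate(self) -> None:
        labels = self.tips
        if len(labels) != len(set(labels)):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise PhyloError(f"duplicate tip labels: {dup}")
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue  # stem edge may be absent
            if node.edge.length is None:
                raise PhyloError("missing branch length")
            if node.edge.length < 0:
                raise PhyloError("negative branch length")
            if node.is_leaf() and node.edge.length == 0:
                warnings.warn(
                    f"zero-length terminal branch at tip "
                    f"{node.taxon.label if node.taxon else '?'}",
                    stacklevel=3,
                )

    # -- basic queries ----------------------------------------------------

    @property
    def tips(self) -> list:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def _depths(self) -> dict:
        """Depth from the origin (top of stem edge) of every node."""
        depths = {}
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                depths[node] = node.edge.length or 0.0
            else:
                depths[node] = depths[node.parent_node] + node.edge.length
        return depths

    @property
    def height(self) -> float:
        """Maximum root-to-tip depth (time of the most recent tip)."""
        d = self._depths()
        return max(d[lf] for lf in self._tree.leaf_node_iter())

    @property
    def tip_depths(self) -> dict:
        d = self._depths()
        return {lf.taxon.label: d[lf] for lf in self._tree.leaf_node_iter()}

    @property
    def tip_ages(self) -> dict:
        """Age before the most recent tip (0 = extant, >0 = fossil)."""
        d = self.tip_depths
        h = max(d.values())
        return {k: h - v for k, v in d.items()}

    def patristic(self, a: str, b: str) -> float:
        """Path length between two tips along the tree."""
        pdm = self._tree.phylogenetic_distance_matrix()
        tns = {t.label: t for t in self._tree.taxon_namespace}
        return pdm.patristic_distance(tns[a], tns[b])

    def write_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def copy(self) -> "Phylogeny":
        return Phylogeny(
            dendropy.Tree.get(
                data=self._tree.as_string(schema="newick"),
                schema="newick",
                preserve_underscores=True,
            )
        )

    # -- editing ----------------------------------------------------------

    def prune_to_taxa(self, keep) -> "Phylogeny":
        """Prune to a subset of tips, preserving all patristic distances.

        Degree-two internal nodes created by pruning are suppressed with
        their branch lengths summed; a degree-one root is collapsed into
        the stem edge so root-to-tip depths are unchanged.
        """
        keep = set(keep)
        unknown = keep - set(self.tips)
        if unknown:
            raise PhyloError(f"unknown taxa: {sorted(unknown)}")
        if len(keep) < 2:
            raise PhyloError("need at least 2 tips after pruning")
        t = self.copy()._tree
        while True:
            drop = [
                lf
                for lf in t.leaf_node_iter()
                if lf.taxon is None or lf.taxon.label not in keep
            ]
            if not drop:
                break
            for lf in drop:
                lf.parent_node.remove_child(lf)
        # collapse degree-one root(s) into the stem edge
        while len(t.seed_node.child_nodes()) == 1:
            child = t.seed_node.child_nodes()[0]
            child.edge.length = (child.edge.length or 0.0) + (
                t.seed_node.edge.length or 0.0
            )
            child.parent_node = None
            t.seed_node = child
        t.suppress_unifurcations()
        return Phylogeny(t)

    def graft_tip(
        self,
        new_label: str,
        attach_edge: str,
        attach_age: float,
        tip_age: float = 0.0,
    ) -> "Phylogeny":
        """Attach a new (typically fossil) tip onto an existing edge.

        Parameters
        ----------
        new_label : str
            Label of the new tip; must not already be present.
        attach_edge : str
            Label of the node *below* the edge to attach to (a tip label,
            or an internal node label if the tree has them).
        attach_age : float
            Age before present (most recent tip) of the attachment point;
            must lie within the age span of the chosen edge.
        tip_age : float
            Age of the new tip (0 for extant); the implied new branch
            length ``attach_age - tip_age`` must be non-negative.
        """
        if new_label in self.tips:
            raise PhyloError(f"tip {new_label!r} already present")
        if tip_age < 0:
            raise PhyloError("tip_age must be >= 0")
        if attach_age - tip_age < 0:
            raise PhyloError(
                f"negative implied branch length: tip_age {tip_age} above "
                f"attachment age {attach_age}"
            )
        out = self.copy()
        t = out._tree
        depths = out._depths()
        h = max(depths[lf] for lf in t.leaf_node_iter())

        target = None
        for node in t.preorder_node_iter():
            label = node.taxon.label if node.taxon else None
            if label == attach_edge:
                target = node
                break
        if target is None:
            raise PhyloError(f"no node labelled {attach_edge!r}")
        if target is t.seed_node:
            raise PhyloError("cannot attach above the root")

        child_age = h - depths[target]
        parent_age = h - depths[target.parent_node]
        if not (child_age <= attach_age <= parent_age):
            raise PhyloError(
                f"attachment age {attach_age} outside edge span "
                f"[{child_age:.6g}, {parent_age:.6g}]"
            )

        parent = target.parent_node
        mid = dendropy.Node()
        mid.edge.length = parent_age - attach_age
        parent.remove_child(target)
        parent.add_child(mid)
        target.edge.length = attach_age - child_age
        mid.add_child(target)

        taxon = t.taxon_namespace.new_taxon(label=new_label)
        tip = dendropy.Node(taxon=taxon)
        tip.edge.length = attach_age - tip_age
        mid.add_child(tip)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # grafts at tip_age == attach_age
            return Phylogeny(t)

    # -- covariance -------------------------------------------------------

    def vcv(self, order=None) -> PhyloCov:
        """Brownian-motion variance-covariance matrix among tips.

        ``C[i, j]`` is the depth of the MRCA of tips i and j; the diagonal
        holds root-to-tip path lengths.  ``order`` fixes the row order
        (default: tree traversal order of the tips).
        """
        tips = self.tips
        if len(tips) < 2:
            raise PhyloError("need at least 2 tips for a covariance matrix")
        if order is None:
            order = tips
        else:
            order = list(order)
            if set(order) != set(tips) or len(order) != len(tips):
                raise PhyloError("order must be a permutation of the tip labels")
        idx = {t: i for i, t in enumerate(order)}
        n = len(order)
        C = np.zeros((n, n))
        depths = self._depths()

        # postorder: collect tip indices per subtree, filling cross-pairs at
        # each internal node with that node's depth
        tipsets = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                i = idx[node.taxon.label]
                C[i, i] = depths[node]
                tipsets[node] = [i]
            else:
                groups = [tipsets.pop(c) for c in node.child_nodes()]
                d = depths[node]
                for gi in range(len(groups)):
                    for gj in range(gi + 1, len(groups)):
                        for a in groups[gi]:
                            for b in groups[gj]:
                                C[a, b] = C[b, a] = d
                tipsets[node] = [i for g in groups for i in g]
        return PhyloCov(tuple(order), C, lam=None)


# -- module-level functional API ------------------------------------------


def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`."""
    return Phylogeny.from_newick(text)


def prune_to_taxa(tree: Phylogeny, keep) -> Phylogeny:
    return tree.prune_to_taxa(keep)


def graft_tip(
    tree: Phylogeny,
    new_label: str,
    attach_edge: str,
    attach_age: float,
    tip_age: float = 0.0,
) -> Phylogeny:
    return tree.graft_tip(new_label, attach_edge, attach_age, tip_age)


def vcv_matrix(tree: Phylogeny, order=None) -> PhyloCov:
    return tree.vcv(order=order)


def lambda_transform(C: PhyloCov, lam: float) -> PhyloCov:
    """Apply Pagel's lambda: multiply off-diagonal entries by ``lam``.

    The diagonal (tip variances) is left unchanged; lambda = 1 is the
    identity and lambda = 0 removes all phylogenetic covariance.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    M = C.matrix
    out = lam * M + (1.0 - lam) * np.diag(np.diag(M))
    return PhyloCov(C.taxa, out, lam=lam)
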
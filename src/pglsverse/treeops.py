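"""Phylogeny handling: Newick input, validation, pruning, and the
Brownian-motion variance-covariance structure that PGLS regression needs.

A rooted tree with branch lengths implies a covariance matrix among tip
trait values under Brownian motion: the covariance of two tips is the
shared branch length from the root down to their most recent common
ancestor, and each tip's variance is its root-to-tip distance.  Pagel's
lambda rescales the off-diagonal (shared) part of that matrix, giving a
one-parameter bridge between full Brownian structure (lambda = 1) and
phylogenetic independence (lambda = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "TreeError",
    "Phylogeny",
    "VCVMatrix",
    "normalize_label",
    "read_newick",
    "vcv",
    "lambda_transform",
    "prune_and_match",
]


class TreeError(ValueError):
    """Raised for malformed or invalid phylogenies."""


def normalize_label(label: str) -> str:
    """Normalize a taxon label: strip surrounding quotes and whitespace,
    treat internal spaces and underscores as equivalent (canonical form
    uses underscores).  Case is preserved."""
    s = str(label).strip()
    if len(s) >= 2 and s[0] == s[-1] and s[0] in ("'", '"'):
        s = s[1:-1]
    return s.strip().replace(" ", "_")


@dataclass
class VCVMatrix:
    """Among-species covariance implied by shared branch lengths.

    ``values[i, j]`` is the root-to-MRCA path length of taxa i and j;
    the diagonal holds root-to-tip distances.
    """

    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise TreeError(
                f"VCV shape {self.values.shape} does not match {n} taxa"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise TreeError("VCV matrix is not symmetric")

    def index(self, taxa: list[str]) -> np.ndarray:
        pos = {t: i for i, t in enumerate(self.taxa)}
        missing = [t for t in taxa if t not in pos]
        if missing:
            raise TreeError(f"taxa not in VCV: {missing}")
        return np.array([pos[t] for t in taxa], dtype=int)

    def reorder(self, taxa: list[str]) -> "VCVMatrix":
        idx = self.index(taxa)
        return VCVMatrix(list(taxa), self.values[np.ix_(idx, idx)])


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths and unique, normalized tip labels.

    Thin wrapper over a :class:`dendropy.Tree`; all label access goes
    through :func:`normalize_label` so tips can be matched against trait
    tables whose species names use spaces instead of underscores.
    """

    tree: dendropy.Tree
    _tips: list[str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        leaves = list(self.tree.leaf_node_iter())
        if len(leaves) < 2:
            raise TreeError("tree must have at least 2 tips")
        labels = [normalize_label(lf.taxon.label) for lf in leaves]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate tip labels after normalization: {dupes}")
        for node in self.tree.preorder_node_iter():
            if node is self.tree.seed_node:
                if node.edge.length is None:
                    node.edge.length = 0.0
                continue
            bl = node.edge.length
            if bl is None:
                raise TreeError(
                    "edge without branch length leading to "
                    f"{self._describe_node(node)!r}; branch lengths are required"
                )
            if not np.isfinite(bl) or bl < 0:
                raise TreeError(
                    f"non-finite or negative branch length {bl} at "
                    f"{self._describe_node(node)!r}"
                )
        self._tips = labels
        depths = self.root_to_tip_distances()
        zero = [t for t, d in zip(labels, depths) if d <= 0]
        if zero:
            raise TreeError(
                f"tips with zero root-to-tip distance (degenerate variance): {zero}"
            )

    @staticmethod
    def _describe_node(node: dendropy.Node) -> str:
        if node.taxon is not None:
            return normalize_label(node.taxon.label)
        tips = [normalize_label(l.taxon.label) for l in node.leaf_iter()]
        return "ancestor of " + ",".join(sorted(tips)[:3])

    # ------------------------------------------------------------------
    @property
    def tips(self) -> list[str]:
        return list(self._tips)

    @property
    def n_tips(self) -> int:
        return len(self._tips)

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        return read_newick(text)

    def to_newick(self) -> str:
        s = self.tree.as_string(schema="newick", suppress_rooting=True,
                                unquoted_underscores=True)
        return s.strip()

    def root_to_tip_distances(self) -> np.ndarray:
        out = []
        for lf in self.tree.leaf_node_iter():
            d, node = 0.0, lf
            while node is not self.tree.seed_node:
                d += node.edge.length
                node = node.parent_node
            out.append(d)
        return np.asarray(out, dtype=float)

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        d = self.root_to_tip_distances()
        return bool(np.allclose(d, d[0], rtol=rtol))

    def vcv(self) -> VCVMatrix:
        return vcv(self)

    def prune(self, taxa) -> "Phylogeny":
        return prune_and_match(self, taxa)


# ----------------------------------------------------------------------
def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a validated :class:`Phylogeny`.

    Branch lengths are mandatory on every non-root edge; a missing length
    is an explicit error rather than a silent zero.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse-error types
        raise TreeError(f"malformed Newick string: {exc}") from exc
    return Phylogeny(tree)


def vcv(tree: Phylogeny) -> VCVMatrix:
    """Brownian-motion covariance: entry (i, j) is the total branch length
    from the root to MRCA(i, j); the diagonal holds root-to-tip distances.

    Computed in one postorder sweep: each internal node of depth d sets
    V[i, j] = d for every tip pair (i, j) split between its child subtrees.
    """
    dtree = tree.tree
    tip_index: dict[int, int] = {}
    labels: list[str] = []
    for lf in dtree.leaf_node_iter():
        tip_index[id(lf)] = len(labels)
        labels.append(normalize_label(lf.taxon.label))
    n = len(labels)
    V = np.zeros((n, n), dtype=float)

    depth: dict[int, float] = {id(dtree.seed_node): 0.0}
    for node in dtree.preorder_node_iter():
        if node is dtree.seed_node:
            continue
        depth[id(node)] = depth[id(node.parent_node)] + node.edge.length

    below: dict[int, list[int]] = {}
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            i = tip_index[id(node)]
            below[id(node)] = [i]
            V[i, i] = depth[id(node)]
            continue
        children = [below[id(c)] for c in node.child_nodes()]
        d = depth[id(node)]
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                for i in children[a]:
                    V[i, children[b]] = d
                    V[np.asarray(children[b]), i] = d
        below[id(node)] = [i for ch in children for i in ch]
    return VCVMatrix(labels, V)


def lambda_transform(V: VCVMatrix, lam: float) -> VCVMatrix:
    """Pagel's lambda transform: scale off-diagonal covariances by ``lam``,
    leaving tip variances untouched.  ``lam`` must lie in [0, 1]; values
    above 1 can destroy positive semidefiniteness and are rejected."""
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    W = V.values * lam
    np.fill_diagonal(W, np.diag(V.values))
    return VCVMatrix(list(V.taxa), W)


def prune_and_match(tree: Phylogeny, taxa) -> Phylogeny:
    """Induced subtree on ``taxa`` with path lengths preserved (unifurcations
    collapsed, their edge lengths summed).  Taxa may use spaces or
    underscores; missing taxa raise an error listing them."""
    wanted = [normalize_label(t) for t in taxa]
    if len(set(wanted)) != len(wanted):
        raise TreeError("duplicate taxa in prune request")
    have = set(tree.tips)
    missing = sorted(set(wanted) - have)
    if missing:
        raise TreeError(f"taxa not in tree: {missing}")
    clone = dendropy.Tree(tree.tree)
    keep = [
        t for t in clone.taxon_namespace
        if normalize_label(t.label) in set(wanted)
    ]
    drop = [t for t in clone.taxon_namespace if t not in set(keep)]
    if drop:
        clone.prune_taxa(drop, suppress_unifurcations=False)
    _collapse_unifurcations(clone)
    clone.taxon_namespace = dendropy.TaxonNamespace(keep)
    return Phylogeny(clone)


def _collapse_unifurcations(tree: dendropy.Tree) -> None:
    """Remove degree-2 nodes while preserving every root-to-tip path
    length.  The root is kept in place even if it ends up with a single
    child lineage, so distances from the original root survive pruning."""
    root = tree.seed_node
    for node in list(tree.postorder_node_iter()):
        if node is root or node.is_leaf():
            continue
        children = node.child_nodes()
        if len(children) == 1:
            child = children[0]
            child.edge.length = (child.edge.length or 0.0) + (node.edge.length or 0.0)
            parent = node.parent_node
            parent.remove_child(node)
            parent.add_child(child)
    # A root left with a single child keeps that stem edge: it carries
    # the basal path length shared by every remaining tip, so both the
    # root-to-tip distances and the shared covariances survive pruning.
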
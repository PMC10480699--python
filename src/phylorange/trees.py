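"""Rooted phylogenies and the Brownian-motion covariance structure they imply.

Every model in this package works from a phylogenetic variance-covariance
(VCV) matrix: ``C[i, j]`` is the branch length shared by the root-to-tip
paths of species *i* and *j*, which under Brownian trait evolution is the
covariance (up to a rate constant) between their trait values.  Pagel's
lambda rescales the off-diagonal entries of ``C`` to interpolate between a
star phylogeny (lambda = 0, no phylogenetic signal) and the full Brownian
structure (lambda = 1).

Newick I/O and taxon pruning are delegated to :mod:`dendropy`; this module
adds strict validation (branch lengths required on every non-root edge),
tip-label canonicalisation so that trees and trait tables with different
naming conventions can be matched, and the VCV / lambda machinery.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "VCVMatrix",
    "canonical_label",
    "parse_newick",
    "read_tree",
    "read_treeblock",
    "to_vcv",
    "lambda_transform",
    "prune_to_taxa",
]

_ULTRAMETRIC_RTOL = 1e-8


def canonical_label(label: str) -> str:
    """Canonical form of a species label.

    Case-insensitive; spaces and underscores interchangeable; internal
    whitespace collapsed.  Trees and trait tables frequently disagree on
    these conventions (``Ursus_maritimus`` vs ``ursus maritimus``), so all
    tip/species matching in the package goes through this function.
    """
    return re.sub(r"\s+", " ", label.replace("_", " ").strip()).lower()


class NewickError(ValueError):
    """Raised for malformed Newick input or missing branch lengths."""


@dataclass(frozen=True)
class VCVMatrix:
    """Phylogenetic variance-covariance matrix with its taxon order."""

    taxa: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("VCV matrix must be square")
        if m.shape[0] != len(self.taxa):
            raise ValueError("taxon count does not match matrix dimension")
        object.__setattr__(self, "matrix", m)

    @property
    def n(self) -> int:
        return len(self.taxa)

    def submatrix(self, taxa: Sequence[str]) -> "VCVMatrix":
        """Restrict to ``taxa`` (canonical matching), preserving their order."""
        lookup = {canonical_label(t): i for i, t in enumerate(self.taxa)}
        try:
            idx = [lookup[canonical_label(t)] for t in taxa]
        except KeyError as exc:
            raise KeyError(f"taxon not present in VCV: {exc.args[0]!r}") from None
        return VCVMatrix(tuple(self.taxa[i] for i in idx), self.matrix[np.ix_(idx, idx)])


class PhyloTree:
    """A rooted tree with branch lengths, wrapping a :class:`dendropy.Tree`.

    Tip labels are unique (after canonicalisation) and every non-root edge
    carries a nonnegative branch length; both are enforced at construction.
    """

    def __init__(self, dtree: dendropy.Tree):
        self._tree = dtree
        self._validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several error classes
            raise NewickError(f"malformed Newick string: {exc}") from exc
        return cls(dtree)

    def _validate(self) -> None:
        labels = [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]
        canon = [canonical_label(x) for x in labels]
        if len(set(canon)) != len(canon):
            dupes = sorted({c for c in canon if canon.count(c) > 1})
            raise NewickError(f"duplicate tip labels: {dupes}")
        root = self._tree.seed_node
        for node in self._tree.preorder_node_iter():
            if node is root:
                continue
            if node.edge.length is None:
                where = node.taxon.label if node.taxon else "an internal node"
                raise NewickError(
                    f"missing branch length on the edge above {where}; "
                    "all non-root edges must carry a length"
                )
            if node.edge.length < 0:
                raise NewickError("negative branch length encountered")

    # -- basic queries -------------------------------------------------

    @property
    def tip_names(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    def __len__(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    def _node_depths(self) -> dict:
        """Root-to-node distances.

        A length on the root edge is treated as a stem shared by every tip
        (it arises when pruning to a clade below the original root) and is
        included in all depths.
        """
        depth = {}
        for node in self._tree.preorder_node_iter():
            parent = node.parent_node
            if parent is None:
                depth[node] = node.edge.length or 0.0
            else:
                depth[node] = depth[parent] + node.edge.length
        return depth

    def tip_depths(self) -> dict[str, float]:
        depth = self._node_depths()
        return {n.taxon.label: depth[n] for n in self._tree.leaf_node_iter()}

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        d = np.array(list(self.tip_depths().values()))
        return bool(np.ptp(d) <= rtol * max(d.mean(), np.finfo(float).tiny))

    # -- I/O -----------------------------------------------------------

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        )
        return s.strip()

    # -- transforms ----------------------------------------------------

    def scaled(self, factor: float) -> "PhyloTree":
        """Return a copy with every branch length multiplied by ``factor``."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        clone = self._tree.clone(depth=1)
        for edge in clone.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length * factor
        return PhyloTree(clone)


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree` (strict validation)."""
    return PhyloTree.from_newick(text)


def read_tree(path: str | Path) -> PhyloTree:
    return parse_newick(Path(path).read_text())


def read_treeblock(path: str | Path) -> list[PhyloTree]:
    """Read a directory of ``*.nwk`` files in lexicographic order.

    A treeblock is a set of alternative plausible phylogenies used to check
    robustness of model results to phylogenetic uncertainty.
    """
    files = sorted(Path(path).glob("*.nwk"))
    if not files:
        raise FileNotFoundError(f"no *.nwk files found in {path}")
    return [read_tree(f) for f in files]


def to_vcv(tree: PhyloTree) -> VCVMatrix:
    """Brownian-motion VCV: shared root-to-tip path length for each tip pair.

    ``C[i, i]`` is the root-to-tip distance of tip *i*; ``C[i, j]`` is the
    depth of the most recent common ancestor of *i* and *j*.  Warns (but
    proceeds) if the tree is not ultrametric.
    """
    dtree = tree._tree
    leaves = list(dtree.leaf_node_iter())
    index = {leaf: i for i, leaf in enumerate(leaves)}
    depth = tree._node_depths()

    n = len(leaves)
    C = np.zeros((n, n))
    tipsets: dict = {}
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            i = index[node]
            C[i, i] = depth[node]
            tipsets[node] = [i]
        else:
            child_sets = [tipsets.pop(ch) for ch in node.child_nodes()]
            for a in range(len(child_sets)):
                for b in range(a + 1, len(child_sets)):
                    for i in child_sets[a]:
                        for j in child_sets[b]:
                            C[i, j] = C[j, i] = depth[node]
            tipsets[node] = [i for s in child_sets for i in s]

    vcv = VCVMatrix(tuple(l.taxon.label for l in leaves), C)
    diag = np.diag(C)
    if np.ptp(diag) > 1e-6 * max(diag.mean(), np.finfo(float).tiny):
        warnings.warn(
            "tree is not ultrametric; PGLS remains defined but tip variances differ",
            stacklevel=2,
        )
    return vcv


def lambda_transform(vcv: VCVMatrix, lam: float) -> VCVMatrix:
    """Pagel's lambda scaling: multiply off-diagonal covariances by ``lam``.

    ``lam`` = 1 leaves the Brownian structure untouched; ``lam`` = 0 yields
    the star-phylogeny limit (a diagonal matrix of tip depths).  The result
    is a convex combination of PSD matrices, hence still PSD.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    C = vcv.matrix
    out = lam * C + (1.0 - lam) * np.diag(np.diag(C))
    return VCVMatrix(vcv.taxa, out)


def prune_to_taxa(tree: PhyloTree, keep: Iterable[str]) -> PhyloTree:
    """Prune the tree to exactly the tips in ``keep`` (canonical matching).

    Root-to-tip distances of retained tips are preserved: suppressed
    degree-2 nodes have their flanking branch lengths summed.
    """
    keep = list(keep)
    if not keep:
        raise ValueError("keep must be a nonempty set of tip labels")
    canon_to_actual = {canonical_label(t): t for t in tree.tip_names}
    missing = [k for k in keep if canonical_label(k) not in canon_to_actual]
    if missing:
        raise KeyError(f"labels not found in tree: {missing}")
    labels = [canon_to_actual[canonical_label(k)] for k in keep]

    before = tree.tip_depths()
    sub = tree._tree.extract_tree_with_taxa_labels(
        labels, suppress_unifurcations=True
    )
    pruned = PhyloTree(sub)
    # dendropy drops the stem above the new root; restore original depths by
    # construction check (the stem is shared by all retained tips, so adding
    # it back to the children of the root preserves relative structure).
    after = pruned.tip_depths()
    some = pruned.tip_names[0]
    deficit = before[some] - after[some]
    if deficit > 1e-12:
        seed = pruned._tree.seed_node
        seed.edge.length = (seed.edge.length or 0.0) + deficit
    return pruned
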
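"""Rooted phylogenies, phylogenetic covariance matrices and branch-length transforms.

A :class:`Phylogeny` is a rooted tree with branch lengths in (relative) time
units and species codes at the tips.  All comparative machinery in this
package is driven by the tip-by-tip phylogenetic covariance matrix ``C`` with
``C[i, j]`` the shared path length from the root to the most recent common
ancestor of tips *i* and *j* (so ``C[i, i]`` is the root-to-tip distance).
The candidate trait-evolution models (Pagel's lambda and delta, early burst,
Ornstein-Uhlenbeck) are expressed as transforms of ``C``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "PhyloCovariance",
    "phylo_vcv",
    "cophenetic_distances",
    "transform_covariance",
    "prune_to_taxa",
    "node_depths",
    "TreeError",
]


class TreeError(ValueError):
    """Raised for malformed trees (duplicate tips, missing branch lengths...)."""


@dataclass
class Phylogeny:
    """Rooted tree stored as parent/length arrays in preorder.

    Parameters
    ----------
    parent : ndarray of int
        ``parent[i]`` is the index of node *i*'s parent; the root has -1.
        Nodes must be topologically ordered (every parent before its child);
        node 0 is the root.
    lengths : ndarray of float
        Branch length of the edge above each node; the root entry is 0 (or a
        root-edge length, which is ignored by all computations).
    labels : list of str or None
        Node labels; every tip (childless node) must carry a unique label.
    """

    parent: np.ndarray
    lengths: np.ndarray
    labels: list

    # derived, filled in __post_init__
    children: list = field(init=False, repr=False)
    tip_indices: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=int)
        self.lengths = np.asarray(self.lengths, dtype=float)
        n = len(self.parent)
        if not (len(self.lengths) == n and len(self.labels) == n):
            raise TreeError("parent/lengths/labels length mismatch")
        if self.parent[0] != -1 or np.any(self.parent[1:] < 0):
            raise TreeError("node 0 must be the root; all others need a parent")
        if np.any(self.parent[1:] >= np.arange(1, n)):
            raise TreeError("nodes must be in topological (preorder) order")
        self.children = [[] for _ in range(n)]
        for i in range(1, n):
            self.children[self.parent[i]].append(i)
        self.tip_indices = np.array(
            [i for i in range(n) if not self.children[i]], dtype=int
        )
        tips = [self.labels[i] for i in self.tip_indices]
        if any(t is None or t == "" for t in tips):
            raise TreeError("every tip must be labeled")
        if len(set(tips)) != len(tips):
            dup = sorted({t for t in tips if tips.count(t) > 1})
            raise TreeError(f"duplicate tip labels: {dup}")
        if np.any(~np.isfinite(self.lengths[1:])):
            raise TreeError("missing or non-finite branch length on a non-root edge")
        if np.any(self.lengths[1:] < 0):
            raise TreeError("negative branch length")

    # ------------------------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.tip_indices)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def tip_labels(self) -> list:
        return [self.labels[i] for i in self.tip_indices]

    def depths(self, relative: bool = False) -> np.ndarray:
        """Root-to-node path lengths; optionally divided by the max tip depth."""
        d = np.zeros(self.n_nodes)
        for i in range(1, self.n_nodes):
            d[i] = d[self.parent[i]] + self.lengths[i]
        if relative:
            d = d / d[self.tip_indices].max()
        return d

    @property
    def height(self) -> float:
        return float(self.depths()[self.tip_indices].max())

    def is_ultrametric(self, tol: float = 1e-8) -> bool:
        td = self.depths()[self.tip_indices]
        return bool(np.ptp(td) <= tol * max(td.max(), 1.0))

    def descendant_tip_masks(self) -> np.ndarray:
        """Boolean (n_nodes, n_tips) matrix: tips descending from each node."""
        n, nt = self.n_nodes, self.n_tips
        tip_pos = {node: j for j, node in enumerate(self.tip_indices)}
        M = np.zeros((n, nt), dtype=bool)
        for i in range(n - 1, -1, -1):
            if not self.children[i]:
                M[i, tip_pos[i]] = True
            else:
                for c in self.children[i]:
                    M[i] |= M[c]
        return M

    # ------------------------------------------------------------------
    @classmethod
    def from_dendropy(cls, dtree: "dendropy.Tree") -> "Phylogeny":
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.empty(len(nodes), dtype=int)
        lengths = np.zeros(len(nodes))
        labels: list = []
        for i, nd in enumerate(nodes):
            parent[i] = -1 if nd.parent_node is None else index[id(nd.parent_node)]
            if nd.parent_node is not None:
                if nd.edge.length is None:
                    raise TreeError("missing branch length on a non-root edge")
                lengths[i] = nd.edge.length
            else:
                lengths[i] = nd.edge.length or 0.0
            if nd.taxon is not None:
                labels.append(nd.taxon.label)
            else:
                labels.append(nd.label)
        return cls(parent, lengths, labels)

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        if text.count("(") != text.count(")"):
            raise TreeError("unbalanced parentheses in newick string")
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises assorted DataError types
            raise TreeError(f"cannot parse newick: {exc}") from exc
        return cls.from_dendropy(dtree)

    def to_newick(self) -> str:
        def render(i: int) -> str:
            if not self.children[i]:
                s = self.labels[i]
            else:
                s = "(" + ",".join(render(c) for c in self.children[i]) + ")"
                if self.labels[i]:
                    s += str(self.labels[i])
            if i != 0:
                s += f":{self.lengths[i]:.12g}"
            return s

        return render(0) + ";"

    # convenience used throughout the comparative modules -------------
    def vcv(self) -> "PhyloCovariance":
        return phylo_vcv(self)


@dataclass
class PhyloCovariance:
    """Tip-by-tip shared-path-length matrix of a rooted phylogeny."""

    C: np.ndarray
    tip_order: list
    T: float  # maximum root-to-tip depth

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=float)


def phylo_vcv(tree: Phylogeny) -> PhyloCovariance:
    """Phylogenetic covariance ``C`` (shared path lengths) of a rooted tree."""
    masks = tree.descendant_tip_masks().astype(float)
    # every non-root edge contributes its length to all tip pairs below it
    w = tree.lengths.copy()
    w[0] = 0.0
    C = (masks * w[:, None]).T @ masks
    C = 0.5 * (C + C.T)
    return PhyloCovariance(C=C, tip_order=tree.tip_labels, T=float(np.diag(C).max()))


def cophenetic_distances(tree: Phylogeny) -> tuple[np.ndarray, list]:
    """Patristic (path-length) distances between all tip pairs."""
    vcv = phylo_vcv(tree)
    d = np.diag(vcv.C)
    D = d[:, None] + d[None, :] - 2.0 * vcv.C
    np.fill_diagonal(D, 0.0)
    return D, vcv.tip_order


def node_depths(tree: Phylogeny, relative: bool = False) -> np.ndarray:
    return tree.depths(relative=relative)


# ----------------------------------------------------------------------
# model transforms of the phylogenetic covariance
# ----------------------------------------------------------------------

#: parameter bounds per transform; EB bounds are per unit tree height and are
#: scaled by 1/T at call time.  Positive EB rate change (acceleration) is
#: deliberately allowed.
PARAM_BOUNDS = {
    "lambda": (0.0, 1.0),
    "delta": (1e-5, 100.0),
    "EB": (-20.0, 20.0),  # divided by T
    "OU": (1e-8, 500.0),
}


def transform_covariance(C: np.ndarray, model: str, param: float) -> np.ndarray:
    """Transform a phylogenetic covariance under a named evolutionary model.

    lambda  -- multiply off-diagonal elements by ``param`` (0 = star tree,
               1 = Brownian motion).
    delta   -- raise each element to the power ``param`` and rescale so the
               maximum diagonal equals the original tree height (delta > 1
               concentrates change towards the tips).
    EB      -- early burst / ACDC: ``(exp(a*C) - 1)/a`` with rate-change
               ``a``; the a -> 0 limit is ``C``.
    OU      -- stationary Ornstein-Uhlenbeck covariance on the depth matrix,
               ``exp(-2*alpha*(T - C)) * (1 - exp(-2*alpha*C)) / (2*alpha)``.
    """
    C = np.asarray(C, dtype=float)
    T = float(np.diag(C).max())
    lo, hi = PARAM_BOUNDS[model] if model != "EB" else tuple(
        b / T for b in PARAM_BOUNDS["EB"]
    )
    if not (lo <= param <= hi):
        raise ValueError(f"{model} parameter {param} outside [{lo:g}, {hi:g}]")
    if model == "lambda":
        V = C * param
        np.fill_diagonal(V, np.diag(C))
        return V
    if model == "delta":
        V = C**param
        return V * (T / np.diag(V).max())
    if model == "EB":
        if abs(param) < 1e-12:
            return C.copy()
        return (np.exp(param * C) - 1.0) / param
    if model == "OU":
        a = param
        return np.exp(-2.0 * a * (T - C)) * (1.0 - np.exp(-2.0 * a * C)) / (2.0 * a)
    raise ValueError(f"unknown model transform {model!r}")


def prune_to_taxa(tree: Phylogeny, labels) -> Phylogeny:
    """Induced subtree on ``labels``; degree-2 nodes are collapsed additively."""
    labels = list(labels)
    missing = set(labels) - set(tree.tip_labels)
    if missing:
        raise TreeError(f"labels not in tree: {sorted(missing)}")
    dtree = dendropy.Tree.get(
        data=tree.to_newick(), schema="newick", preserve_underscores=True
    )
    dtree.retain_taxa_with_labels(labels)
    # a leftover root edge from pruning must not inflate depths; keep it, the
    # covariance code ignores the root entry anyway
    return Phylogeny.from_dendropy(dtree)
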
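"""Phylogeny-induced correlation structures among OTUs.

Under a trait-evolution model with evolutionary-rate parameter ``alpha``, the
correlation between a trait carried by two OTUs separated by patristic distance
``d`` decays as ``exp(-2 * alpha * d)``.  At ``alpha = 0`` every pair is
perfectly correlated (no evolution: one shared trait); as ``alpha -> inf`` the
traits evolve independently and the correlation matrix tends to the identity.

The inverse of this correlation matrix, ``Omega = C^{-1}``, defines a graph
among OTUs whose edge weights decay much faster with patristic distance than
those of the graph Laplacian built from the same correlations.  Penalizing
``beta' Omega beta`` therefore smooths regression coefficients mainly between
*phylogenetically close* OTUs (local smoothing), while retaining a weighted
ridge component that provides data-driven smoothing.  This module builds the
pieces: patristic distances, the correlation matrix, its (ridge-stabilized)
inverse, and the Laplacian comparator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PatristicDistanceMatrix",
    "CorrelationStructure",
    "LaplacianStructure",
    "patristic_distances",
    "correlation_matrix",
    "inverse_correlation",
    "build_laplacian",
]

#: Ridge values tried, in order, when inverting a (possibly singular)
#: correlation matrix.  The first value whose solve has max residual below
#: 1e-6 is accepted and recorded.
RIDGE_LADDER = (0.0, 1e-8, 1e-6, 1e-4)

_RESIDUAL_TOL = 1e-6


@dataclass
class PatristicDistanceMatrix:
    """Symmetric matrix of leaf-to-leaf path lengths on a phylogenetic tree.

    Parameters
    ----------
    labels : list of str
        OTU identifiers, in the order of the rows/columns of ``D``.
    D : ndarray of shape (p, p)
        Nonnegative symmetric matrix with zero diagonal, in branch-length
        units.  May also be a user-supplied genetic distance matrix; no tree
        is required.
    """

    labels: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        p = len(self.labels)
        if self.D.shape != (p, p):
            raise ValueError(
                f"distance matrix shape {self.D.shape} does not match "
                f"{p} labels"
            )
        if len(set(self.labels)) != p:
            raise ValueError("duplicate OTU labels in distance matrix")
        if not np.allclose(self.D, self.D.T, atol=1e-10):
            raise ValueError("distance matrix is not symmetric")
        if np.any(self.D < 0):
            raise ValueError("distance matrix has negative entries")
        if np.any(np.abs(np.diag(self.D)) > 1e-12):
            raise ValueError("distance matrix diagonal is not zero")

    @property
    def p(self) -> int:
        return len(self.labels)

    def reorder(self, labels: list[str]) -> "PatristicDistanceMatrix":
        """Return a copy with rows/columns permuted to ``labels``.

        Every requested label must be present; missing or extra names are a
        hard error (no silent intersection).
        """
        index = {lab: i for i, lab in enumerate(self.labels)}
        missing = [lab for lab in labels if lab not in index]
        if missing:
            raise KeyError(f"labels not present in distance matrix: {missing}")
        if len(labels) != len(self.labels):
            extra = sorted(set(self.labels) - set(labels))
            raise KeyError(
                f"distance matrix has labels absent from the requested "
                f"order: {extra}"
            )
        idx = np.array([index[lab] for lab in labels])
        return PatristicDistanceMatrix(list(labels), self.D[np.ix_(idx, idx)])


@dataclass
class CorrelationStructure:
    """A phylogeny-induced correlation matrix and its stabilized inverse.

    ``(C + ridge_used * I) @ Omega = I`` holds within numerical tolerance.
    ``positive_offdiag`` counts off-diagonal entries of ``Omega`` that are
    positive beyond tolerance; for tree-derived correlation matrices these are
    expected to be absent, so violations are flagged (never clamped).
    """

    alpha: float
    C: np.ndarray
    Omega: np.ndarray
    ridge_used: float
    labels: list[str] | None = None
    positive_offdiag: int = 0


@dataclass
class LaplacianStructure:
    """Graph Laplacian built from a sparsified correlation adjacency."""

    adjacency: np.ndarray
    L: np.ndarray
    sparsity_level: float
    realized_sparsity: float = field(default=0.0)


def _leaf_label(leaf) -> str:
    if leaf.taxon is not None and leaf.taxon.label is not None:
        return leaf.taxon.label
    if getattr(leaf, "label", None):
        return leaf.label
    raise ValueError("tree has an unlabeled leaf")


def patristic_distances(tree, labels: list[str] | None = None) -> PatristicDistanceMatrix:
    """Compute all pairwise patristic distances between the leaves of a tree.

    Parameters
    ----------
    tree : dendropy.Tree
        Rooted or unrooted tree; every edge below the root must carry a
        nonnegative branch length.
    labels : list of str, optional
        Desired row/column order (e.g. the count-table row order).  Defaults
        to the tree's leaf order.  Unmatched names are a hard error.

    Returns
    -------
    PatristicDistanceMatrix
        ``D[i, j]`` is the sum of branch lengths on the unique path between
        leaves ``i`` and ``j``.
    """
    leaves = list(tree.leaf_node_iter())
    if len(leaves) < 2:
        raise ValueError("tree must have at least 2 leaves")
    leaf_labels = [_leaf_label(lf) for lf in leaves]
    if len(set(leaf_labels)) != len(leaf_labels):
        seen, dups = set(), set()
        for lab in leaf_labels:
            (dups if lab in seen else seen).add(lab)
        raise ValueError(f"duplicate leaf labels: {sorted(dups)}")

    # Distance from the root to every node; a missing edge length anywhere on
    # a root-to-leaf path is an error naming the offending edge.
    depth: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depth[id(node)] = 0.0
            continue
        elen = node.edge.length
        if elen is None:
            child = _leaf_label(node) if node.is_leaf() else "internal node"
            raise ValueError(f"missing branch length on edge above {child!r}")
        if elen < 0:
            raise ValueError(f"negative branch length: {elen}")
        depth[id(node)] = depth[id(node.parent_node)] + elen

    # d(u, v) = depth(u) + depth(v) - 2 * depth(MRCA(u, v)), computed by
    # accumulating pairwise contributions clade by clade in postorder.
    p = len(leaves)
    leaf_index = {id(lf): i for i, lf in enumerate(leaves)}
    D = np.zeros((p, p))
    below: dict[int, list[int]] = {}
    d = np.array([depth[id(lf)] for lf in leaves])
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = [leaf_index[id(node)]]
            continue
        children = [below.pop(id(ch)) for ch in node.child_nodes()]
        h = depth[id(node)]
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                ia = np.array(children[a])
                ib = np.array(children[b])
                D[np.ix_(ia, ib)] = d[ia][:, None] + d[ib][None, :] - 2.0 * h
        merged = [i for ch in children for i in ch]
        below[id(node)] = merged
    D = np.maximum(D, D.T)
    np.fill_diagonal(D, 0.0)

    pdm = PatristicDistanceMatrix(leaf_labels, D)
    if labels is not None:
        pdm = pdm.reorder(list(labels))
    return pdm


def correlation_matrix(D, alpha: float) -> np.ndarray:
    """Evaluate the phylogeny-induced correlation ``c_ij = exp(-2 alpha d_ij)``.

    ``D`` may be a :class:`PatristicDistanceMatrix` or a square array.
    """
    if alpha < 0:
        raise ValueError(f"alpha must be nonnegative, got {alpha}")
    Dm = D.D if isinstance(D, PatristicDistanceMatrix) else np.asarray(D, dtype=float)
    C = np.exp(-2.0 * alpha * Dm)
    np.fill_diagonal(C, 1.0)
    return C


def inverse_correlation(
    C: np.ndarray,
    alpha: float = np.nan,
    labels: list[str] | None = None,
    ridge_ladder=RIDGE_LADDER,
) -> CorrelationStructure:
    """Invert a correlation matrix with recorded ridge stabilization.

    The ridge ladder is tried in order; the first ``eps`` for which the solve
    of ``(C + eps I) Omega = I`` has max-norm residual below 1e-6 is accepted
    and recorded in ``ridge_used``.  At ``alpha = 0`` the correlation matrix
    is the all-ones (rank-1) matrix, so a positive ridge is unavoidable.

    Positive off-diagonal entries of ``Omega`` (unexpected for tree-derived
    correlations) are counted and flagged with a warning, never altered.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("C must be square")
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("C is not symmetric")
    p = C.shape[0]
    I = np.eye(p)
    last_err = None
    for eps in ridge_ladder:
        try:
            Omega = np.linalg.solve(C + eps * I, I)
        except np.linalg.LinAlgError as err:  # exactly singular
            last_err = err
            continue
        resid = np.max(np.abs((C + eps * I) @ Omega - I))
        if resid < _RESIDUAL_TOL:
            Omega = 0.5 * (Omega + Omega.T)
            off = Omega[~np.eye(p, dtype=bool)]
            n_pos = int(np.sum(off > 1e-10))
            if n_pos:
                warnings.warn(
                    f"{n_pos} off-diagonal entries of the inverse correlation "
                    "matrix are positive; the correlation matrix may not be "
                    "tree-derived or the ridge altered its sign pattern",
                    RuntimeWarning,
                    stacklevel=2,
                )
            return CorrelationStructure(
                alpha=alpha, C=C, Omega=Omega, ridge_used=eps,
                labels=labels, positive_offdiag=n_pos,
            )
    raise np.linalg.LinAlgError(
        f"correlation matrix could not be stably inverted even at the largest "
        f"ridge {ridge_ladder[-1]} (last error: {last_err})"
    )


def build_laplacian(C: np.ndarray, sparsity_level: float = 0.9,
                    normalized: bool = False) -> LaplacianStructure:
    """Build the graph Laplacian comparator from correlations.

    The adjacency is ``C`` with the diagonal zeroed and the smallest
    off-diagonal entries set to zero so that the requested fraction of
    off-diagonal entries is zero; symmetric pairs are kept or removed
    together, and entries tied at the threshold are all retained
    (conservative), so the realized sparsity can fall slightly short of the
    request and is reported.  ``L = Dg - A`` with ``Dg`` the degree diagonal
    (the unnormalized convention, the default); ``normalized=True`` gives the
    symmetric normalization ``I - Dg^{-1/2} A Dg^{-1/2}`` (isolated nodes
    get a zero row).
    """
    C = np.asarray(C, dtype=float)
    p = C.shape[0]
    if not (0 <= sparsity_level < 1):
        raise ValueError(f"sparsity_level must be in [0, 1), got {sparsity_level}")
    A = C.copy()
    np.fill_diagonal(A, 0.0)
    iu = np.triu_indices(p, 1)
    vals = A[iu]
    n_pairs = vals.size
    n_zero = int(np.floor(sparsity_level * n_pairs))
    if n_zero > 0:
        order = np.argsort(vals, kind="stable")
        # smallest value that survives; ties at the threshold all retained
        thresh = vals[order[min(n_zero, n_pairs - 1)]]
        kill = vals < thresh
        mask = np.zeros_like(A, dtype=bool)
        mask[iu[0][kill], iu[1][kill]] = True
        A[mask | mask.T] = 0.0
    realized = float(np.mean(A[iu] == 0.0))
    deg = A.sum(axis=1)
    if normalized:
        with np.errstate(divide="ignore"):
            dinv = np.where(deg > 0, 1.0 / np.sqrt(deg), 0.0)
        L = np.diag((deg > 0).astype(float)) - dinv[:, None] * A * dinv[None, :]
    else:
        L = np.diag(deg) - A
    return LaplacianStructure(
        adjacency=A, L=L, sparsity_level=sparsity_level, realized_sparsity=realized
    )
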
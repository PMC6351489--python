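"""Construction of the homogeneous networks, association views and
bi-colored matrices.

The lncRNA co-expression network W_l and the gene (PPI) network W_g are the
within-class blocks; each association view contributes a cross-class block
Y_i, giving per-view bi-colored adjacencies C_i = [[W_l, Y_i], [Y_i', W_g]].
Propagation baselines additionally need the symmetrically normalized
adjacency W_bar = D^{-1/2} W D^{-1/2} and Laplacian L = I - W_bar.
"""
from __future__ import annotations

import networkx as nx
import numpy as np

from .types import (
    BiColoredMatrix,
    BipartiteView,
    EntityNetwork,
    ExpressionMatrix,
    ValidationError,
)


def _pearson_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlations between two entities-by-samples blocks.

    Zero-variance rows correlate 0 with everything.
    """
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    sa = np.sqrt((Ac**2).sum(axis=1))
    sb = np.sqrt((Bc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (Ac @ Bc.T) / np.outer(sa, sb)
    R[~np.isfinite(R)] = 0.0
    return np.clip(R, -1.0, 1.0)


def build_coexpression_network(
    expr: ExpressionMatrix,
    threshold: float,
    use_absolute_correlation: bool = False,
) -> EntityNetwork:
    """Threshold pairwise Pearson correlations into a weighted network.

    Edge (i, j) carries weight r_ij when r_ij >= threshold (or |r_ij| when
    the absolute-correlation option is on); negative correlations are
    otherwise dropped because downstream factorization requires nonnegative
    adjacencies.
    """
    if len(expr.samples) < 2:
        raise ValidationError("co-expression needs >= 2 samples per entity")
    R = _pearson_rows(expr.values, expr.values)
    if use_absolute_correlation:
        R = np.abs(R)
    W = np.where(R >= threshold - 1e-12, R, 0.0)  # round-off guard at r = t
    np.fill_diagonal(W, 0.0)
    W = np.maximum(W, W.T)  # guard against asymmetric float round-off
    return EntityNetwork(ids=list(expr.ids), W=W)


def build_expression_view(
    expr_l: ExpressionMatrix,
    expr_g: ExpressionMatrix,
    threshold: float,
    use_absolute_correlation: bool = False,
) -> BipartiteView:
    """lncRNA-gene association view from cross Pearson correlation."""
    if expr_l.samples != expr_g.samples:
        raise ValidationError(
            "lncRNA and gene expression matrices must share the same samples "
            f"({len(expr_l.samples)} vs {len(expr_g.samples)})"
        )
    R = _pearson_rows(expr_l.values, expr_g.values)
    if use_absolute_correlation:
        R = np.abs(R)
    Y = np.where(R >= threshold - 1e-12, R, 0.0)
    return BipartiteView(
        name="expression", lnc_ids=list(expr_l.ids), gene_ids=list(expr_g.ids), Y=Y
    )


def jaccard(a: set, b: set) -> float:
    """|a ∩ b| / |a ∪ b|, with 0 for two empty sets (absence of evidence)."""
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def build_disease_view(
    lnc_diseases: dict[str, set[str]],
    gene_diseases: dict[str, set[str]],
    lnc_ids: list[str] | None = None,
    gene_ids: list[str] | None = None,
) -> BipartiteView:
    """lncRNA-gene association view from shared-disease Jaccard indices."""
    lnc_ids = list(lnc_diseases) if lnc_ids is None else list(lnc_ids)
    gene_ids = list(gene_diseases) if gene_ids is None else list(gene_ids)
    Y = np.zeros((len(lnc_ids), len(gene_ids)))
    for i, l in enumerate(lnc_ids):
        dl = lnc_diseases.get(l, set())
        for j, g in enumerate(gene_ids):
            Y[i, j] = jaccard(dl, gene_diseases.get(g, set()))
    return BipartiteView(name="disease", lnc_ids=lnc_ids, gene_ids=gene_ids, Y=Y)


def largest_connected_component(
    net: EntityNetwork,
) -> tuple[EntityNetwork, list[int]]:
    """Restrict a network to its largest connected component.

    Returns the induced sub-network plus the surviving original indices so
    that coupled matrices (views, annotations) can be subset consistently.
    Ties between equally large components are broken by the smallest
    first-entity index.
    """
    if net.n == 0:
        raise ValidationError("cannot take a component of an empty network")
    G = nx.from_numpy_array(net.W)
    components = [sorted(c) for c in nx.connected_components(G)]
    components.sort(key=lambda c: (-len(c), c[0]))
    keep = components[0]
    return net.subnetwork(keep), keep


def normalize_adjacency(net: EntityNetwork) -> np.ndarray:
    """Symmetric normalization W_bar = D^{-1/2} W D^{-1/2}.

    Isolated vertices (degree zero) keep zero rows/columns.
    """
    d = net.degrees()
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
    return inv_sqrt[:, None] * net.W * inv_sqrt[None, :]


def laplacian(net: EntityNetwork) -> np.ndarray:
    """Normalized Laplacian L = I - W_bar (positive semidefinite)."""
    return np.eye(net.n) - normalize_adjacency(net)


def assemble_bicolored(
    W_l: EntityNetwork, W_g: EntityNetwork, view: BipartiteView
) -> BiColoredMatrix:
    """Stack [[W_l, Y], [Y', W_g]] for one association view."""
    n_l, n_g = W_l.n, W_g.n
    if view.Y.shape != (n_l, n_g):
        raise ValidationError(
            f"view {view.name!r} has shape {view.Y.shape}, expected ({n_l},{n_g})"
        )
    C = np.zeros((n_l + n_g, n_l + n_g))
    C[:n_l, :n_l] = W_l.W
    C[n_l:, n_l:] = W_g.W
    C[:n_l, n_l:] = view.Y
    C[n_l:, :n_l] = view.Y.T
    return BiColoredMatrix(C=C, n_l=n_l, n_g=n_g)


def bicolored_network(C: BiColoredMatrix) -> EntityNetwork:
    """View a bi-colored matrix as a single network over both classes."""
    ids = [f"node{i}" for i in range(C.n_l + C.n_g)]
    W = C.C.copy()
    np.fill_diagonal(W, 0.0)
    return EntityNetwork(ids=ids, W=W)
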
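"""End-to-end glue: raw inputs -> networks, views, couplings -> model.

This is the order the method runs in: build the lncRNA co-expression
network and take the PPI's largest connected component, construct the
expression-correlation and shared-disease association views restricted to
the surviving genes, embed each view into a coupling matrix, and fit the
factorization on the joint annotation matrix.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .factorization import build_coupling, fit, predict_lncrna_scores
from .io import RunConfig
from .model_selection import EvalBundle
from .networks import (
    assemble_bicolored,
    build_coexpression_network,
    build_disease_view,
    build_expression_view,
    largest_connected_component,
)
from .synthetic import SyntheticInstance
from .types import (
    AnnotationMatrix,
    BiColoredMatrix,
    BipartiteView,
    CouplingMatrix,
    EntityNetwork,
    ExpressionMatrix,
    FactorModel,
)


@dataclass
class BuiltInputs:
    W_l: EntityNetwork
    W_g: EntityNetwork
    views: list[BipartiteView]
    couplings: list[CouplingMatrix]
    bicolored: list[BiColoredMatrix]
    X: AnnotationMatrix
    gene_keep: list[int]


def build_inputs(
    expr_l: ExpressionMatrix,
    expr_g: ExpressionMatrix,
    ppi: EntityNetwork,
    lnc_diseases: dict[str, set[str]],
    gene_diseases: dict[str, set[str]],
    annotations: AnnotationMatrix,
    config: RunConfig,
) -> BuiltInputs:
    """Construct all matrices downstream of raw inputs.

    Only the PPI network is filtered for connectivity; lncRNAs are never
    dropped. Views, gene expression and annotation columns are re-indexed
    to the surviving genes.
    """
    expr_values = expr_l, expr_g
    if config.log_transform_expression:
        expr_values = tuple(
            ExpressionMatrix(e.ids, e.samples, np.log1p(np.maximum(e.values, 0)))
            for e in expr_values
        )
    expr_l, expr_g = expr_values

    ppi_cc, keep = largest_connected_component(ppi)
    kept_genes = set(ppi_cc.ids)
    g_idx = [i for i, g in enumerate(expr_g.ids) if g in kept_genes]
    expr_g = ExpressionMatrix(
        ids=[expr_g.ids[i] for i in g_idx],
        samples=expr_g.samples,
        values=expr_g.values[g_idx],
    )
    # align PPI order to expression order of surviving genes
    order = [ppi_cc.ids.index(g) for g in expr_g.ids]
    ppi_cc = ppi_cc.subnetwork(order)

    W_l = build_coexpression_network(
        expr_l, config.coexpr_threshold, config.use_absolute_correlation
    )
    views = []
    for name in config.view_list:
        if name == "expression":
            views.append(
                build_expression_view(
                    expr_l, expr_g, config.coexpr_threshold,
                    config.use_absolute_correlation,
                )
            )
        elif name == "disease":
            views.append(
                build_disease_view(
                    lnc_diseases, gene_diseases, expr_l.ids, expr_g.ids
                )
            )
        else:
            raise ValueError(f"unknown view {name!r}")

    lnc_col = {e: i for i, e in enumerate(annotations.entity_ids[: annotations.n_l])}
    gene_col = {e: i for i, e in enumerate(annotations.entity_ids)}
    cols = [lnc_col[l] for l in expr_l.ids] + [gene_col[g] for g in expr_g.ids]
    X = AnnotationMatrix(
        term_ids=list(annotations.term_ids),
        entity_ids=list(expr_l.ids) + list(expr_g.ids),
        n_l=len(expr_l.ids),
        X=annotations.X[:, cols],
    )
    couplings = [build_coupling(v) for v in views]
    bicolored = [assemble_bicolored(W_l, ppi_cc, v) for v in views]
    return BuiltInputs(
        W_l=W_l,
        W_g=ppi_cc,
        views=views,
        couplings=couplings,
        bicolored=bicolored,
        X=X,
        gene_keep=keep,
    )


def build_from_instance(
    instance: SyntheticInstance, config: RunConfig
) -> BuiltInputs:
    return build_inputs(
        instance.expr_l,
        instance.expr_g,
        instance.ppi,
        instance.lnc_diseases,
        instance.gene_diseases,
        instance.train_X,
        config,
    )


def heldout_bundle(
    instance: SyntheticInstance, built: BuiltInputs, grid: list[float]
) -> EvalBundle:
    """Evaluation bundle over the masked (held-out) lncRNA annotations."""
    truth: dict[str, set[str]] = {}
    for term, lnc in instance.mask:
        truth.setdefault(lnc, set()).add(term)
    train_positive = {
        lnc: {
            built.X.term_ids[r]
            for r in np.nonzero(built.X.X[:, j])[0]
        }
        for j, lnc in enumerate(built.X.lnc_ids)
    }
    return EvalBundle(
        truth=truth,
        term_ids=list(built.X.term_ids),
        lnc_ids=list(built.X.lnc_ids),
        grid=list(grid),
        train_positive=train_positive,
    )


def fit_and_predict(
    built: BuiltInputs, config: RunConfig
) -> tuple[FactorModel, np.ndarray]:
    model = fit(built.X, built.couplings, config)
    return model, predict_lncrna_scores(model, scale=config.scale_scores)
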
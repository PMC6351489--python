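"""Coupled synthetic benchmark instances with planted function modules.

Every downstream stage assumes the same latent structure: groups of lncRNAs
and genes that share a biological function also share correlated expression,
overlapping disease associations, dense interaction-network connectivity and
a common block of ontology terms. The generator plants exactly that
structure so the whole pipeline is testable without external databases.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .types import AnnotationMatrix, EntityNetwork, ExpressionMatrix, ValidationError

N_SAMPLES = 30            # expression profile length; balances correlation
                          # stability against run time
DISEASES_PER_MODULE = 8
BACKGROUND_DISEASE_RATE = 3.0   # Poisson mean is noise * this
PPI_WITHIN_P = 0.6
PPI_CROSS_P = 0.02


@dataclass
class SyntheticInstance:
    expr_l: ExpressionMatrix
    expr_g: ExpressionMatrix
    lnc_diseases: dict[str, set[str]]
    gene_diseases: dict[str, set[str]]
    ppi: EntityNetwork
    truth_X: AnnotationMatrix
    train_X: AnnotationMatrix
    mask: set[tuple[str, str]]
    planted_k: int
    seed: int
    lnc_modules: np.ndarray
    gene_modules: np.ndarray
    term_modules: np.ndarray


def _assign_modules(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Assign each entity a primary module; every module gets >= 1 member."""
    modules = np.empty(n, dtype=int)
    modules[:k] = np.arange(k)
    modules[k:] = rng.integers(0, k, size=n - k)
    return modules


def generate_instance(
    n_l: int,
    n_g: int,
    n_o: int,
    planted_k: int,
    noise: float,
    mask_fraction: float,
    seed: int,
) -> SyntheticInstance:
    """Generate one coupled instance with ``planted_k`` latent modules.

    Module-mates share a latent expression signal (per-module base profile
    plus independent noise scaled by ``noise``), draw diseases from a
    module-specific pool (each member carries a fraction 1 - noise*U(0, 0.5)
    of the pool, plus Poisson(noise*3) background diseases), genes are wired
    within modules with high probability and across with low probability,
    and each module owns a disjoint block of ontology terms annotated to all
    of its members. With noise = 0 and mask_fraction = 0 the instance is
    exactly block-structured.
    """
    if planted_k < 1 or planted_k > min(n_l, n_g, n_o):
        raise ValidationError(
            f"planted_k={planted_k} infeasible for sizes "
            f"(n_l={n_l}, n_g={n_g}, n_o={n_o})"
        )
    if not 0 <= noise <= 1:
        raise ValidationError("noise must lie in [0, 1]")
    if not 0 <= mask_fraction < 1:
        raise ValidationError("mask_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)

    lnc_ids = [f"l{i}" for i in range(n_l)]
    gene_ids = [f"g{i}" for i in range(n_g)]
    term_ids = [f"GO:{i:07d}" for i in range(n_o)]
    lnc_modules = _assign_modules(n_l, planted_k, rng)
    gene_modules = _assign_modules(n_g, planted_k, rng)
    term_modules = np.concatenate(
        [np.full(len(block), m) for m, block in
         enumerate(np.array_split(np.arange(n_o), planted_k))]
    )

    # expression: per-module latent profile + independent entity noise
    base = rng.standard_normal((planted_k, N_SAMPLES))
    samples = [f"s{j}" for j in range(N_SAMPLES)]
    expr_l = ExpressionMatrix(
        ids=lnc_ids,
        samples=samples,
        values=base[lnc_modules] + noise * rng.standard_normal((n_l, N_SAMPLES)),
    )
    expr_g = ExpressionMatrix(
        ids=gene_ids,
        samples=samples,
        values=base[gene_modules] + noise * rng.standard_normal((n_g, N_SAMPLES)),
    )

    # diseases: module pools plus noise-rate background
    pools = [
        [f"dis_m{m}_{j}" for j in range(DISEASES_PER_MODULE)]
        for m in range(planted_k)
    ]

    def draw_diseases(module: int) -> set[str]:
        pool = pools[module]
        frac = 1.0 - noise * rng.uniform(0.0, 0.5)
        n_carry = max(1, int(round(frac * len(pool))))
        carried = set(rng.choice(pool, size=n_carry, replace=False))
        n_bg = rng.poisson(noise * BACKGROUND_DISEASE_RATE)
        carried.update(f"dis_bg_{rng.integers(0, 10 * DISEASES_PER_MODULE)}"
                       for _ in range(n_bg))
        return carried

    lnc_diseases = {l: draw_diseases(m) for l, m in zip(lnc_ids, lnc_modules)}
    gene_diseases = {g: draw_diseases(m) for g, m in zip(gene_ids, gene_modules)}

    # PPI over genes: dense within modules, sparse across
    W = np.zeros((n_g, n_g))
    same = gene_modules[:, None] == gene_modules[None, :]
    probs = np.where(same, PPI_WITHIN_P, PPI_CROSS_P)
    upper = np.triu(rng.random((n_g, n_g)) < probs, k=1)
    W[upper] = 1.0
    W = W + W.T
    ppi = EntityNetwork(ids=gene_ids, W=W)

    # annotations: each module's term block annotated to all its members
    entity_modules = np.concatenate([lnc_modules, gene_modules])
    X = (term_modules[:, None] == entity_modules[None, :]).astype(float)
    truth_X = AnnotationMatrix(
        term_ids=term_ids,
        entity_ids=lnc_ids + gene_ids,
        n_l=n_l,
        X=X,
    )
    mask_seed = int(rng.integers(0, 2**31 - 1))
    train_X, mask = mask_annotations(truth_X, mask_fraction, mask_seed)

    return SyntheticInstance(
        expr_l=expr_l,
        expr_g=expr_g,
        lnc_diseases=lnc_diseases,
        gene_diseases=gene_diseases,
        ppi=ppi,
        truth_X=truth_X,
        train_X=train_X,
        mask=mask,
        planted_k=planted_k,
        seed=seed,
        lnc_modules=lnc_modules,
        gene_modules=gene_modules,
        term_modules=term_modules,
    )


def mask_annotations(
    X: AnnotationMatrix, fraction: float, seed: int
) -> tuple[AnnotationMatrix, set[tuple[str, str]]]:
    """Hide a fraction of the lncRNA annotations for held-out evaluation.

    Exactly floor(fraction * lncRNA-block positives) entries are zeroed,
    chosen uniformly without replacement; gene columns are untouched.
    Returns the training matrix and the hidden (term, lncRNA) pairs.
    """
    if not 0 <= fraction < 1:
        raise ValidationError("mask fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    rows, cols = np.nonzero(X.X[:, : X.n_l])
    n_hide = math.floor(fraction * len(rows))
    train = X.X.copy()
    mask: set[tuple[str, str]] = set()
    if n_hide > 0:
        chosen = rng.choice(len(rows), size=n_hide, replace=False)
        for idx in chosen:
            r, c = rows[idx], cols[idx]
            train[r, c] = 0.0
            mask.add((X.term_ids[r], X.entity_ids[c]))
    train_X = AnnotationMatrix(
        term_ids=list(X.term_ids),
        entity_ids=list(X.entity_ids),
        n_l=X.n_l,
        X=train,
    )
    return train_X, mask
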
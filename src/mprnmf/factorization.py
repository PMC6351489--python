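"""MPrNMF: multi-view partially regularized nonnegative matrix factorization.

The annotation matrix X (ontology terms x entities, lncRNA columns first) is
approximated by the product of a nonnegative basis B (n_o x k) and feature
matrix F (k x n), while F is pulled toward agreement with each lncRNA-gene
association view through a coupling matrix C_i* = [[0, Y_i], [Y_i', 0]].
Only the cross-class block of each view enters the regularizer — the
"partial" in the name — so the within-class networks do not double-count.

Objective
---------
    J(B, F) = ||X - B F||_F^2  -  alpha * sum_i tr(F C_i* F')
    s.t. B >= 0, F >= 0, every column of F on the k-simplex.

The trace term *rewards* agreement between the latent features of coupled
lncRNAs and genes (tr(F C_i* F') = 2 tr(F_l Y_i F_g')), which is the
orientation whose Karush-Kuhn-Tucker multiplicative update places the
alpha-term in the numerator; the simplex constraint on the F columns keeps
the reward bounded and yields sparse feature distributions.

Updates (multiplicative, Lee-Seung style; epsilon-guarded denominators)
-----------------------------------------------------------------------
    B <- B . (X F') / (B F F')
    F <- F . (B'X + alpha * sum_i F C_i*) / (B'B F),  then column-renormalize

An optional damped variant takes the element-wise square root of the update
ratio before multiplying (``update_variant="sqrt"``).
"""
from __future__ import annotations

import logging

import numpy as np

from .io import RunConfig
from .types import (
    AnnotationMatrix,
    BipartiteView,
    CouplingMatrix,
    FactorModel,
    ValidationError,
)

logger = logging.getLogger("mprnmf")

EPS = 1e-12


def build_coupling(view: BipartiteView) -> CouplingMatrix:
    """Embed a view's Y into the off-diagonal blocks of a coupling matrix."""
    n_l, n_g = view.Y.shape
    C = np.zeros((n_l + n_g, n_l + n_g))
    C[:n_l, n_l:] = view.Y
    C[n_l:, :n_l] = view.Y.T
    return CouplingMatrix(C_star=C, n_l=n_l, n_g=n_g)


def _check_finite(*mats: np.ndarray) -> None:
    for M in mats:
        if not np.isfinite(M).all():
            raise ValidationError("non-finite entries in factorization input")


def objective(
    X: np.ndarray,
    B: np.ndarray,
    F: np.ndarray,
    couplings: list[CouplingMatrix],
    alpha: float,
) -> float:
    """J = ||X - BF||_F^2 - alpha * sum_i tr(F C_i* F')."""
    X = np.asarray(X, dtype=float)
    _check_finite(X, B, F)
    if alpha < 0:
        raise ValidationError("alpha must be nonnegative")
    recon = float(np.linalg.norm(X - B @ F, "fro") ** 2)
    reg = sum(float(np.sum((F @ c.C_star) * F)) for c in couplings)
    return recon - alpha * reg


def update_basis(
    B: np.ndarray, F: np.ndarray, X: np.ndarray, variant: str = "standard"
) -> np.ndarray:
    """One multiplicative basis update: B . (X F') / (B F F')."""
    if B.shape[0] != X.shape[0] or B.shape[1] != F.shape[0] or F.shape[1] != X.shape[1]:
        raise ValidationError(
            f"shape mismatch: B{B.shape}, F{F.shape}, X{X.shape}"
        )
    num = X @ F.T
    den = B @ (F @ F.T) + EPS
    ratio = num / den
    if variant == "sqrt":
        ratio = np.sqrt(ratio)
    return B * ratio


def update_features(
    B: np.ndarray,
    F: np.ndarray,
    X: np.ndarray,
    couplings: list[CouplingMatrix],
    alpha: float,
    variant: str = "standard",
    normalize: bool = True,
) -> np.ndarray:
    """One multiplicative feature update with partial-view regularization.

    F . (B'X + alpha * sum_i F C_i*) / (B'B F); afterwards each column is
    renormalized onto the simplex (a column that collapses to all zeros is
    reset to uniform 1/k with a warning).
    """
    if B.shape[0] != X.shape[0] or B.shape[1] != F.shape[0] or F.shape[1] != X.shape[1]:
        raise ValidationError(
            f"shape mismatch: B{B.shape}, F{F.shape}, X{X.shape}"
        )
    if alpha < 0:
        raise ValidationError("alpha must be nonnegative")
    num = B.T @ X
    if alpha > 0:
        for c in couplings:
            num = num + alpha * (F @ c.C_star)
    den = (B.T @ B) @ F + EPS
    ratio = num / den
    if variant == "sqrt":
        ratio = np.sqrt(ratio)
    F_new = F * ratio
    if normalize:
        F_new = _normalize_columns(F_new)
    return F_new


def _normalize_columns(F: np.ndarray) -> np.ndarray:
    sums = F.sum(axis=0)
    zero = sums <= 0
    if zero.any():
        logger.warning(
            "%d feature column(s) collapsed to zero; reset to uniform", zero.sum()
        )
        F = F.copy()
        F[:, zero] = 1.0 / F.shape[0]
        sums = F.sum(axis=0)
    return F / sums


def fit(
    X: AnnotationMatrix | np.ndarray,
    couplings: list[CouplingMatrix],
    config: RunConfig,
    n_l: int | None = None,
    normalize: bool = True,
) -> FactorModel:
    """Fit MPrNMF by alternating multiplicative updates.

    B and F are initialized uniform(0, 1) under ``config.seed`` with F
    column-normalized; the updates alternate for ``config.iterations``
    rounds or until the relative objective change drops below ``config.tol``.

    ``normalize=False`` skips the per-iteration simplex renormalization of
    F, recovering the classical multiplicative algorithm whose objective is
    provably non-increasing at alpha = 0 (the simplex constraint only
    belongs to the regularized objective).
    """
    if isinstance(X, AnnotationMatrix):
        n_l = X.n_l
        Xm = X.X
    else:
        Xm = np.asarray(X, dtype=float)
        if n_l is None:
            raise ValidationError("n_l required when X is a bare array")
    _check_finite(Xm)
    n_o, n = Xm.shape
    k = config.k
    if not 1 <= k < min(n_o, n):
        raise ValidationError(f"rank k={k} out of range for X of shape {Xm.shape}")
    for c in couplings:
        if c.C_star.shape != (n, n):
            raise ValidationError("coupling dimension mismatch with X columns")

    rng = np.random.default_rng(config.seed)
    B = rng.uniform(0.0, 1.0, size=(n_o, k))
    F = _normalize_columns(rng.uniform(0.0, 1.0, size=(k, n)))

    history = [objective(Xm, B, F, couplings, config.alpha)]
    for _ in range(config.iterations):
        B = update_basis(B, F, Xm, variant=config.update_variant)
        F = update_features(
            B, F, Xm, couplings, config.alpha,
            variant=config.update_variant, normalize=normalize,
        )
        J = objective(Xm, B, F, couplings, config.alpha)
        if not np.isfinite(J):
            raise ValidationError(
                f"objective diverged (J={J}) at iteration {len(history)}"
            )
        history.append(J)
        prev = history[-2]
        if abs(J - prev) < config.tol * max(abs(prev), EPS):
            break
    return FactorModel(
        B=B,
        F=F,
        k=k,
        alpha=config.alpha,
        objective_history=history,
        seed=config.seed,
        n_l=n_l,
    )


def predict_lncrna_scores(model: FactorModel, scale: bool = True) -> np.ndarray:
    """Score every (term, lncRNA) pair as B . F_l.

    With ``scale`` the scores are min-max scaled to [0, 1] over the whole
    matrix so a single threshold sweep applies.
    """
    S = model.B @ model.F_l
    if scale:
        lo, hi = S.min(), S.max()
        if hi > lo:
            S = (S - lo) / (hi - lo)
        else:
            S = np.zeros_like(S)
    return S
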
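"""Rank selection by factorization instability, plus the alpha sweep.

For each candidate rank k the model is refit tau times from random starts;
the dissimilarity of two basis matrices is

    diss(B1, B2) = (1/2k) * (2k - sum_j max_i h_ij - sum_i max_j h_ij)

where h_ij is the Pearson correlation between column i of B1 and column j
of B2, and the instability Upsilon(k) is the mean dissimilarity over all
unordered pairs of the tau runs. A stable rank (columns reproducible up to
permutation) scores near 0; the minimizer of the curve is selected.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .evaluation import EvaluationReport, fmax
from .factorization import fit, predict_lncrna_scores
from .io import RunConfig
from .types import AnnotationMatrix, CouplingMatrix, ValidationError


@dataclass
class InstabilityCurve:
    k_values: list[int]
    upsilon: list[float]
    tau: int
    seeds: list[list[int]]


def _column_standardize(B: np.ndarray) -> np.ndarray:
    """Center and unit-scale columns; zero-variance columns become zero."""
    Bc = B - B.mean(axis=0, keepdims=True)
    norms = np.sqrt((Bc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = Bc / norms
    Z[:, norms == 0] = 0.0
    return Z


def cross_correlation_matrix(B1: np.ndarray, B2: np.ndarray) -> np.ndarray:
    """h_ij = Pearson correlation of column i of B1 with column j of B2."""
    B1 = np.asarray(B1, dtype=float)
    B2 = np.asarray(B2, dtype=float)
    if B1.shape != B2.shape:
        raise ValidationError(f"shape mismatch: {B1.shape} vs {B2.shape}")
    return _column_standardize(B1).T @ _column_standardize(B2)


def dissimilarity(B1: np.ndarray, B2: np.ndarray) -> float:
    """0 when the columns match up to permutation; approaches 1 when no
    column of one factorization correlates with any column of the other."""
    H = cross_correlation_matrix(B1, B2)
    k = H.shape[0]
    return float((2 * k - H.max(axis=0).sum() - H.max(axis=1).sum()) / (2 * k))


def instability(bases: list[np.ndarray]) -> float:
    """Mean pairwise dissimilarity over all unordered pairs of runs."""
    tau = len(bases)
    if tau < 2:
        raise ValidationError("instability needs at least 2 basis matrices")
    total = 0.0
    for i in range(tau):
        for j in range(i + 1, tau):
            total += dissimilarity(bases[i], bases[j])
    return 2.0 * total / (tau * (tau - 1))


def _derive_seed(base_seed: int, index: int) -> int:
    return int((base_seed * 1_000_003 + index) % (2**31 - 1))


def select_rank(
    X: AnnotationMatrix | np.ndarray,
    couplings: list[CouplingMatrix],
    alpha: float,
    k_grid: list[int],
    tau: int,
    seed: int,
    config: RunConfig | None = None,
    n_l: int | None = None,
) -> tuple[int, InstabilityCurve]:
    """Fit tau seeded models per rank and return the instability minimizer.

    Ties break toward the smallest k.
    """
    if tau < 2:
        raise ValidationError("tau must be >= 2")
    config = RunConfig() if config is None else config
    upsilon: list[float] = []
    all_seeds: list[list[int]] = []
    for gi, k in enumerate(k_grid):
        seeds = [_derive_seed(seed, gi * tau + t) for t in range(tau)]
        bases = []
        for s in seeds:
            cfg = replace(config, k=int(k), alpha=alpha, seed=s)
            bases.append(fit(X, couplings, cfg, n_l=n_l).B)
        upsilon.append(instability(bases))
        all_seeds.append(seeds)
    best_idx = int(np.argmin(upsilon))  # argmin takes the first minimum
    curve = InstabilityCurve(
        k_values=[int(k) for k in k_grid], upsilon=upsilon, tau=tau, seeds=all_seeds
    )
    return int(k_grid[best_idx]), curve


@dataclass
class EvalBundle:
    """Held-out evaluation inputs for parameter sweeps.

    ``truth`` maps lncRNA id -> hidden (held-out) true term set;
    ``train_positive`` maps lncRNA id -> terms already known at training
    time, which are excluded from the candidate predictions.
    """

    truth: dict[str, set[str]]
    term_ids: list[str]
    lnc_ids: list[str]
    grid: list[float]
    train_positive: dict[str, set[str]] | None = None


def evaluate_model_on_bundle(scores: np.ndarray, bundle: EvalBundle) -> EvaluationReport:
    """Fmax on held-out annotations, masking out training positives."""
    S = np.asarray(scores, dtype=float).copy()
    if bundle.train_positive:
        row = {t: i for i, t in enumerate(bundle.term_ids)}
        for j, lnc in enumerate(bundle.lnc_ids):
            for term in bundle.train_positive.get(lnc, ()):
                S[row[term], j] = 0.0
    return fmax(S, bundle.truth, bundle.grid, bundle.term_ids, bundle.lnc_ids)


def sweep_alpha(
    X: AnnotationMatrix | np.ndarray,
    couplings: list[CouplingMatrix],
    alpha_grid: list[float],
    k: int,
    eval_bundle: EvalBundle,
    seed: int = 0,
    config: RunConfig | None = None,
    n_l: int | None = None,
) -> list[tuple[float, float]]:
    """One held-out Fmax per alpha at fixed rank k."""
    config = RunConfig() if config is None else config
    results: list[tuple[float, float]] = []
    for alpha in alpha_grid:
        cfg = replace(config, k=int(k), alpha=float(alpha), seed=seed)
        model = fit(X, couplings, cfg, n_l=n_l)
        scores = predict_lncrna_scores(model)[:, : len(eval_bundle.lnc_ids)]
        report = evaluate_model_on_bundle(scores, eval_bundle)
        results.append((float(alpha), report.fmax))
    return results
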
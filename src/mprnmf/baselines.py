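"""Graph-propagation reference predictors.

Four methods from the network-analysis family are implemented exactly as
their objective functions are printed, to serve as baselines for the
factorization model:

* label propagation on a single entity network,
* label propagation on a bi-colored (two-class) network,
* dual label propagation (independent smoothing over each class), and
* a truncated KATZ path-counting scorer on the bi-colored network.
"""
from __future__ import annotations

import numpy as np

from .networks import bicolored_network, laplacian, normalize_adjacency
from .types import BiColoredMatrix, PropagationResult, ValidationError

ITER_TOL = 1e-10
MAX_ITERS = 100_000


def _lp_closed(X: np.ndarray, L: np.ndarray, theta: float) -> np.ndarray:
    # minimizer of theta*tr(Xh L Xh') + (1-theta)||Xh - X||^2
    A = theta * L + (1.0 - theta) * np.eye(L.shape[0])
    return (1.0 - theta) * np.linalg.solve(A.T, X.T).T


def _lp_iterative(X: np.ndarray, W_bar: np.ndarray, theta: float) -> np.ndarray:
    X_hat = X.copy()
    for _ in range(MAX_ITERS):
        X_next = theta * (X_hat @ W_bar) + (1.0 - theta) * X
        if np.max(np.abs(X_next - X_hat)) < ITER_TOL:
            return X_next
        X_hat = X_next
    return X_hat


def label_propagation(
    X: np.ndarray,
    W_bar: np.ndarray,
    theta: float = 0.5,
    method: str = "closed",
) -> PropagationResult:
    """Propagate labels over one network.

    Minimizes theta*tr(Xh L Xh') + (1-theta)*||Xh - X||^2 with L = I - W_bar,
    either in closed form Xh = (1-theta) X (theta L + (1-theta) I)^{-1} or by
    iterating Xh <- theta Xh W_bar + (1-theta) X to tolerance; the two agree.
    """
    if not 0.0 < theta < 1.0:
        raise ValidationError("theta must lie strictly in (0, 1)")
    X = np.asarray(X, dtype=float)
    if method == "closed":
        L = np.eye(W_bar.shape[0]) - W_bar
        X_hat = _lp_closed(X, L, theta)
    elif method == "iterative":
        X_hat = _lp_iterative(X, W_bar, theta)
    else:
        raise ValidationError(f"unknown method {method!r}")
    return PropagationResult(
        X_hat=X_hat, method="label_propagation", params={"theta": theta}
    )


def bicolored_label_propagation(
    X: np.ndarray,
    C: BiColoredMatrix,
    theta: float = 0.5,
    method: str = "closed",
) -> PropagationResult:
    """Label propagation over the bi-colored network.

    Gene annotation signal flows into the lncRNA columns through the
    cross-class block Y of C.
    """
    W_bar = normalize_adjacency(bicolored_network(C))
    res = label_propagation(X, W_bar, theta=theta, method=method)
    return PropagationResult(
        X_hat=res.X_hat,
        method="bicolored_label_propagation",
        params={"theta": theta},
    )


def dual_label_propagation(
    X: np.ndarray,
    L_g: np.ndarray,
    L_l: np.ndarray,
    n_l: int,
    beta: float = 0.5,
    gamma: float = 0.5,
) -> PropagationResult:
    """Independent Laplacian smoothing over the two entity classes.

    Minimizes ||Xh - X||^2 + beta*tr(Xh_g L_g Xh_g') + gamma*tr(Xh_l L_l Xh_l')
    whose blocks decouple: Xh_l = X_l (gamma L_l + I)^{-1} and
    Xh_g = X_g (beta L_g + I)^{-1}. As formulated there is no lncRNA-gene
    coupling: the two classes are smoothed separately.
    """
    if beta < 0 or gamma < 0:
        raise ValidationError("beta and gamma must be nonnegative")
    X = np.asarray(X, dtype=float)
    X_l, X_g = X[:, :n_l], X[:, n_l:]
    A_l = gamma * L_l + np.eye(L_l.shape[0])
    A_g = beta * L_g + np.eye(L_g.shape[0])
    X_hat = np.hstack(
        [np.linalg.solve(A_l.T, X_l.T).T, np.linalg.solve(A_g.T, X_g.T).T]
    )
    return PropagationResult(
        X_hat=X_hat,
        method="dual_label_propagation",
        params={"beta": beta, "gamma": gamma},
    )


def katz_scores(
    C: BiColoredMatrix, beta: float = 0.01, max_len: int | None = 3
) -> np.ndarray:
    """Truncated KATZ index S = sum_{p=1..max_len} beta^p C^p.

    With ``max_len=None`` the full series is summed in closed form
    (I - beta C)^{-1} - I, which requires beta * spectral_radius(C) < 1.
    """
    if beta < 0:
        raise ValidationError("beta must be nonnegative")
    M = C.C
    n = M.shape[0]
    if max_len is None:
        radius = float(np.max(np.abs(np.linalg.eigvalsh(M))))
        if beta * radius >= 1.0:
            raise ValidationError(
                f"KATZ series diverges: beta * spectral_radius = {beta * radius:.4g} >= 1"
            )
        return np.linalg.inv(np.eye(n) - beta * M) - np.eye(n)
    if max_len < 1:
        raise ValidationError("max_len must be a positive integer")
    S = np.zeros_like(M)
    P = np.eye(n)
    for _ in range(max_len):
        P = beta * (P @ M)
        S += P
    return S


def katz_predict(
    C: BiColoredMatrix,
    X_g: np.ndarray,
    beta: float = 0.01,
    max_len: int | None = 3,
) -> PropagationResult:
    """Term scores for lncRNAs from KATZ proximity to annotated genes.

    The gene-to-lncRNA block of S carries path-weighted proximities; scores
    are X_g (n_o x n_g) times S_gl, i.e. each lncRNA inherits the terms of
    the genes it is KATZ-close to.
    """
    S = katz_scores(C, beta=beta, max_len=max_len)
    S_gl = S[C.n_l :, : C.n_l]
    X_hat = np.asarray(X_g, dtype=float) @ S_gl
    return PropagationResult(
        X_hat=X_hat, method="katz", params={"beta": beta, "max_len": max_len}
    )
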
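"""Core domain containers shared across the pipeline.

A single entity-ordering convention is used everywhere: lncRNAs first, then
genes, each class in the order its identifiers were first introduced. Every
matrix whose columns (or rows) index entities follows that one index map.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class ParseError(ValueError):
    """Raised when an external file cannot be parsed."""


@dataclass
class ExpressionMatrix:
    """Entities-by-samples expression values with identifier bookkeeping."""

    ids: list[str]
    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.ids), len(self.samples)):
            raise ValidationError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.ids)} ids x {len(self.samples)} samples"
            )
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValidationError(f"duplicate entity IDs: {dupes}")

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class EntityNetwork:
    """Weighted undirected graph over one entity class.

    ``W`` is the symmetric nonnegative adjacency with zero diagonal.
    """

    ids: list[str]
    W: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        n = len(self.ids)
        if self.W.shape != (n, n):
            raise ValidationError(f"adjacency shape {self.W.shape} != ({n},{n})")
        if not np.allclose(self.W, self.W.T):
            raise ValidationError("adjacency must be symmetric")
        if (self.W < 0).any():
            raise ValidationError("adjacency weights must be nonnegative")
        if np.any(np.diag(self.W) != 0):
            raise ValidationError("adjacency diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.ids)

    def degrees(self) -> np.ndarray:
        return self.W.sum(axis=1)

    def subnetwork(self, indices: list[int]) -> "EntityNetwork":
        idx = np.asarray(indices, dtype=int)
        return EntityNetwork(
            ids=[self.ids[i] for i in idx], W=self.W[np.ix_(idx, idx)]
        )


@dataclass
class BipartiteView:
    """One source of lncRNA-gene associations (a view)."""

    name: str
    lnc_ids: list[str]
    gene_ids: list[str]
    Y: np.ndarray

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.shape != (len(self.lnc_ids), len(self.gene_ids)):
            raise ValidationError(
                f"view {self.name!r}: Y shape {self.Y.shape} inconsistent with ids"
            )
        if (self.Y < 0).any():
            raise ValidationError(f"view {self.name!r}: associations must be >= 0")


@dataclass
class BiColoredMatrix:
    """Adjacency of the two-class network: [[W_l, Y], [Y', W_g]]."""

    C: np.ndarray
    n_l: int
    n_g: int

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        n = self.n_l + self.n_g
        if self.C.shape != (n, n):
            raise ValidationError(f"bi-colored matrix shape {self.C.shape} != ({n},{n})")
        if not np.allclose(self.C, self.C.T):
            raise ValidationError("bi-colored matrix must be symmetric")

    @property
    def W_l(self) -> np.ndarray:
        return self.C[: self.n_l, : self.n_l]

    @property
    def W_g(self) -> np.ndarray:
        return self.C[self.n_l :, self.n_l :]

    @property
    def Y(self) -> np.ndarray:
        return self.C[: self.n_l, self.n_l :]


@dataclass
class AnnotationMatrix:
    """Binary ontology-by-entity matrix; lncRNA columns first, then genes."""

    term_ids: list[str]
    entity_ids: list[str]
    n_l: int
    X: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape != (len(self.term_ids), len(self.entity_ids)):
            raise ValidationError(
                f"annotation shape {self.X.shape} inconsistent with ids"
            )
        if not np.isin(self.X, (0.0, 1.0)).all():
            raise ValidationError("annotation entries must be binary")
        if not 0 <= self.n_l <= len(self.entity_ids):
            raise ValidationError("n_l out of range")

    @property
    def n_o(self) -> int:
        return len(self.term_ids)

    @property
    def n_g(self) -> int:
        return len(self.entity_ids) - self.n_l

    @property
    def lnc_ids(self) -> list[str]:
        return self.entity_ids[: self.n_l]

    @property
    def gene_ids(self) -> list[str]:
        return self.entity_ids[self.n_l :]

    @property
    def X_l(self) -> np.ndarray:
        return self.X[:, : self.n_l]

    @property
    def X_g(self) -> np.ndarray:
        return self.X[:, self.n_l :]


@dataclass
class CouplingMatrix:
    """Off-diagonal embedding [[0, Y], [Y', 0]] of one view's associations.

    Only the cross-class blocks carry weight: the within-class blocks are
    identically zero, which is what makes the regularization *partial*.
    """

    C_star: np.ndarray
    n_l: int
    n_g: int

    def __post_init__(self) -> None:
        self.C_star = np.asarray(self.C_star, dtype=float)
        n = self.n_l + self.n_g
        if self.C_star.shape != (n, n):
            raise ValidationError("coupling matrix shape mismatch")
        if np.any(self.C_star[: self.n_l, : self.n_l] != 0) or np.any(
            self.C_star[self.n_l :, self.n_l :] != 0
        ):
            raise ValidationError("coupling diagonal blocks must be zero")
        if not np.allclose(self.C_star, self.C_star.T):
            raise ValidationError("coupling matrix must be symmetric")


@dataclass
class FactorModel:
    """A fitted nonnegative factorization X ~ B F.

    ``B`` (n_o x k) holds per-term loadings on latent function groups and
    ``F`` (k x (n_l+n_g)) the per-entity feature distributions; every column
    of F lies on the k-simplex.
    """

    B: np.ndarray
    F: np.ndarray
    k: int
    alpha: float
    objective_history: list[float]
    seed: int
    n_l: int

    @property
    def F_l(self) -> np.ndarray:
        return self.F[:, : self.n_l]

    @property
    def F_g(self) -> np.ndarray:
        return self.F[:, self.n_l :]


@dataclass
class PropagationResult:
    """Scores produced by one of the graph-propagation reference methods."""

    X_hat: np.ndarray
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X_hat = np.asarray(self.X_hat, dtype=float)
        if not np.isfinite(self.X_hat).all():
            raise ValidationError(f"{self.method}: non-finite scores")
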
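"""Core quantities for direct differential-network estimation.

The differential network between two conditions is the difference
``Delta = Theta_Y - Theta_X`` of their precision (inverse covariance)
matrices; a nonzero off-diagonal entry marks a gene pair whose
conditional dependence changes between the conditions.  Rather than
estimating each precision matrix separately, ``Delta`` is estimated
directly by minimising the D-trace loss

    L_D(Delta) = (1/4) (<Sx Delta, Delta Sy> + <Sy Delta, Delta Sx>)
                 - <Delta, Sx - Sy>,

with ``<A, B> = tr(A B^T)`` and ``Sx``, ``Sy`` the two sample
covariance matrices.  The loss is convex and quadratic in ``Delta``
and its unpenalised minimiser is ``Sy^{-1} - Sx^{-1}``, which is
exactly the population differential network when the sample
covariances are exact.

This module holds the data containers (expression matrix, covariance
pair, estimated network), the loss, its gradient, and the weighted
soft-thresholding operator that is the proximal map of the weighted
lasso penalty used by the solver.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "CovariancePair",
    "DifferentialNetwork",
    "sample_covariance",
    "dtrace_loss",
    "dtrace_gradient",
    "weighted_soft_threshold",
]

# Symmetry / PSD round-off tolerances for covariance containers.
SYMMETRY_TOL = 1e-12
PSD_TOL = 1e-10
# Entries smaller than this after symmetrisation averaging are treated
# as zero when a support is recomputed from a dense matrix; the prox
# itself produces exact zeros, which are used directly.
SUPPORT_TOL = 1e-8


@dataclass
class ExpressionMatrix:
    """Genes-by-samples expression matrix for one condition.

    ``values`` has one row per gene and one column per sample.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D genes x samples array")
        p, n = self.values.shape
        if len(self.gene_ids) != p:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {p} rows")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} columns")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def restrict(self, genes: list[str]) -> "ExpressionMatrix":
        """Return the sub-matrix for ``genes``, in the given order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not present in matrix: {missing[:5]}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(self.values[rows], list(genes), list(self.sample_ids))


def sample_covariance(X: ExpressionMatrix | np.ndarray, center: bool = True) -> np.ndarray:
    """Sample covariance ``(1/n) X X^T`` over samples, optionally mean-centred.

    With genes as rows this is the gene-by-gene covariance.  The model
    assumes zero-mean data, but real expression values are not
    zero-mean, so per-gene centring is on by default; ``center=False``
    gives the literal ``(1/n) X X^T`` second-moment matrix.
    """
    V = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    if V.ndim != 2:
        raise ValueError("expected a 2-D genes x samples array")
    n = V.shape[1]
    if n < 2:
        raise ValueError(f"need at least 2 samples to estimate a covariance, got {n}")
    if center:
        V = V - V.mean(axis=1, keepdims=True)
    S = (V @ V.T) / n
    return 0.5 * (S + S.T)


@dataclass
class CovariancePair:
    """The two p x p sample covariances and their provenance."""

    sigma_X: np.ndarray
    sigma_Y: np.ndarray
    n_X: int
    n_Y: int
    gene_ids: list[str] = field(default_factory=list)
    centered: bool = True

    def __post_init__(self) -> None:
        self.sigma_X = np.asarray(self.sigma_X, dtype=float)
        self.sigma_Y = np.asarray(self.sigma_Y, dtype=float)
        for name, S in (("sigma_X", self.sigma_X), ("sigma_Y", self.sigma_Y)):
            if S.ndim != 2 or S.shape[0] != S.shape[1]:
                raise ValueError(f"{name} must be square, got shape {S.shape}")
            if not np.all(np.abs(S - S.T) <= SYMMETRY_TOL * max(1.0, np.abs(S).max())):
                raise ValueError(f"{name} is not symmetric")
        if self.sigma_X.shape != self.sigma_Y.shape:
            raise ValueError("sigma_X and sigma_Y must have the same shape")
        # Symmetrise exactly so downstream algebra preserves symmetry.
        self.sigma_X = 0.5 * (self.sigma_X + self.sigma_X.T)
        self.sigma_Y = 0.5 * (self.sigma_Y + self.sigma_Y.T)
        for name, S in (("sigma_X", self.sigma_X), ("sigma_Y", self.sigma_Y)):
            w = np.linalg.eigvalsh(S)
            if w.min() < -PSD_TOL * max(1.0, w.max()):
                raise ValueError(
                    f"{name} is not positive semidefinite (min eigenvalue {w.min():.3e})"
                )
        if not self.gene_ids:
            self.gene_ids = [f"G{i:04d}" for i in range(self.p)]
        elif len(self.gene_ids) != self.p:
            raise ValueError("gene_ids length does not match matrix dimension")

    @property
    def p(self) -> int:
        return self.sigma_X.shape[0]

    @classmethod
    def from_samples(
        cls, X: ExpressionMatrix, Y: ExpressionMatrix, center: bool = True
    ) -> "CovariancePair":
        if X.gene_ids != Y.gene_ids:
            raise ValueError("the two conditions must share the same gene list")
        return cls(
            sigma_X=sample_covariance(X, center=center),
            sigma_Y=sample_covariance(Y, center=center),
            n_X=X.n_samples,
            n_Y=Y.n_samples,
            gene_ids=list(X.gene_ids),
            centered=center,
        )


@dataclass
class DifferentialNetwork:
    """Estimated differential network: a symmetric sparse matrix.

    Nonzero off-diagonal entries of ``delta`` are the differential
    edges; ``support`` holds them as unordered index pairs (i < j).
    """

    delta: np.ndarray
    gene_ids: list[str]
    lambda_used: float
    support: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        self.delta = 0.5 * (self.delta + self.delta.T)
        if not self.support:
            self.support = support_of(self.delta)

    @property
    def p(self) -> int:
        return self.delta.shape[0]

    @property
    def n_edges(self) -> int:
        return len(self.support)


def support_of(delta: np.ndarray, tol: float = 0.0) -> set[tuple[int, int]]:
    """Off-diagonal support of a symmetric matrix as unordered pairs.

    The proximal operator produces exact zeros, so the default
    threshold is exact; pass ``tol`` > 0 only for matrices that went
    through averaging.
    """
    i_idx, j_idx = np.nonzero(np.triu(np.abs(delta) > tol, k=1))
    return set(zip(i_idx.tolist(), j_idx.tolist()))


def _check_pair_shapes(delta: np.ndarray, cov: CovariancePair) -> np.ndarray:
    delta = np.asarray(delta, dtype=float)
    if delta.shape != cov.sigma_X.shape:
        raise ValueError(
            f"delta shape {delta.shape} does not match covariance shape {cov.sigma_X.shape}"
        )
    return delta


def dtrace_loss(delta: np.ndarray, cov: CovariancePair) -> float:
    """D-trace loss ``(1/4)(<Sx D, D Sy> + <Sy D, D Sx>) - <D, Sx - Sy>``."""
    D = _check_pair_shapes(delta, cov)
    Sx, Sy = cov.sigma_X, cov.sigma_Y
    # <A, B> = tr(A B^T) = sum(A * B)
    quad = np.sum((Sx @ D) * (D @ Sy)) + np.sum((Sy @ D) * (D @ Sx))
    lin = np.sum(D * (Sx - Sy))
    return float(0.25 * quad - lin)


def dtrace_gradient(delta: np.ndarray, cov: CovariancePair) -> np.ndarray:
    """Gradient ``(1/2)(Sx D Sy + Sy D Sx) - (Sx - Sy)`` of the D-trace loss."""
    D = _check_pair_shapes(delta, cov)
    Sx, Sy = cov.sigma_X, cov.sigma_Y
    return 0.5 * (Sx @ D @ Sy + Sy @ D @ Sx) - (Sx - Sy)


def weighted_soft_threshold(
    A: np.ndarray,
    lam: float,
    W: np.ndarray,
    penalize_diagonal: bool = False,
) -> np.ndarray:
    """Elementwise ``sign(A) * max(|A| - lam * W, 0)``.

    This is the exact proximal map of the weighted lasso penalty
    ``lam * sum W_ij |Delta_ij|`` (plus ``(1/2)||Delta - A||_F^2``).
    The diagonal passes through unchanged unless ``penalize_diagonal``
    is set: edges are off-diagonal relationships, so by default the
    diagonal carries no penalty.
    """
    if lam < 0:
        raise ValueError(f"lam must be nonnegative, got {lam}")
    A = np.asarray(A, dtype=float)
    W = np.asarray(W, dtype=float)
    out = np.sign(A) * np.maximum(np.abs(A) - lam * W, 0.0)
    if not penalize_diagonal:
        np.fill_diagonal(out, np.diag(A))
    return out
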
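"""StARS stability selection for the lasso level of the differential network.

The Stability Approach to Regularization Selection chooses the least
regularisation whose estimated graph is stable under subsampling: for
each lambda on a decreasing grid, the model is refit on S subsample
pairs (the two conditions subsampled independently, without
replacement, b = min(floor(10*sqrt(n)), n-1) samples each), per-edge
selection frequencies xi_ij are tallied, edge instability is
2*xi*(1-xi), and total instability is the mean over off-diagonal
pairs.  The instability curve is monotonised by a running supremum
from the most-penalised end, and the selected lambda is the smallest
(densest graph) whose monotonised instability stays at or below the
threshold beta (0.005 here, with S = 20 subsamples).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dtrace import CovariancePair, ExpressionMatrix, sample_covariance
from .solver import SolverConfig, lambda_max, solve_wdtrace

__all__ = ["StarsConfig", "StarsResult", "subsample_pair", "stars_select", "default_lambda_grid"]

logger = logging.getLogger(__name__)


@dataclass
class StarsConfig:
    """StARS settings; grid defaults to 20 log-spaced points from
    lambda_max down to 0.01*lambda_max computed on the full data."""

    beta: float = 0.005
    n_subsamples: int = 20
    lambda_grid: np.ndarray | None = None
    n_lambda: int = 20
    lambda_min_ratio: float = 0.01
    seed: int = 0
    solver: SolverConfig = field(default_factory=SolverConfig)
    center: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.beta < 1.0:
            raise ValueError("beta must lie in (0, 1)")
        if self.n_subsamples < 2:
            raise ValueError("need at least 2 subsamples")
        if self.lambda_grid is not None:
            grid = np.asarray(self.lambda_grid, dtype=float)
            if grid.size == 0:
                raise ValueError("lambda grid must be non-empty")
            if np.any(grid <= 0) or np.any(np.diff(grid) >= 0):
                raise ValueError("lambda grid must be positive and strictly decreasing")
            self.lambda_grid = grid


@dataclass
class StarsResult:
    lambda_selected: float
    lambda_grid: np.ndarray
    instability_per_lambda: np.ndarray        # raw total instability
    monotone_instability: np.ndarray          # running sup from largest lambda
    edge_frequency: np.ndarray                # n_lambda x p x p selection frequencies
    n_fits_used: np.ndarray                   # converged fits per lambda
    all_stable: bool = False
    none_stable: bool = False


def subsample_size(n: int) -> int:
    """b = floor(10*sqrt(n)), capped at n-1."""
    return min(int(np.floor(10.0 * np.sqrt(n))), n - 1)


def subsample_pair(
    n_X: int, n_Y: int, b_X: int, b_Y: int, S: int, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """S paired index subsets, drawn without replacement per condition."""
    if b_X >= n_X or b_Y >= n_Y:
        raise ValueError("subsample size must be smaller than the sample count")
    if S < 2:
        raise ValueError("need at least 2 subsamples")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(S):
        ix = np.sort(rng.choice(n_X, size=b_X, replace=False))
        iy = np.sort(rng.choice(n_Y, size=b_Y, replace=False))
        out.append((ix, iy))
    return out


def default_lambda_grid(lam_max: float, n_lambda: int = 20,
                        min_ratio: float = 0.01) -> np.ndarray:
    if lam_max <= 0:
        # Degenerate data (identical covariances); a token positive grid.
        lam_max = 1e-8
    return np.geomspace(lam_max, min_ratio * lam_max, n_lambda)


def stars_select(
    X: ExpressionMatrix,
    Y: ExpressionMatrix,
    W=None,
    config: StarsConfig | None = None,
) -> StarsResult:
    """Run StARS over paired subsamples of the two conditions.

    Each subsample pair is fit along the whole lambda path with warm
    starts (large to small lambda).  Fits that fail to converge are
    excluded from the frequency tally with a warning; selection
    proceeds while at least half the subsamples remain per lambda.
    """
    if config is None:
        config = StarsConfig()
    n_X, n_Y = X.n_samples, Y.n_samples
    p = X.n_genes

    full_cov = CovariancePair.from_samples(X, Y, center=config.center)
    if config.lambda_grid is not None:
        grid = config.lambda_grid
    else:
        lam_max = lambda_max(full_cov, W, config.solver.penalize_diagonal)
        grid = default_lambda_grid(lam_max, config.n_lambda, config.lambda_min_ratio)
    n_lambda = len(grid)

    b_X, b_Y = subsample_size(n_X), subsample_size(n_Y)
    subsets = subsample_pair(n_X, n_Y, b_X, b_Y, config.n_subsamples, config.seed)

    freq = np.zeros((n_lambda, p, p))
    n_used = np.zeros(n_lambda, dtype=int)
    n_failed = 0
    for ix, iy in subsets:
        cov = CovariancePair(
            sigma_X=sample_covariance(X.values[:, ix], center=config.center),
            sigma_Y=sample_covariance(Y.values[:, iy], center=config.center),
            n_X=len(ix),
            n_Y=len(iy),
            gene_ids=list(X.gene_ids),
            centered=config.center,
        )
        init = None
        for li, lam in enumerate(grid):
            scfg = SolverConfig(
                lam=float(lam),
                max_iter=config.solver.max_iter,
                tol=config.solver.tol,
                step_rule=config.solver.step_rule,
                penalize_diagonal=config.solver.penalize_diagonal,
                restart=config.solver.restart,
            )
            net, trace = solve_wdtrace(cov, W, scfg, init=init)
            init = net.delta
            if trace.converged:
                adj = np.zeros((p, p))
                for i, j in net.support:
                    adj[i, j] = adj[j, i] = 1.0
                freq[li] += adj
                n_used[li] += 1
            else:
                n_failed += 1
    if n_failed:
        logger.warning("%d subsample fit(s) did not converge and were excluded", n_failed)
    if np.any(n_used < config.n_subsamples / 2):
        logger.warning(
            "fewer than half the subsample fits converged at %d lambda value(s)",
            int(np.sum(n_used < config.n_subsamples / 2)),
        )

    with np.errstate(invalid="ignore"):
        xi = freq / np.maximum(n_used, 1)[:, None, None]
    inst_edge = 2.0 * xi * (1.0 - xi)
    offdiag = ~np.eye(p, dtype=bool)
    n_pairs = p * (p - 1) / 2
    instability = np.array(
        [inst_edge[li][offdiag].sum() / 2.0 / n_pairs for li in range(n_lambda)]
    )
    monotone = np.maximum.accumulate(instability)

    stable = monotone <= config.beta
    all_stable = bool(stable.all())
    none_stable = bool(~stable.any())
    if none_stable:
        logger.warning("no lambda on the grid is stable at beta=%.4g; "
                       "returning the most penalised grid point", config.beta)
        lam_sel = float(grid[0])
    else:
        # smallest stable lambda = densest graph still deemed stable
        lam_sel = float(grid[np.where(stable)[0][-1]])

    return StarsResult(
        lambda_selected=lam_sel,
        lambda_grid=np.asarray(grid, dtype=float),
        instability_per_lambda=instability,
        monotone_instability=monotone,
        edge_frequency=xi,
        n_fits_used=n_used,
        all_stable=all_stable,
        none_stable=none_stable,
    )
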
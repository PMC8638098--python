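"""Independent oracles used by the test suite.

Everything here deliberately avoids the implementation paths it
checks: naive double loops, exact integer combinatorics, a
general-purpose bound-constrained quasi-Newton solve of the penalised
objective via its smooth positive/negative-part split, and a hand
transcription of the Benjamini-Hochberg step-up rule.
"""

from __future__ import annotations

from math import comb

import numpy as np
from scipy.optimize import minimize


def naive_covariance(values: np.ndarray, center: bool) -> np.ndarray:
    """Entry-by-entry double-loop sample covariance of a genes x samples matrix."""
    V = np.asarray(values, dtype=float)
    p, n = V.shape
    if center:
        V = V - V.mean(axis=1, keepdims=True)
    S = np.zeros((p, p))
    for i in range(p):
        for j in range(p):
            acc = 0.0
            for k in range(n):
                acc += V[i, k] * V[j, k]
            S[i, j] = acc / n
    return S


def naive_dtrace_loss(delta, sigma_x, sigma_y) -> float:
    """Trace-by-trace evaluation of the D-trace loss, <A,B> = tr(A B^T)."""
    D = np.asarray(delta, dtype=float)
    Sx, Sy = np.asarray(sigma_x), np.asarray(sigma_y)
    inner = lambda A, B: float(np.trace(A @ B.T))
    return (
        0.25 * (inner(Sx @ D, D @ Sy) + inner(Sy @ D, D @ Sx))
        - inner(D, Sx - Sy)
    )


def loop_soft_threshold(A, lam, W, penalize_diagonal) -> np.ndarray:
    """Elementwise loop transcription of the weighted shrinkage rule."""
    A = np.asarray(A, dtype=float)
    W = np.asarray(W, dtype=float)
    out = np.empty_like(A)
    for i in range(A.shape[0]):
        for j in range(A.shape[1]):
            if i == j and not penalize_diagonal:
                out[i, j] = A[i, j]
                continue
            mag = abs(A[i, j]) - lam * W[i, j]
            out[i, j] = np.sign(A[i, j]) * mag if mag > 0 else 0.0
    return out


def reference_objective_minimum(
    sigma_x, sigma_y, W, lam, penalize_diagonal=False, tol=1e-12
) -> float:
    """Minimum of the penalised D-trace objective by an independent route.

    Splits Delta = P - N with P, N >= 0 so the weighted L1 term becomes
    the linear form lam * sum(W * (P + N)) and the whole objective is
    smooth; solves the bound-constrained problem with L-BFGS-B.
    Returns the optimal objective value.
    """
    Sx = np.asarray(sigma_x, dtype=float)
    Sy = np.asarray(sigma_y, dtype=float)
    W = np.asarray(W, dtype=float)
    p = Sx.shape[0]
    pen_mask = W * lam
    if not penalize_diagonal:
        pen_mask = pen_mask - np.diag(np.diag(pen_mask))

    def split(v):
        P = v[: p * p].reshape(p, p)
        N = v[p * p :].reshape(p, p)
        return P, N

    def fun(v):
        P, N = split(v)
        D = P - N
        loss = naive_dtrace_loss(D, Sx, Sy)
        return loss + float(np.sum(pen_mask * (P + N)))

    def grad(v):
        P, N = split(v)
        D = P - N
        G = 0.5 * (Sx @ D @ Sy + Sy @ D @ Sx) - (Sx - Sy)
        gP = G + pen_mask
        gN = -G + pen_mask
        return np.concatenate([gP.ravel(), gN.ravel()])

    x0 = np.zeros(2 * p * p)
    res = minimize(
        fun,
        x0,
        jac=grad,
        method="L-BFGS-B",
        bounds=[(0, None)] * (2 * p * p),
        options={"maxiter": 20000, "ftol": tol, "gtol": 1e-12},
    )
    return float(res.fun)


def enumerate_hypergeom_tail(N: int, M: int, n: int, m: int) -> float:
    """Exact integer-combinatorics upper tail P(overlap >= m)."""
    denom = comb(N, n)
    total = 0
    for i in range(m, min(M, n) + 1):
        total += comb(M, i) * comb(N - M, n - i)
    return total / denom


def stepup_bh(p_values) -> np.ndarray:
    """Hand transcription of the Benjamini-Hochberg step-up rule."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        value = min(p[idx] * m / rank, 1.0)
        running_min = min(running_min, value)
        adjusted[idx] = running_min
    return adjusted


def random_covariance_pair(p: int, rng: np.random.Generator, n: int = 60):
    """A well-behaved random covariance pair for oracle comparisons."""
    A = rng.standard_normal((p, n))
    B = rng.standard_normal((p, n)) + 0.3 * rng.standard_normal((p, 1))
    Sx = (A @ A.T) / n
    Sy = (B @ B.T) / n
    return 0.5 * (Sx + Sx.T), 0.5 * (Sy + Sy.T)


def correlated_counts_bundle(
    scenario, n_per_group, n_null_genes, base_mean=500.0, lfc=3.0, seed=0
):
    """Counts whose first block of genes carries a planted network.

    The scenario genes' log2 expression follows the two planted
    Gaussian graphical models (one per group) plus a fold-change shift
    in group 2, realised as Poisson counts around ``base_mean * 2**z``;
    the null genes are independent Poisson at ``base_mean``.  Returns
    (counts, gene_ids, sample_ids, group_labels).
    """
    import wdtrace as w

    rng = np.random.default_rng(seed)
    p = scenario.p
    zx = w.sample_expression(scenario.theta_X, n_per_group, seed=seed + 1).values
    zy = w.sample_expression(scenario.theta_Y, n_per_group, seed=seed + 2).values
    mu_sig = np.hstack([base_mean * 2.0**zx, base_mean * 2.0 ** (zy + lfc)])
    mu_null = np.full((n_null_genes, 2 * n_per_group), base_mean)
    counts = rng.poisson(np.vstack([mu_sig, mu_null]))
    gene_ids = list(scenario.gene_ids) + [f"N{i:04d}" for i in range(n_null_genes)]
    sample_ids = [f"S{j:04d}" for j in range(2 * n_per_group)]
    labels = ["A"] * n_per_group + ["B"] * n_per_group
    return counts, gene_ids, sample_ids, labels
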
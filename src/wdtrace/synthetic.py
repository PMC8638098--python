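"""Synthetic inputs for every stage of the differential-network pipeline.

Three generators cover the three kinds of data the pipeline consumes:

* paired multivariate-Gaussian expression whose two precision matrices
  differ on a known, planted set of off-diagonal edges (the ground
  truth for support-recovery checks);
* negative-binomial count matrices with planted log2 fold changes for
  the differential-expression stage, parameterised by mean ``mu`` and
  dispersion ``alpha`` so that ``var = mu + alpha * mu**2``;
* prior regulatory edge lists with controllable overlap with the true
  differential edges, plus toy gene sets.

All generators are pure functions of their arguments including the
seed; writers emit the same plain-text dialects the pipeline reads
(genes-by-samples TSV, TRRUST-style 4-column edge list, GMT).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dtrace import ExpressionMatrix
from .prior import PriorNetwork

__all__ = [
    "DifferentialScenario",
    "CountScenario",
    "make_precision_pair",
    "sample_expression",
    "make_prior_network",
    "make_nb_counts",
    "default_gene_ids",
    "write_expression_tsv",
    "write_counts_tsv",
    "write_group_labels_tsv",
    "write_trrust",
    "write_gmt",
]

# Diagonal margin added beyond the most negative eigenvalue when
# conditioning the planted precision matrices to positive definiteness.
PD_MARGIN = 0.1


def default_gene_ids(p: int) -> list[str]:
    return [f"G{i:04d}" for i in range(p)]


@dataclass
class DifferentialScenario:
    """Ground truth for one simulated two-condition experiment."""

    p: int
    n_X: int
    n_Y: int
    theta_X: np.ndarray
    theta_Y: np.ndarray
    delta_true: np.ndarray
    diff_edges: set[tuple[int, int]]
    seed: int
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.gene_ids:
            self.gene_ids = default_gene_ids(self.p)


@dataclass
class CountScenario:
    """Simulated count matrix with planted differential expression."""

    counts: np.ndarray
    group_labels: list[str]
    de_genes: set[int]
    true_lfc: np.ndarray
    dispersion: np.ndarray
    seed: int
    gene_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n_genes, n_samples = self.counts.shape
        if not self.gene_ids:
            self.gene_ids = default_gene_ids(n_genes)
        if not self.sample_ids:
            self.sample_ids = [f"S{j:04d}" for j in range(n_samples)]
        if len(self.group_labels) != n_samples:
            raise ValueError("one group label per sample is required")


def _all_pairs(p: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(p) for j in range(i + 1, p)]


def make_precision_pair(
    p: int,
    n_common_edges: int,
    n_diff_edges: int,
    magnitude: float = 0.3,
    seed: int = 0,
) -> DifferentialScenario:
    """Build two precision matrices differing on a planted edge set.

    ``theta_X`` gets ``n_common_edges`` random off-diagonal entries of
    ``+-magnitude``; ``theta_Y`` adds ``+-magnitude`` perturbations at
    ``n_diff_edges`` further random pairs.  Both matrices are then made
    positive definite by the *same* diagonal shift ``c * I`` with
    ``c = |most negative eigenvalue across both| + 0.1``, so the
    off-diagonal difference — the ground-truth differential network —
    is preserved exactly.
    """
    if p < 3:
        raise ValueError("need at least 3 genes")
    n_pairs = p * (p - 1) // 2
    if n_common_edges > n_pairs or n_diff_edges > n_pairs:
        raise ValueError(f"edge counts must not exceed p(p-1)/2 = {n_pairs}")
    if magnitude <= 0:
        raise ValueError("magnitude must be positive")
    rng = np.random.default_rng(seed)
    pairs = _all_pairs(p)

    theta_X = np.zeros((p, p))
    common_idx = rng.choice(n_pairs, size=n_common_edges, replace=False)
    for k in common_idx:
        i, j = pairs[k]
        v = magnitude * rng.choice([-1.0, 1.0])
        theta_X[i, j] = theta_X[j, i] = v

    perturb = np.zeros((p, p))
    remaining = [k for k in range(n_pairs) if k not in set(common_idx.tolist())]
    if n_diff_edges > len(remaining):
        raise ValueError("not enough free pairs for the requested differential edges")
    diff_idx = rng.choice(len(remaining), size=n_diff_edges, replace=False)
    diff_edges: set[tuple[int, int]] = set()
    for k in diff_idx:
        i, j = pairs[remaining[k]]
        v = magnitude * rng.choice([-1.0, 1.0])
        perturb[i, j] = perturb[j, i] = v
        diff_edges.add((i, j))
    theta_Y = theta_X + perturb

    eig_min = min(
        np.linalg.eigvalsh(theta_X).min(), np.linalg.eigvalsh(theta_Y).min()
    )
    c = abs(min(eig_min, 0.0)) + PD_MARGIN
    theta_X = theta_X + c * np.eye(p)
    theta_Y = theta_Y + c * np.eye(p)
    for name, th in (("theta_X", theta_X), ("theta_Y", theta_Y)):
        if np.linalg.eigvalsh(th).min() <= 0:
            raise RuntimeError(f"{name} failed positive-definiteness conditioning")

    return DifferentialScenario(
        p=p,
        n_X=0,
        n_Y=0,
        theta_X=theta_X,
        theta_Y=theta_Y,
        delta_true=theta_Y - theta_X,
        diff_edges=diff_edges,
        seed=seed,
    )


def sample_expression(theta: np.ndarray, n: int, seed: int = 0) -> ExpressionMatrix:
    """Draw ``n`` samples from ``N(0, theta^{-1})`` as a genes x samples matrix."""
    theta = np.asarray(theta, dtype=float)
    if theta.ndim != 2 or theta.shape[0] != theta.shape[1]:
        raise ValueError("theta must be a square matrix")
    if not np.allclose(theta, theta.T, atol=1e-10):
        raise ValueError("theta must be symmetric")
    eigs = np.linalg.eigvalsh(theta)
    if eigs.min() <= 0:
        raise ValueError(
            f"theta must be positive definite (min eigenvalue {eigs.min():.3e})"
        )
    if n < 2:
        raise ValueError("need at least 2 samples")
    p = theta.shape[0]
    cov = np.linalg.inv(theta)
    cov = 0.5 * (cov + cov.T)
    L = np.linalg.cholesky(cov)
    rng = np.random.default_rng(seed)
    values = L @ rng.standard_normal((p, n))
    return ExpressionMatrix(
        values=values,
        gene_ids=default_gene_ids(p),
        sample_ids=[f"S{j:04d}" for j in range(n)],
    )


def make_prior_network(
    scenario: DifferentialScenario,
    coverage: float,
    noise_edges: int = 0,
    seed: int = 0,
) -> PriorNetwork:
    """Prior edge list overlapping the true differential edges.

    ``coverage`` is the fraction of true differential edges included;
    ``noise_edges`` further random non-differential pairs are added to
    emulate prior knowledge that is unrelated to the condition change.
    """
    if not 0.0 <= coverage <= 1.0:
        raise ValueError("coverage must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = scenario.gene_ids
    diff = sorted(scenario.diff_edges)
    n_true = int(round(coverage * len(diff)))
    chosen: set[tuple[int, int]] = set()
    if n_true:
        picked = rng.choice(len(diff), size=n_true, replace=False)
        chosen = {diff[k] for k in picked}
    non_diff = [pr for pr in _all_pairs(scenario.p) if pr not in scenario.diff_edges]
    if noise_edges > len(non_diff):
        raise ValueError("not enough non-differential pairs for the requested noise")
    if noise_edges:
        picked = rng.choice(len(non_diff), size=noise_edges, replace=False)
        chosen |= {non_diff[k] for k in picked}
    edges = {frozenset((genes[i], genes[j])) for i, j in chosen}
    return PriorNetwork(edges=edges, source=f"synthetic(coverage={coverage}, seed={seed})")


def make_nb_counts(
    n_genes: int,
    n_per_group: int = 40,
    n_de: int = 0,
    lfc: float = 3.0,
    dispersion: float = 0.1,
    base_mean: float = 100.0,
    seed: int = 0,
) -> CountScenario:
    """Two-group NB counts with ``n_de`` planted fold-change genes.

    Group-1 genes have mean ``base_mean``; the planted genes have mean
    ``base_mean * 2**lfc`` in group 2.  Draws follow the mean/dispersion
    parameterisation ``var = mu + alpha * mu**2``; dispersions below
    1e-8 fall back to Poisson draws (the ``alpha -> 0`` limit).
    """
    if n_per_group < 1:
        raise ValueError("need at least 1 sample per group")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    if n_de > n_genes:
        raise ValueError("cannot plant more DE genes than genes")
    rng = np.random.default_rng(seed)
    de_genes: set[int] = set()
    if n_de:
        de_genes = set(rng.choice(n_genes, size=n_de, replace=False).tolist())
    true_lfc = np.zeros(n_genes)
    for g in de_genes:
        true_lfc[g] = lfc

    mu = np.full((n_genes, 2 * n_per_group), base_mean, dtype=float)
    mu[list(de_genes), n_per_group:] = base_mean * 2.0**lfc

    if dispersion < 1e-8:
        counts = rng.poisson(mu)
    else:
        # numpy's NB(n, p) has mean n(1-p)/p; n = 1/alpha, p = 1/(1+alpha*mu)
        # reproduces mean mu and variance mu + alpha*mu^2.
        size = 1.0 / dispersion
        prob = 1.0 / (1.0 + dispersion * mu)
        counts = rng.negative_binomial(size, prob)

    labels = ["A"] * n_per_group + ["B"] * n_per_group
    return CountScenario(
        counts=counts,
        group_labels=labels,
        de_genes=de_genes,
        true_lfc=true_lfc,
        dispersion=np.full(n_genes, dispersion),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# plain-text writers (the dialects the pipeline readers expect)


def write_expression_tsv(X: ExpressionMatrix, path: str | Path) -> None:
    """Genes x samples TSV: header of sample ids, first column gene ids."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene_id\t" + "\t".join(X.sample_ids) + "\n")
        for g, row in zip(X.gene_ids, X.values):
            fh.write(g + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def write_counts_tsv(cs: CountScenario, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene_id\t" + "\t".join(cs.sample_ids) + "\n")
        for g, row in zip(cs.gene_ids, cs.counts):
            fh.write(g + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def write_group_labels_tsv(cs: CountScenario, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sample_id\tgroup\n")
        for s, g in zip(cs.sample_ids, cs.group_labels):
            fh.write(f"{s}\t{g}\n")


def write_trrust(prior: PriorNetwork, path: str | Path) -> None:
    """TRRUST-dialect TSV: regulator, target, mode, reference."""
    path = Path(path)
    rows = sorted(tuple(sorted(e)) for e in prior.edges)
    with path.open("w") as fh:
        for a, b in rows:
            fh.write(f"{a}\t{b}\tUnknown\tsynthetic\n")


def write_gmt(sets: dict[str, list[str] | set[str]], path: str | Path,
              description: str = "synthetic") -> None:
    """GMT: set name, description, tab-separated members (one set per line)."""
    path = Path(path)
    with path.open("w") as fh:
        for name, members in sets.items():
            fh.write(name + "\t" + description + "\t" + "\t".join(sorted(members)) + "\n")
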
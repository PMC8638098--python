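"""Prior regulatory network and the penalty weight matrix it induces.

A curated regulatory database (TRRUST-style tab-separated records of
regulator, target, mode, reference) supplies a binary prior adjacency
S over gene symbols.  The weighted lasso uses it to make prior-supported
pairs cheaper to include: W_ij = w (default 0.1) where S_ij = 1 and
W_ij = 1 elsewhere.  Directionality and regulation mode are discarded —
the estimated differential network is symmetric, so the prior acts only
as an unordered edge indicator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["PriorNetwork", "WeightMatrix", "read_trrust", "build_weight_matrix"]

logger = logging.getLogger(__name__)

DEFAULT_PRIOR_WEIGHT = 0.1


@dataclass
class PriorNetwork:
    """Unordered gene-symbol pairs from a prior regulatory database."""

    edges: set[frozenset[str]] = field(default_factory=set)
    source: str = ""

    def __post_init__(self) -> None:
        for e in self.edges:
            if len(e) != 2:
                raise ValueError(f"prior edge {set(e)} is not an unordered pair")

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class WeightMatrix:
    """Penalty weights W with entries in {w, 1}, symmetric, unit diagonal."""

    values: np.ndarray
    w: float
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def read_trrust(path: str | Path) -> PriorNetwork:
    """Read a TRRUST-style TSV into an unordered prior edge set.

    Only the first two columns (regulator, target) are used; mode and
    reference columns are ignored.  Directed duplicates (A->B, B->A)
    collapse to one edge, self-loops are dropped, malformed lines are
    skipped — each with a logged count / line number.
    """
    path = Path(path)
    edges: set[frozenset[str]] = set()
    n_self = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                logger.warning("%s line %d: fewer than 2 fields, skipped", path, lineno)
                continue
            a, b = fields[0].strip(), fields[1].strip()
            if a == b:
                n_self += 1
                continue
            edges.add(frozenset((a, b)))
    if n_self:
        logger.info("%s: dropped %d self-loop record(s)", path, n_self)
    return PriorNetwork(edges=edges, source=str(path))


def build_weight_matrix(
    prior: PriorNetwork,
    gene_ids: list[str],
    w: float = DEFAULT_PRIOR_WEIGHT,
) -> WeightMatrix:
    """Penalty weights: w for prior-supported pairs, 1 elsewhere.

    Prior edges touching genes absent from ``gene_ids`` are ignored
    (with a logged count); the diagonal is always 1.
    """
    if not 0.0 < w < 1.0:
        raise ValueError(f"prior weight w must lie in (0, 1), got {w}")
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("gene_ids must be unique")
    index = {g: i for i, g in enumerate(gene_ids)}
    p = len(gene_ids)
    W = np.ones((p, p))
    n_outside = 0
    for edge in prior.edges:
        a, b = tuple(edge)
        if a in index and b in index:
            i, j = index[a], index[b]
            W[i, j] = W[j, i] = w
        else:
            n_outside += 1
    if n_outside:
        logger.info(
            "%d prior edge(s) touch genes outside the analysis gene list and were ignored",
            n_outside,
        )
    return WeightMatrix(values=W, w=w, gene_ids=list(gene_ids))
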
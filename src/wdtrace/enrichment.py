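"""Gene-set over-representation analysis (hypergeometric tail + BH).

For a differential gene list of size n drawn from a universe of N
genes, and a gene set covering M universe genes with m genes shared
with the list, the enrichment p-value is the hypergeometric upper
tail

    p = sum_{i=m}^{min(M,n)} C(M,i) C(N-M,n-i) / C(N,n),

i.e. the probability of an overlap at least as large under random
sampling.  P-values are Benjamini-Hochberg adjusted across the tested
sets.  The machinery is generic over any GMT gene-set collection
(KEGG-like pathways, GO-like terms); the analysis universe — here the
genes that survived the expression filter — plays the role of the
database-wide background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .de import bh_adjust

__all__ = ["GeneSetCollection", "hypergeom_tail", "enrich", "read_gmt"]

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe (N of the test)."""

    sets: dict[str, set[str]]
    universe: set[str] | None = None

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            self.sets[name] = set(members)
        if self.universe is not None:
            self.universe = set(self.universe)


def hypergeom_tail(N: int, M: int, n: int, m: int) -> float:
    """P(overlap >= m) for n draws from N with M marked.

    The sum runs to min(M, n); terms above n vanish.  m = 0 gives 1
    exactly (the full mass).
    """
    if not (0 <= M <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent margins N={N}, M={M}, n={n}")
    if not 0 <= m <= min(M, n):
        raise ValueError(f"overlap m={m} outside [0, min(M, n)={min(M, n)}]")
    if m == 0:
        return 1.0
    p = float(hypergeom.sf(m - 1, N, M, n))
    return min(max(p, 0.0), 1.0)


def enrich(de_genes, collection: GeneSetCollection) -> pd.DataFrame:
    """Over-representation table for a gene list against a collection.

    Genes absent from the universe are dropped (logged) before n is
    counted.  One row per set with at least one overlapping gene;
    BH adjustment across the tested sets; sorted by adjusted p-value,
    ties by set name.  Columns: set_name, N, M, n, count, p_value,
    p_adjust, overlap_genes.
    """
    if not collection.sets:
        raise ValueError("the gene-set collection is empty")
    if collection.universe is None:
        raise ValueError("the collection needs a background universe")
    universe = collection.universe
    de = set(de_genes)
    outside = de - universe
    if outside:
        logger.info("%d differential gene(s) outside the universe were dropped", len(outside))
    de &= universe
    N, n = len(universe), len(de)

    rows = []
    for name, members in collection.sets.items():
        inset = members & universe
        overlap = sorted(de & inset)
        if not overlap:
            continue
        M, m = len(inset), len(overlap)
        rows.append(
            {
                "set_name": name,
                "N": N,
                "M": M,
                "n": n,
                "count": m,
                "p_value": hypergeom_tail(N, M, n, m),
                "overlap_genes": ",".join(overlap),
            }
        )
    columns = ["set_name", "N", "M", "n", "count", "p_value", "p_adjust", "overlap_genes"]
    if not rows:
        return pd.DataFrame(columns=columns)
    table = pd.DataFrame(rows)
    table["p_adjust"] = bh_adjust(table["p_value"].to_numpy())
    table = table.sort_values(
        by=["p_adjust", "set_name"], kind="mergesort"
    ).reset_index(drop=True)
    return table[columns]


def read_gmt(path: str | Path, universe=None) -> GeneSetCollection:
    """Read a GMT file (name, description, tab-separated members).

    Duplicate members within a set are deduplicated; lines with fewer
    than 3 fields are skipped with a warning.  The universe is the
    caller's to supply — a GMT carries no background information.
    """
    path = Path(path)
    sets: dict[str, set[str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                logger.warning("%s line %d: fewer than 3 fields, skipped", path, lineno)
                continue
            name = fields[0].strip()
            members = {g.strip() for g in fields[2:] if g.strip()}
            if not members:
                logger.warning("%s line %d: set %r has no members, skipped", path, lineno, name)
                continue
            sets[name] = members
    return GeneSetCollection(sets=sets, universe=set(universe) if universe is not None else None)
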
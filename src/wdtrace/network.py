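"""Summaries of an estimated differential network.

Degrees, hub genes (top-k by degree; degree counts distinct nonzero
off-diagonal partners) and a plain-text edge-list export.  Edge
presence is the solver's exact-zero support — the proximal operator
produces exact zeros, so no magnitude re-thresholding happens here.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .dtrace import DifferentialNetwork

__all__ = ["degrees", "hub_genes", "export_edges"]


def degrees(net: DifferentialNetwork) -> pd.Series:
    """Per-gene degree in the differential network."""
    deg = np.zeros(net.p, dtype=int)
    for i, j in net.support:
        deg[i] += 1
        deg[j] += 1
    out = pd.Series(deg, index=pd.Index(net.gene_ids, name="gene_id"), name="degree")
    # handshake identity
    assert int(out.sum()) == 2 * len(net.support)
    return out


def hub_genes(net: DifferentialNetwork, k: int = 10) -> list[str]:
    """Top-k genes by degree, ties broken lexicographically by gene id.

    Genes of degree zero are never hubs, even when fewer than k genes
    have edges.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    deg = degrees(net)
    nonzero = deg[deg > 0]
    ranked = sorted(nonzero.items(), key=lambda kv: (-kv[1], kv[0]))
    return [g for g, _ in ranked[:k]]


def export_edges(net: DifferentialNetwork, path: str | Path) -> pd.DataFrame:
    """Write the edge list as TSV and return it as a DataFrame.

    One row per unordered pair (gene_a < gene_b lexicographically),
    sorted by |delta| descending, with columns gene_a, gene_b,
    delta_value, abs_delta.
    """
    rows = []
    for i, j in net.support:
        a, b = net.gene_ids[i], net.gene_ids[j]
        if b < a:
            a, b = b, a
        v = float(net.delta[i, j])
        rows.append({"gene_a": a, "gene_b": b, "delta_value": v, "abs_delta": abs(v)})
    table = pd.DataFrame(rows, columns=["gene_a", "gene_b", "delta_value", "abs_delta"])
    if len(table):
        table = table.sort_values(
            by=["abs_delta", "gene_a", "gene_b"],
            ascending=[False, True, True],
            kind="mergesort",
        ).reset_index(drop=True)
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return table
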
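"""End-to-end orchestration of the differential-network analysis.

Two tracks mirror how the analysis is run in practice:

* top-k mode: NB differential expression on a count matrix, keep the
  k most significant genes, estimate the differential network on
  those genes (StARS-selected lasso level, prior-weighted penalty),
  then summarise (degrees, hubs, edge list) and run gene-set
  enrichment of the differential genes;
* gene-set mode: restrict both expression matrices to the members of
  one named gene set and estimate the differential network there,
  localising the regulatory change to a pathway.

Counts entering the network stage are transformed as
``log2(count / size_factor + 1)`` by default — the network model
assumes Gaussian data — with ``transform: none`` honouring
pre-normalised input.  Every run writes TSV tables plus a JSON
manifest (config echo, seed, versions, convergence flags); outputs
are deterministic given the seed, and contain no timestamps, so
reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .de import filter_low_expressed, nb_wald_test, select_de_genes, size_factors, top_k_genes
from .dtrace import CovariancePair, ExpressionMatrix
from .enrichment import GeneSetCollection, enrich, read_gmt
from .network import degrees, export_edges, hub_genes
from .prior import PriorNetwork, build_weight_matrix, read_trrust
from .solver import SolverConfig, solve_wdtrace
from .stars import StarsConfig, stars_select
from .synthetic import CountScenario

__all__ = [
    "PipelineConfig",
    "read_counts_tsv",
    "read_expression_tsv",
    "read_group_labels_tsv",
    "run_topk_pipeline",
    "run_geneset_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, loadable from YAML."""

    # inputs
    counts_path: str | None = None
    labels_path: str | None = None
    expression_x_path: str | None = None
    expression_y_path: str | None = None
    prior_path: str | None = None
    gmt_path: str | None = None
    out_dir: str = "wdtrace_out"
    mode: str = "top-k-genes"           # or "gene-set"
    gene_set: str | None = None
    # DE stage
    min_total: int = 10
    p_adjust_max: float = 0.01
    lfc_min: float = 2.0
    k: int = 100
    # network stage
    w: float = 0.1
    beta: float = 0.005
    n_subsamples: int = 20
    n_lambda: int = 20
    lambda_min_ratio: float = 0.01
    lambda_fixed: float | None = None   # skip StARS and fit at this level
    solver_tol: float = 1e-6
    solver_max_iter: int = 5000
    penalize_diagonal: bool = False
    transform: str = "log1p-normalized"  # or "none"
    seed: int = 0
    # summary
    n_hubs: int = 10

    def __post_init__(self) -> None:
        if self.mode not in ("top-k-genes", "gene-set"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.transform not in ("log1p-normalized", "none"):
            raise ValueError(f"unknown transform {self.transform!r}")
        for name in ("p_adjust_max", "lfc_min", "w", "beta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def read_counts_tsv(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Genes x samples TSV -> (matrix, gene_ids, sample_ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(), [str(g) for g in df.index], [str(s) for s in df.columns]


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    values, genes, samples = read_counts_tsv(path)
    return ExpressionMatrix(values=np.asarray(values, dtype=float),
                            gene_ids=genes, sample_ids=samples)


def read_group_labels_tsv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("group-label file needs columns sample_id and group")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def _expression_transform(counts: np.ndarray, transform: str) -> np.ndarray:
    if transform == "none":
        return np.asarray(counts, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if counts.min() < 0:
        raise ValueError(
            "negative values found: the input looks already normalised; "
            "set transform: 'none'"
        )
    sf = size_factors(counts)
    return np.log2(counts / sf + 1.0)


def _split_by_group(
    values: np.ndarray, gene_ids: list[str], sample_ids: list[str], labels: dict[str, str]
) -> tuple[ExpressionMatrix, ExpressionMatrix, str, str]:
    missing = [s for s in sample_ids if s not in labels]
    if missing:
        raise ValueError(f"samples without a group label: {missing[:5]}")
    levels = sorted({labels[s] for s in sample_ids})  # alphabetical reference
    if len(levels) != 2:
        raise ValueError(f"exactly two groups are required, got {levels}")
    g1, g2 = levels
    ix = [j for j, s in enumerate(sample_ids) if labels[s] == g1]
    iy = [j for j, s in enumerate(sample_ids) if labels[s] == g2]
    if len(ix) < 2 or len(iy) < 2:
        raise ValueError("each group needs at least 2 samples")
    X = ExpressionMatrix(values[:, ix], list(gene_ids), [sample_ids[j] for j in ix])
    Y = ExpressionMatrix(values[:, iy], list(gene_ids), [sample_ids[j] for j in iy])
    return X, Y, g1, g2


def _network_stage(
    X: ExpressionMatrix,
    Y: ExpressionMatrix,
    prior: PriorNetwork | None,
    config: PipelineConfig,
    out: Path,
) -> dict:
    """Shared StARS + final fit + summary, writing the network outputs."""
    W = None
    n_prior_edges = 0
    if prior is not None:
        wm = build_weight_matrix(prior, X.gene_ids, w=config.w)
        W = wm.values
        n_prior_edges = int((wm.values == config.w).sum() // 2)
    solver_cfg = SolverConfig(
        tol=config.solver_tol,
        max_iter=config.solver_max_iter,
        penalize_diagonal=config.penalize_diagonal,
    )
    if config.lambda_fixed is not None:
        lam_sel = float(config.lambda_fixed)
        stars = None
    else:
        stars_cfg = StarsConfig(
            beta=config.beta,
            n_subsamples=config.n_subsamples,
            n_lambda=config.n_lambda,
            lambda_min_ratio=config.lambda_min_ratio,
            seed=config.seed,
            solver=solver_cfg,
        )
        logger.info(
            "StARS selection over %d subsample pairs, %d genes",
            config.n_subsamples, X.n_genes,
        )
        stars = stars_select(X, Y, W, stars_cfg)
        lam_sel = stars.lambda_selected
    cov = CovariancePair.from_samples(X, Y)
    final_cfg = dataclasses.replace(solver_cfg, lam=lam_sel)
    net, trace = solve_wdtrace(cov, W, final_cfg)
    logger.info("selected lambda=%.5g; %d differential edge(s)", lam_sel, net.n_edges)

    if stars is not None:
        pd.DataFrame(
            {
                "lambda": stars.lambda_grid,
                "instability": stars.instability_per_lambda,
                "monotone_instability": stars.monotone_instability,
                "n_fits_used": stars.n_fits_used,
            }
        ).to_csv(out / "stars_instability.tsv", sep="\t", index=False, float_format="%.10g")
    edge_table = export_edges(net, out / "edges.tsv")
    deg = degrees(net)
    deg.to_frame().to_csv(out / "degrees.tsv", sep="\t")
    hubs = hub_genes(net, k=config.n_hubs)
    (out / "hub_genes.txt").write_text("".join(h + "\n" for h in hubs))

    return {
        "lambda_selected": lam_sel,
        "n_edges": int(net.n_edges),
        "n_prior_edges_used": n_prior_edges,
        "final_fit_converged": bool(trace.converged),
        "stars_all_stable": stars.all_stable if stars else None,
        "stars_none_stable": stars.none_stable if stars else None,
        "hub_genes": hubs,
        "network_genes": list(X.gene_ids),
        "_net": net,
        "_edges": edge_table,
    }


def _write_manifest(out: Path, config: PipelineConfig, stage_info: dict) -> dict:
    manifest = {
        "tool": "wdtrace",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        **{k: v for k, v in stage_info.items() if not k.startswith("_")},
    }
    with (out / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def run_topk_pipeline(config: PipelineConfig) -> dict:
    """DE -> top-k genes -> differential network -> summaries + enrichment."""
    if not config.counts_path or not config.labels_path:
        raise ValueError("top-k mode needs counts_path and labels_path")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    counts, gene_ids, sample_ids = read_counts_tsv(config.counts_path)
    labels = read_group_labels_tsv(config.labels_path)
    label_list = [labels.get(s) for s in sample_ids]
    if any(lab is None for lab in label_list):
        raise ValueError("every sample column needs a group label")
    level_counts = pd.Series(label_list).value_counts()
    if len(level_counts) != 2 or level_counts.min() < 2:
        raise ValueError("exactly two groups with >= 2 samples each are required")

    scenario = CountScenario(
        counts=counts,
        group_labels=label_list,
        de_genes=set(),
        true_lfc=np.zeros(len(gene_ids)),
        dispersion=np.ones(len(gene_ids)),
        seed=config.seed,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
    )
    filtered = filter_low_expressed(scenario, config.min_total)
    logger.info(
        "expression filter: %d of %d genes kept (min_total=%d)",
        len(filtered.gene_ids), len(gene_ids), config.min_total,
    )

    res = nb_wald_test(filtered.counts, filtered.group_labels, filtered.gene_ids)
    res.to_csv(out / "de_results.tsv", sep="\t", float_format="%.10g")
    de_genes = select_de_genes(res, config.p_adjust_max, config.lfc_min)
    top_genes = top_k_genes(res, k=config.k)
    (out / "de_genes.txt").write_text("".join(g + "\n" for g in de_genes))
    (out / "network_genes.txt").write_text("".join(g + "\n" for g in top_genes))
    logger.info("%d DE gene(s) under the thresholds; %d genes enter the network stage",
                len(de_genes), len(top_genes))

    expr = _expression_transform(filtered.counts, config.transform)
    em = ExpressionMatrix(expr, filtered.gene_ids, filtered.sample_ids)
    sub = em.restrict(top_genes)
    X, Y, g1, g2 = _split_by_group(sub.values, sub.gene_ids, sub.sample_ids, labels)

    prior = read_trrust(config.prior_path) if config.prior_path else None
    stage = _network_stage(X, Y, prior, config, out)

    enrichment_rows = 0
    if config.gmt_path:
        collection = read_gmt(config.gmt_path, universe=filtered.gene_ids)
        table = enrich(de_genes, collection)
        table.to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format="%.10g")
        enrichment_rows = len(table)

    config.to_yaml(out / "config_echo.yaml")
    info = {
        "mode": "top-k-genes",
        "groups": [g1, g2],
        "n_genes_filtered": len(filtered.gene_ids),
        "n_de_genes": len(de_genes),
        "n_network_genes": len(top_genes),
        "n_enriched_sets": enrichment_rows,
        **stage,
    }
    manifest = _write_manifest(out, config, info)
    info["manifest"] = manifest
    return info


def run_geneset_pipeline(config: PipelineConfig, set_name: str | None = None) -> dict:
    """Differential network restricted to the genes of one named set."""
    set_name = set_name or config.gene_set
    if not set_name:
        raise ValueError("gene-set mode needs a set name")
    if not config.gmt_path:
        raise ValueError("gene-set mode needs gmt_path")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.expression_x_path and config.expression_y_path:
        X_full = read_expression_tsv(config.expression_x_path)
        Y_full = read_expression_tsv(config.expression_y_path)
        if config.transform == "log1p-normalized":
            X_full.values = _expression_transform(X_full.values, config.transform)
            Y_full.values = _expression_transform(Y_full.values, config.transform)
    elif config.counts_path and config.labels_path:
        counts, gene_ids, sample_ids = read_counts_tsv(config.counts_path)
        labels = read_group_labels_tsv(config.labels_path)
        expr = _expression_transform(counts, config.transform)
        X_full, Y_full, _, _ = _split_by_group(expr, gene_ids, sample_ids, labels)
    else:
        raise ValueError(
            "gene-set mode needs either expression_x_path/expression_y_path "
            "or counts_path/labels_path"
        )

    collection = read_gmt(config.gmt_path)
    if set_name not in collection.sets:
        raise KeyError(f"gene set {set_name!r} not found in {config.gmt_path}")
    members = collection.sets[set_name]
    usable = [g for g in X_full.gene_ids if g in members and g in set(Y_full.gene_ids)]
    if len(usable) < 3:
        report = {
            "set_size": len(members),
            "present_in_X": len(members & set(X_full.gene_ids)),
            "present_in_Y": len(members & set(Y_full.gene_ids)),
            "usable": len(usable),
        }
        raise ValueError(f"fewer than 3 usable genes for set {set_name!r}: {report}")
    X = X_full.restrict(usable)
    Y = Y_full.restrict(usable)
    logger.info("gene set %r: %d of %d member genes usable", set_name, len(usable), len(members))

    prior = read_trrust(config.prior_path) if config.prior_path else None
    stage = _network_stage(X, Y, prior, config, out)

    config.to_yaml(out / "config_echo.yaml")
    info = {
        "mode": "gene-set",
        "gene_set": set_name,
        "n_network_genes": len(usable),
        **stage,
    }
    manifest = _write_manifest(out, config, info)
    info["manifest"] = manifest
    return info
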
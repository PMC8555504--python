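"""End-to-end orchestration: per-study DE, rank aggregation, MCODE hubs,
network assembly, loop detection and diagnostics."""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from . import diffexpr, mcode, rra
from .dataio import DEFAULT_THRESHOLDS, ExpressionStudy, RegPredictionTables
from .diagnostics import correlation_screen, marker_screen
from .regnet import FeedbackLoop, TriadNetwork, build_network


@dataclass
class PipelineResult:
    de_tables: dict[str, pd.DataFrame]
    mirna_de_table: pd.DataFrame
    rra_up: pd.DataFrame
    rra_down: pd.DataFrame
    deg_calls: dict[str, str]
    dem_calls: dict[str, str]
    network: TriadNetwork
    loops: list[FeedbackLoop]
    modules: mcode.ModuleSet | None
    hub_genes: list
    correlations: pd.DataFrame | None = None
    markers: pd.DataFrame | None = None


def call_degs(
    studies: list[ExpressionStudy], cfg: dict
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Per-study DE tables plus rank-aggregated consensus DEG calls."""
    de_tables = {
        s.study_id: diffexpr.de_test(s, lfc_threshold=cfg["lfc"], fdr_threshold=cfg["fdr"])
        for s in studies
    }
    agg = {}
    for direction in ("up", "down"):
        lists = rra.ranked_lists_from_de(
            de_tables, direction, mode=cfg["rra_mode"], lfc=cfg["lfc"], fdr=cfg["fdr"]
        )
        agg[direction] = rra.aggregate(lists, alpha=cfg["rra_alpha"])
    deg_calls = rra.consensus_calls(agg["up"], agg["down"], kind="gene")
    return de_tables, agg["up"], agg["down"], deg_calls


def run_pipeline(
    studies: list[ExpressionStudy],
    mirna_study: ExpressionStudy,
    tables: RegPredictionTables,
    ppi: nx.Graph | None = None,
    config: dict | None = None,
    validation_study: ExpressionStudy | None = None,
) -> PipelineResult:
    """Run the full screen.

    ``validation_study`` (default: the first mRNA study) supplies the
    expression values for the TF-target correlation screen and the per-gene
    ROC marker evaluation over the assembled network.
    """
    cfg = dict(DEFAULT_THRESHOLDS)
    cfg.update(config or {})

    de_tables, rra_up, rra_down, deg_calls = call_degs(studies, cfg)

    mirna_table = diffexpr.de_test(mirna_study, lfc_threshold=cfg["lfc"], fdr_threshold=cfg["fdr"])
    dem_calls = diffexpr.de_calls(mirna_table, lfc=cfg["lfc"], fdr=cfg["fdr"], kind="mirna")

    network, loops = build_network(deg_calls, dem_calls, tables, score_cutoff=cfg["score_cutoff"])

    modules = None
    hubs: list = []
    if ppi is not None:
        de_sub = ppi.subgraph([n for n in ppi if n in deg_calls])
        modules = mcode.find_modules(
            de_sub,
            degree_cutoff=cfg["degree_cutoff"],
            kcore_filter=cfg["kcore_filter"],
            vwp=cfg["vwp"],
            haircut=cfg["haircut"],
        )
        hubs = mcode.hub_genes(modules)

    correlations = markers = None
    val = validation_study if validation_study is not None else (studies[0] if studies else None)
    if val is not None and network.triads:
        pairs = sorted({(tf, g) for tf, _, g in network.triads})
        correlations = correlation_screen(val, pairs, r_cut=cfg["r_cut"], p_cut=cfg["p_cut"])
        genes = sorted({s for tf, _, g in network.triads for s in (tf, g)} | set(hubs))
        markers = marker_screen(val, genes, auc_cut=cfg["auc_cut"])

    return PipelineResult(
        de_tables=de_tables,
        mirna_de_table=mirna_table,
        rra_up=rra_up,
        rra_down=rra_down,
        deg_calls=deg_calls,
        dem_calls=dem_calls,
        network=network,
        loops=loops,
        modules=modules,
        hub_genes=hubs,
        correlations=correlations,
        markers=markers,
    )


def f1_score(predicted: set, truth: set) -> float:
    """Set-level F1; defined as 1.0 when both sets are empty."""
    predicted, truth = set(predicted), set(truth)
    if not predicted and not truth:
        return 1.0
    tp = len(predicted & truth)
    if tp == 0:
        return 0.0
    precision = tp / len(predicted)
    recall = tp / len(truth)
    return 2 * precision * recall / (precision + recall)
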
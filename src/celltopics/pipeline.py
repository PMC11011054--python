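"""End-to-end runner: counts -> graph -> fit -> topics -> assignment -> scores."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .cluster_assignment import AssignmentError, ClusterTopicAssignment, assign_from_level
from .data_io import CountLayer
from .evaluation import ClusteringScore, score_clustering
from .graph_build import HeterogeneousGraph, build_graph, normalize_library_size, select_highly_variable
from .sbm_core import BlockHierarchy, FitConfig, fit
from .topic_extract import TopicModelResult, extract_topics


@dataclass
class PipelineConfig:
    """Configuration of the full run.

    ``min_disp`` may be a single threshold or one per layer (the two omics
    layers have different intrinsic variability).  ``normalize=False`` skips
    library-size normalization and HVG selection (useful when counts are
    already pre-filtered, e.g. synthetic data).
    """

    normalize: bool = False
    target_sum: float = 1e4
    select_hvg: bool = False
    min_disp: float | tuple[float, ...] = 0.5
    n_bins: int = 20
    weight_mode: str = "raw-integer"
    fit: FitConfig = field(default_factory=FitConfig)
    assign_level: int = 0
    n_shuffles: int = 100


@dataclass
class PipelineResult:
    graph: HeterogeneousGraph
    hierarchy: BlockHierarchy
    topics: TopicModelResult
    assignment: ClusterTopicAssignment | None
    scores: dict[int, ClusteringScore] = field(default_factory=dict)


def run_pipeline(
    layers: list[CountLayer],
    labels: pd.Series | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    cfg = config or PipelineConfig()
    prepared = []
    for i, raw in enumerate(layers):
        norm = normalize_library_size(raw, target_sum=cfg.target_sum) if cfg.normalize else raw
        if cfg.select_hvg:
            md = cfg.min_disp[i] if isinstance(cfg.min_disp, tuple) else cfg.min_disp
            # HVG selection looks at normalized data; with raw-integer weights
            # the graph keeps the original counts of the selected genes
            hv = select_highly_variable(norm, min_disp=md, n_bins=cfg.n_bins)
            if cfg.weight_mode == "raw-integer":
                layer = raw.subset_genes(list(hv.genes)).subset_cells(list(hv.cells))
            else:
                layer = hv
        else:
            layer = raw if cfg.weight_mode == "raw-integer" else norm
        prepared.append(layer)

    graph = build_graph(prepared, weight_mode=cfg.weight_mode)
    hierarchy = fit(graph, cfg.fit)
    topics = extract_topics(hierarchy)

    assignment = None
    try:
        assignment = assign_from_level(topics.level(min(cfg.assign_level, len(topics.levels) - 1)))
    except AssignmentError:
        assignment = None  # degenerate partitions surface as a missing table

    scores: dict[int, ClusteringScore] = {}
    if labels is not None:
        cell_ids = [str(c) for c in graph.cells]
        truth = labels.reindex(cell_ids).to_numpy()
        for lvl in range(hierarchy.n_levels):
            pred = hierarchy.cell_clusters(lvl)
            scores[lvl] = score_clustering(
                pred, truth, n_shuffles=cfg.n_shuffles, seed=cfg.fit.seed
            )
    return PipelineResult(graph, hierarchy, topics, assignment, scores)
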
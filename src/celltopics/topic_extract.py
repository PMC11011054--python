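"""Convert fitted block hierarchies into topic/cluster probability tables.

For a level of the hierarchy, each gene block is a *topic* and each cell
block a *cluster*.  The tables are pure functions of (graph, partition):

* ``P(gene | topic) = k_gene / e_topic`` for genes inside the topic, where
  ``e_topic`` is the total edge multiplicity incident to the topic's genes;
  zero outside (hard block membership).
* ``P(topic | cell) = e(cell, topic) / k_cell^(layer)``, the fraction of the
  cell's edges *within that layer* that run into the topic; rows sum to one
  per layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graph_build import CELL_TYPE, HeterogeneousGraph
from .sbm_core import BlockHierarchy, BlockState


def _layer_labels(graph: HeterogeneousGraph, labels: np.ndarray, layer: str) -> np.ndarray:
    lo, hi = graph.gene_ranges[layer]
    lab = labels[lo:hi]
    _, compact = np.unique(lab, return_inverse=True)
    return compact


def _as_labels(graph: HeterogeneousGraph, state_or_labels) -> np.ndarray:
    if isinstance(state_or_labels, BlockState):
        return np.asarray(state_or_labels.b)
    return np.asarray(state_or_labels)


def gene_topic_distribution(
    graph: HeterogeneousGraph, state_or_labels, layer: str, prefix: str | None = None
) -> pd.DataFrame:
    """P(gene | topic) table (genes x topics) for one layer."""
    labels = _as_labels(graph, state_or_labels)
    topics = _layer_labels(graph, labels, layer)
    lo, hi = graph.gene_ranges[layer]
    k = graph.degrees[lo:hi].astype(float)
    n_topics = topics.max() + 1
    e_topic = np.bincount(topics, weights=k, minlength=n_topics)
    if (e_topic == 0).any():
        raise ValueError("empty topic encountered")
    table = np.zeros((hi - lo, n_topics))
    table[np.arange(hi - lo), topics] = k / e_topic[topics]
    pre = prefix if prefix is not None else layer
    cols = [f"{pre}_T{j}" for j in range(n_topics)]
    return pd.DataFrame(table, index=graph.genes(layer), columns=cols)


def topic_cell_distribution(
    graph: HeterogeneousGraph, state_or_labels, layer: str, prefix: str | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """P(topic | cell) table (cells x topics) for one layer.

    Returns the table and the list of cells with zero degree in the layer
    (their rows are zero and are flagged rather than silently normalized).
    """
    labels = _as_labels(graph, state_or_labels)
    topics = _layer_labels(graph, labels, layer)
    n_topics = topics.max() + 1
    M = graph.layer_matrices[layer]  # cells x genes, counts
    ind = np.zeros((M.shape[1], n_topics))
    ind[np.arange(M.shape[1]), topics] = 1.0
    e_ct = np.asarray(M @ ind)  # cells x topics
    k_cell = e_ct.sum(axis=1)
    zero = k_cell == 0
    out = np.zeros_like(e_ct)
    out[~zero] = e_ct[~zero] / k_cell[~zero, None]
    pre = prefix if prefix is not None else layer
    cols = [f"{pre}_T{j}" for j in range(n_topics)]
    cells = graph.cells
    flagged = [str(c) for c in cells[zero]]
    return pd.DataFrame(out, index=cells, columns=cols), flagged


@dataclass
class LevelTopics:
    """Probability tables of one hierarchy level."""

    level: int
    gene_topic: dict[str, pd.DataFrame]
    topic_cell: dict[str, pd.DataFrame]
    clusters: pd.Series  # cell -> cluster label
    zero_degree_cells: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return self.clusters.nunique()

    def pooled_topic_cell(self) -> pd.DataFrame:
        """Concatenate the per-layer P(topic|cell) tables column-wise."""
        return pd.concat([self.topic_cell[l] for l in sorted(self.topic_cell)], axis=1)


@dataclass
class TopicModelResult:
    """Per-level tables extracted from a fitted hierarchy."""

    levels: list[LevelTopics]
    sigma: float = float("nan")
    sigmas_per_init: list[float] = field(default_factory=list)

    def level(self, i: int) -> LevelTopics:
        return self.levels[i]


def extract_level(graph: HeterogeneousGraph, labels: np.ndarray, level: int) -> LevelTopics:
    gene_topic: dict[str, pd.DataFrame] = {}
    topic_cell: dict[str, pd.DataFrame] = {}
    zero_degree: dict[str, list[str]] = {}
    for layer in graph.gene_ranges:
        gene_topic[layer] = gene_topic_distribution(graph, labels, layer)
        topic_cell[layer], flagged = topic_cell_distribution(graph, labels, layer)
        if flagged:
            zero_degree[layer] = flagged
    cell_lab = labels[graph.node_type == CELL_TYPE]
    _, compact = np.unique(cell_lab, return_inverse=True)
    clusters = pd.Series(
        [f"C{j}" for j in compact], index=graph.cells, name="cluster", dtype=object
    )
    return LevelTopics(level, gene_topic, topic_cell, clusters, zero_degree)


def extract_topics(hierarchy: BlockHierarchy) -> TopicModelResult:
    """Extract probability tables for every level of a fitted hierarchy."""
    levels = [
        extract_level(hierarchy.graph, hierarchy.labels[i], i)
        for i in range(hierarchy.n_levels)
    ]
    return TopicModelResult(
        levels, sigma=hierarchy.sigma, sigmas_per_init=list(hierarchy.sigmas_per_init)
    )
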
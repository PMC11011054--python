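"""Adaptive assignment of topics to cell clusters.

The raw P(topic|cell) rows are dominated by large, unspecific topics; the
centered table Pc(topic|cell) = P(topic|cell) - mean_cells P(topic|cell) is
more informative.  Cluster-level means Pc(topic|cluster) are thresholded at
mu + n*sigma (mean and population standard deviation of a cluster's Pc values
across topics).  The multiplier n starts at 3 and is lowered in steps of 0.05
until (i) every cluster has at least one topic and (ii) no two clusters carry
identical topic sets (subsets are allowed); the first n on the grid meeting
both conditions is final.  Lowering n only loosens the thresholds, so topic
sets grow monotonically as n decreases and the first feasible grid value can
be returned.

The same operation applies to any cell partition (e.g. tumor-subtype labels),
not only fitted clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class AssignmentError(ValueError):
    pass


def center_topic_distribution(P: pd.DataFrame) -> pd.DataFrame:
    """Subtract each topic's mean over cells: Pc(T|c) = P(T|c) - mean_c' P(T|c').

    Input rows (cells) must each sum to 1 within one layer; for pooled
    multi-layer tables each layer's column block must sum to 1 per row.
    After centering every column has zero mean and every row sums to zero
    (up to the number of pooled layers times zero).
    """
    if P.size == 0:
        raise AssignmentError("empty probability table")
    return P - P.mean(axis=0)


def cluster_topic_probability(Pc: pd.DataFrame, clusters: pd.Series) -> pd.DataFrame:
    """Mean of Pc(topic|cell) over the cells of each cluster."""
    missing = Pc.index.difference(clusters.index)
    if len(missing):
        raise AssignmentError(f"cells missing from cluster map: {list(missing)[:5]}")
    labels = clusters.reindex(Pc.index)
    grouped = Pc.groupby(labels).mean()
    unpopulated = set(clusters.unique()) - set(grouped.index)
    if unpopulated:
        raise AssignmentError(f"empty cluster(s): {sorted(map(str, unpopulated))}")
    grouped.index.name = "cluster"
    return grouped


def _grid_value(k: int, n_start: float, step: float) -> float:
    # exact decimal grid: avoids 3 - k*0.05 drifting past the intended value
    return round(n_start * 100 - k * round(step * 100)) / 100


@dataclass
class ClusterTopicAssignment:
    """Result of the adaptive thresholding loop."""

    pc_cluster: pd.DataFrame  # clusters x topics
    mu: pd.Series  # per-cluster mean of Pc across topics
    sigma: pd.Series  # per-cluster population std across topics
    n_final: float
    topic_sets: dict[str, frozenset[str]]

    def to_long(self) -> pd.DataFrame:
        """Heatmap-ready long table: cluster, topic, Pc value, final n."""
        rows = []
        for cluster, topics in self.topic_sets.items():
            for topic in sorted(topics):
                rows.append(
                    {
                        "cluster": cluster,
                        "topic": topic,
                        "pc": self.pc_cluster.loc[cluster, topic],
                        "n": self.n_final,
                    }
                )
        return pd.DataFrame(rows, columns=["cluster", "topic", "pc", "n"])


def assign_topics_to_clusters(
    pc_cluster: pd.DataFrame, n_start: float = 3.0, step: float = 0.05
) -> ClusterTopicAssignment:
    """Assign each cluster the topics with Pc(topic|cluster) > mu + n*sigma.

    ``pc_cluster`` is the clusters x topics table of centered probabilities
    (both layers' topics may be pooled column-wise; mu and sigma are then
    computed across the pooled topics).  Raises if the two feasibility
    conditions cannot be met by the time n reaches 0.
    """
    if pc_cluster.shape[0] < 1 or pc_cluster.shape[1] < 2:
        raise AssignmentError("need at least one cluster and two topics")
    values = pc_cluster.to_numpy(dtype=float)
    mu = values.mean(axis=1)
    sigma = values.std(axis=1)  # population (divide-by-N) std across topics

    n_steps = int(round(n_start / step))
    for k in range(n_steps + 1):
        n = _grid_value(k, n_start, step)
        thresh = mu + n * sigma
        mask = values > thresh[:, None]
        if not mask.any(axis=1).all():
            continue
        sets = [frozenset(pc_cluster.columns[row]) for row in mask]
        if len(set(sets)) != len(sets):
            continue
        topic_sets = {
            str(cluster): s for cluster, s in zip(pc_cluster.index, sets)
        }
        return ClusterTopicAssignment(
            pc_cluster=pc_cluster,
            mu=pd.Series(mu, index=pc_cluster.index),
            sigma=pd.Series(sigma, index=pc_cluster.index),
            n_final=n,
            topic_sets=topic_sets,
        )

    # diagnose the failure for the error message
    mask = values > mu[:, None]  # n = 0 thresholds
    empty = [str(c) for c, row in zip(pc_cluster.index, mask) if not row.any()]
    seen: dict[frozenset, list[str]] = {}
    for cluster, row in zip(pc_cluster.index, mask):
        seen.setdefault(frozenset(pc_cluster.columns[row]), []).append(str(cluster))
    dupes = [cs for cs in seen.values() if len(cs) > 1]
    raise AssignmentError(
        "adaptive thresholding failed at n=0: "
        f"clusters with no topic: {empty}; clusters with identical topic sets: {dupes}"
    )


def assign_from_level(level, clusters: pd.Series | None = None,
                      n_start: float = 3.0, step: float = 0.05) -> ClusterTopicAssignment:
    """Run the full centering -> cluster mean -> adaptive threshold chain.

    ``level`` is a :class:`~celltopics.topic_extract.LevelTopics`; topics of
    all layers are pooled column-wise, mirroring the mixed mRNA-/lncRNA-topic
    assignment of the tripartite model.  ``clusters`` defaults to the level's
    own hard cell clusters but any cell partition may be supplied.
    """
    P = level.pooled_topic_cell()
    Pc = center_topic_distribution(P)
    cl = clusters if clusters is not None else level.clusters
    pc_cluster = cluster_topic_probability(Pc, cl)
    return assign_topics_to_clusters(pc_cluster, n_start=n_start, step=step)
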
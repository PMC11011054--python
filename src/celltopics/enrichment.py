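"""Hypergeometric gene-set enrichment of topics with BH correction.

Topics (gene blocks) are tested against gene-set collections.  Before
testing, each collection is pruned of its extremely large sets: a set whose
size exceeds 15% of the distinct genes in its own collection is dominated by
unspecific content and is filtered out (a fast approximation of pairwise
Jaccard-redundancy pruning).  Enrichment p-values are upper-tail
hypergeometric probabilities; q-values are Benjamini-Hochberg adjusted within
each topic's family of tests.  Each assigned topic is finally summarized by
its most enriched set, with a set allowed to label only the topic where it is
most significant.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .data_io import GeneSetCollection

UNANNOTATED = "unannotated"


def filter_gene_sets(
    collection: GeneSetCollection, max_ratio: float = 0.15
) -> GeneSetCollection:
    """Drop sets with |set| / total collection genes strictly above ``max_ratio``.

    The denominator is the number of distinct genes of the *original*
    collection; the boundary case (ratio exactly ``max_ratio``) is kept.
    """
    if len(collection.sets) == 0:
        raise ValueError("empty collection")
    total = collection.total_genes
    kept = {
        name: members
        for name, members in collection.sets.items()
        if len(members) / total <= max_ratio
    }
    if not kept:
        warnings.warn(
            f"collection {collection.collection_name!r}: no gene set passes "
            f"max_ratio={max_ratio}; returning an empty collection"
        )
    return GeneSetCollection(collection.collection_name, kept)


def hypergeometric_enrich(
    topic_genes: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric p-value of each set's overlap with the topic.

    With N = |universe|, K = |set ∩ universe|, n = |topic ∩ universe| and
    k = |topic ∩ set ∩ universe|, p = P(X >= k) for X ~ Hypergeom(N, K, n).
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    topic = frozenset(topic_genes) & universe
    N = len(universe)
    n = len(topic)
    rows = []
    for name, members in collection.sets.items():
        members_u = members & universe
        K = len(members_u)
        k = len(topic & members_u)
        p = 1.0 if k == 0 else float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "gene_set": name,
                "collection": collection.collection_name,
                "overlap": k,
                "set_size": K,
                "topic_size": n,
                "universe_size": N,
                "p_value": min(p, 1.0),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_set", "collection", "overlap", "set_size",
            "topic_size", "universe_size", "p_value",
        ],
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def enrich_topics(
    topic_to_genes: Mapping[str, Iterable[str]],
    collections: Sequence[GeneSetCollection] | GeneSetCollection,
    universe: Iterable[str],
    max_ratio: float = 0.15,
) -> pd.DataFrame:
    """Test every topic against every (filtered) collection.

    Returns the long table of EnrichmentResult rows with BH q-values adjusted
    within each topic's family of tests.
    """
    if isinstance(collections, GeneSetCollection):
        collections = [collections]
    filtered = [filter_gene_sets(c, max_ratio=max_ratio) for c in collections]
    frames = []
    for topic, genes in topic_to_genes.items():
        parts = [
            hypergeometric_enrich(genes, c, universe) for c in filtered if len(c.sets)
        ]
        if not parts:
            continue
        df = pd.concat(parts, ignore_index=True)
        df.insert(0, "topic", topic)
        df["q_value"] = bh_adjust(df["p_value"].to_numpy())
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=[
                "topic", "gene_set", "collection", "overlap", "set_size",
                "topic_size", "universe_size", "p_value", "q_value",
            ]
        )
    return pd.concat(frames, ignore_index=True)


def summarize_topic_annotations(
    results: pd.DataFrame, fdr_threshold: float = 0.05
) -> pd.Series:
    """Label each topic with its most enriched gene set (min q-value).

    A gene set may label only one topic: when several topics share the same
    best set, the topic with the smallest q keeps it and the others fall back
    to their next-best set.  Ties break by larger overlap, then lexicographic
    set name, then topic name (determinism).  Topics with no set under
    ``fdr_threshold`` are labeled ``"unannotated"``.
    """
    topics = sorted(results["topic"].unique()) if len(results) else []
    sig = results[results["q_value"] <= fdr_threshold] if len(results) else results
    claims = sorted(
        (float(r.q_value), -int(r.overlap), str(r.gene_set), str(r.topic))
        for r in sig.itertuples()
    )
    assigned: dict[str, str] = {}
    taken: set[str] = set()
    # global greedy in q order: a topic's label is its best still-free set,
    # and a contested set goes to the topic where it is most significant
    for _, _, name, topic in claims:
        if topic in assigned or name in taken:
            continue
        assigned[topic] = name
        taken.add(name)
    for topic in topics:
        assigned.setdefault(str(topic), UNANNOTATED)
    return pd.Series(assigned, name="annotation").reindex([str(t) for t in topics])
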
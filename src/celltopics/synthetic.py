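"""Synthetic two-layer single-cell count data with planted structure.

The generator emulates a four-population breast-cancer PDX design: two tumor
subtypes (luminal-like and basal-like), each present as a drug-sensitive and
a drug-resistant population, profiled in two omics layers that share the same
cells (an mRNA-like layer and a lncRNA-like layer with higher per-gene
coefficient of variation).  Topic structure is planted explicitly: genes are
partitioned into topics, each population mixes topics with its own affinity
weights, and counts are multinomial draws (layer 1) or gamma-perturbed
multinomial draws (layer 2, overdispersed).

The default affinities make the layers *complementary*: layer 1 separates the
subtypes strongly and the resistance axis only weakly, while layer 2 strongly
separates resistance within the luminal-like subtype.  Neither layer alone
resolves all four populations; together they do -- mirroring the motivation
for the multipartite model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import CountLayer

DEFAULT_GROUPS = ("LumS", "LumR", "TnbS", "TnbR")

# rows: groups in DEFAULT_GROUPS order; columns: topics of the layer.
# Layer 1 (mRNA-like): [luminal program, basal program, resistance program,
# housekeeping].  Subtypes split strongly, resistance only weakly.
DEFAULT_AFFINITY_1 = np.array(
    [
        [6.0, 0.3, 0.3, 3.0],
        [6.0, 0.3, 1.2, 3.0],
        [0.3, 6.0, 0.3, 3.0],
        [0.3, 6.0, 1.2, 3.0],
    ]
)
# Layer 2 (lncRNA-like): [luminal identity, basal identity, luminal-resistance
# program, housekeeping].  Resistance splits strongly within the luminal
# subtype only, weakly in the basal one.
DEFAULT_AFFINITY_2 = np.array(
    [
        [5.0, 0.3, 0.3, 3.0],
        [1.0, 0.3, 6.0, 3.0],
        [0.3, 5.0, 0.3, 3.0],
        [0.3, 5.0, 1.2, 3.0],
    ]
)


@dataclass
class SyntheticSpec:
    """Stated world of the generator; defaults follow the emulated design."""

    n_cells_per_group: tuple[int, ...] = (50, 50, 50, 50)
    group_names: tuple[str, ...] = DEFAULT_GROUPS
    n_genes: tuple[int, int] = (200, 150)
    n_topics: tuple[int, int] = (4, 4)
    layer_names: tuple[str, str] = ("mrna", "lncrna")
    affinities: tuple[np.ndarray, np.ndarray] | None = None
    dispersions: tuple[float, float] = (0.0, 0.4)
    depth_range: tuple[int, int] = (800, 1200)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_cells_per_group) != len(self.group_names):
            raise ValueError("group sizes and names disagree")
        if any(n < 2 for n in self.n_cells_per_group):
            raise ValueError("each group needs at least 2 cells")
        if any(t > g for t, g in zip(self.n_topics, self.n_genes)):
            raise ValueError("more topics than genes in a layer")
        if self.depth_range[0] <= 0 or self.depth_range[1] < self.depth_range[0]:
            raise ValueError("invalid sequencing depth range")
        if any(d < 0 for d in self.dispersions):
            raise ValueError("dispersions must be >= 0")
        if self.affinities is not None:
            for aff, k in zip(self.affinities, self.n_topics):
                aff = np.asarray(aff)
                if aff.shape != (len(self.group_names), k):
                    raise ValueError("affinity matrix shape mismatch")
                if (aff < 0).any():
                    raise ValueError("affinities must be >= 0")

    def affinity(self, layer_idx: int) -> np.ndarray:
        if self.affinities is not None:
            return np.asarray(self.affinities[layer_idx], dtype=float)
        default = DEFAULT_AFFINITY_1 if layer_idx == 0 else DEFAULT_AFFINITY_2
        if default.shape == (len(self.group_names), self.n_topics[layer_idx]):
            return default
        # non-default geometry: one dominant topic per group, cycling
        g, k = len(self.group_names), self.n_topics[layer_idx]
        aff = np.full((g, k), 0.3)
        for i in range(g):
            aff[i, i % k] = 6.0
        return aff


def _topic_gene_profiles(
    n_genes: int, n_topics: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Split genes into contiguous topics; Dirichlet profile inside each."""
    topic_of_gene = np.repeat(np.arange(n_topics), np.diff(
        np.linspace(0, n_genes, n_topics + 1).astype(int)
    ))
    phi = np.zeros((n_topics, n_genes))
    for t in range(n_topics):
        members = np.flatnonzero(topic_of_gene == t)
        phi[t, members] = rng.dirichlet(np.ones(len(members)))
    return topic_of_gene, phi


def _draw_layer(
    layer_idx: int,
    spec: SyntheticSpec,
    group_of_cell: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    n_genes = spec.n_genes[layer_idx]
    n_topics = spec.n_topics[layer_idx]
    disp = spec.dispersions[layer_idx]
    topic_of_gene, phi = _topic_gene_profiles(n_genes, n_topics, rng)
    aff = spec.affinity(layer_idx)
    weights = aff / aff.sum(axis=1, keepdims=True)
    group_probs = weights @ phi  # groups x genes

    n_cells = len(group_of_cell)
    counts = np.zeros((n_genes, n_cells), dtype=np.int64)
    depths = rng.integers(spec.depth_range[0], spec.depth_range[1] + 1, size=n_cells)
    for c in range(n_cells):
        p = group_probs[group_of_cell[c]]
        if disp > 0:
            # per-cell gamma multipliers on gene rates (mean 1, var = disp)
            lam = p * rng.gamma(shape=1.0 / disp, scale=disp, size=n_genes)
            total = lam.sum()
            p = lam / total if total > 0 else p
        counts[:, c] = rng.multinomial(depths[c], p)
    return counts, topic_of_gene


def generate(
    spec: SyntheticSpec | None = None,
) -> tuple[CountLayer, CountLayer, pd.Series, dict[str, pd.Series]]:
    """Draw the two count layers with planted groups and topics.

    Returns ``(layer1, layer2, group_labels, gene_topic_truth)`` where
    ``group_labels`` maps cell id to its planted population and
    ``gene_topic_truth`` maps, per layer, gene id to its planted topic.
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    group_of_cell = np.repeat(
        np.arange(len(spec.group_names)), spec.n_cells_per_group
    )
    cells = [f"cell{i:04d}" for i in range(len(group_of_cell))]
    labels = pd.Series(
        [spec.group_names[g] for g in group_of_cell], index=cells, name="group"
    )

    layers: list[CountLayer] = []
    truth: dict[str, pd.Series] = {}
    for li, lname in enumerate(spec.layer_names):
        counts, topic_of_gene = _draw_layer(li, spec, group_of_cell, rng)
        genes = [f"{lname}_g{j:04d}" for j in range(spec.n_genes[li])]
        layers.append(CountLayer(lname, genes, cells, counts.astype(float)))
        truth[lname] = pd.Series(topic_of_gene, index=genes, name="topic")
    return layers[0], layers[1], labels, truth


def complementary_spec(seed: int = 0) -> SyntheticSpec:
    """A scaled-down spec whose layers carry strictly complementary signal.

    The two population axes are crossed over the layers: layer 1 separates
    the tumor subtypes only (the resistance axis is invisible in it), layer 2
    separates sensitive from resistant only.  Neither layer alone resolves
    the four populations; the joint (tripartite) fit does.  Mild
    overdispersion in both layers adds the within-population heterogeneity
    that keeps single-layer fits from looking artificially clean.  Sized to
    fit a laptop-scale benchmark (120 cells, 60 genes per layer).
    """
    subtype_only = np.array(
        [
            [6.0, 0.3, 0.5, 3.0],
            [6.0, 0.3, 0.5, 3.0],
            [0.3, 6.0, 0.5, 3.0],
            [0.3, 6.0, 0.5, 3.0],
        ]
    )
    resistance_only = np.array(
        [
            [6.0, 0.3, 0.5, 3.0],
            [0.3, 6.0, 0.5, 3.0],
            [6.0, 0.3, 0.5, 3.0],
            [0.3, 6.0, 0.5, 3.0],
        ]
    )
    return SyntheticSpec(
        n_cells_per_group=(30, 30, 30, 30),
        n_genes=(60, 60),
        depth_range=(400, 600),
        dispersions=(0.15, 0.25),
        affinities=(subtype_only, resistance_only),
        seed=seed,
    )


def planted_partition_layer(
    n_cells: int = 200,
    n_genes: int = 100,
    n_cell_blocks: int = 4,
    n_gene_blocks: int = 4,
    rate_in: float = 5.0,
    rate_out: float = 0.5,
    seed: int = 0,
    layer_name: str = "planted",
) -> tuple[CountLayer, pd.Series, pd.Series]:
    """Bipartite planted-partition counts: aligned blocks get ``rate_in``.

    Cell block j is wired to gene block (j mod n_gene_blocks); counts are
    Poisson with the within-block rate (default 10x the background rate).
    Returns the layer plus the planted cell and gene block labels.
    """
    rng = np.random.default_rng(seed)
    cell_block = np.repeat(np.arange(n_cell_blocks), -(-n_cells // n_cell_blocks))[:n_cells]
    gene_block = np.repeat(np.arange(n_gene_blocks), -(-n_genes // n_gene_blocks))[:n_genes]
    aligned = gene_block[:, None] == (cell_block[None, :] % n_gene_blocks)
    rates = np.where(aligned, rate_in, rate_out)
    counts = rng.poisson(rates).astype(float)
    genes = [f"{layer_name}_g{j:04d}" for j in range(n_genes)]
    cells = [f"cell{i:04d}" for i in range(n_cells)]
    return (
        CountLayer(layer_name, genes, cells, counts),
        pd.Series(cell_block, index=cells, name="cell_block"),
        pd.Series(gene_block, index=genes, name="gene_block"),
    )


def per_gene_cv(layer: CountLayer) -> np.ndarray:
    """Coefficient of variation per gene (genes with zero mean excluded)."""
    mean = layer.counts.mean(axis=1)
    sd = layer.counts.std(axis=1)
    pos = mean > 0
    return sd[pos] / mean[pos]
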
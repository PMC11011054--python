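"""Pre-processing and assembly of the gene-cell multigraph.

Cells and genes become nodes of a weighted multigraph; a gene-cell edge with
integer multiplicity w encodes w observed transcripts of that gene in that
cell.  With one count layer the graph is bipartite; with two (e.g. mRNA and
lncRNA) it is tripartite, the layers sharing the cell nodes and never linking
gene to gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse

from .data_io import CountLayer, ValidationError

CELL_TYPE = 0  # node-type index reserved for cells


class GraphBuildError(ValueError):
    pass


@dataclass
class HeterogeneousGraph:
    """Typed weighted multigraph over cell and per-layer gene nodes.

    Node ids are 0..N-1 with cells first, then each layer's genes in order.
    ``node_type`` maps a node to an index into ``type_names`` where entry 0 is
    always ``"cell"`` and the others are ``"gene@<layer>"``.  The adjacency is
    a symmetric CSR structure (``indptr``, ``indices``, ``weights``); edge
    weights are integer multiplicities.
    """

    node_names: np.ndarray
    node_type: np.ndarray
    type_names: list[str]
    indptr: np.ndarray
    indices: np.ndarray
    weights: np.ndarray
    layer_matrices: dict[str, scipy.sparse.csr_matrix] = field(default_factory=dict)
    gene_ranges: dict[str, tuple[int, int]] = field(default_factory=dict)
    dropped_cells: list[str] = field(default_factory=list)
    dropped_genes: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # degree = total incident multiplicity
        src = np.repeat(np.arange(self.n_nodes), np.diff(self.indptr))
        self.degrees = np.bincount(src, weights=self.weights, minlength=self.n_nodes).astype(
            np.int64
        )
        self.E = int(self.degrees.sum() // 2)
        # per-node degree split by the *opposite* endpoint's type
        self.deg_by_type = np.zeros((self.n_nodes, self.n_types), dtype=np.int64)
        np.add.at(self.deg_by_type, (src, self.node_type[self.indices]), self.weights)

    # -- basic accessors -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    @property
    def n_types(self) -> int:
        return len(self.type_names)

    def nodes_of_type(self, t: int) -> np.ndarray:
        return np.flatnonzero(self.node_type == t)

    def type_counts(self) -> np.ndarray:
        return np.bincount(self.node_type, minlength=self.n_types)

    def layer_edge_total(self, t: int) -> int:
        """Total multiplicity of edges incident to nodes of gene type ``t``."""
        return int(self.degrees[self.node_type == t].sum())

    @property
    def cells(self) -> np.ndarray:
        return self.node_names[self.node_type == CELL_TYPE]

    def genes(self, layer: str) -> np.ndarray:
        lo, hi = self.gene_ranges[layer]
        return self.node_names[lo:hi]

    def neighbors(self, v: int) -> tuple[np.ndarray, np.ndarray]:
        sl = slice(self.indptr[v], self.indptr[v + 1])
        return self.indices[sl], self.weights[sl]

    def validate(self) -> None:
        """Check multipartiteness and degree bookkeeping."""
        src = np.repeat(np.arange(self.n_nodes), np.diff(self.indptr))
        ts, td = self.node_type[src], self.node_type[self.indices]
        if np.any((ts == CELL_TYPE) == (td == CELL_TYPE)):
            raise ValidationError("edge connects two nodes on the same side (cell-cell or gene-gene)")
        if (self.weights < 1).any():
            raise ValidationError("edge multiplicities must be >= 1")
        if (self.degrees == 0).any():
            raise ValidationError("zero-degree node present")
        if int(self.degrees.sum()) != 2 * self.E:
            raise ValidationError("sum of degrees != 2E")

    @classmethod
    def from_edges(
        cls,
        node_names,
        node_type,
        type_names,
        edges,  # iterable of (u, v, w)
        **kwargs,
    ) -> "HeterogeneousGraph":
        """Build the symmetric CSR adjacency from an edge multiset."""
        n = len(node_names)
        rows, cols, vals = [], [], []
        for u, v, w in edges:
            rows.extend((u, v))
            cols.extend((v, u))
            vals.extend((w, w))
        adj = scipy.sparse.csr_matrix(
            (np.asarray(vals, dtype=np.int64), (rows, cols)), shape=(n, n)
        )
        adj.sum_duplicates()
        return cls(
            node_names=np.asarray(node_names, dtype=object),
            node_type=np.asarray(node_type, dtype=np.int64),
            type_names=list(type_names),
            indptr=adj.indptr.astype(np.int64),
            indices=adj.indices.astype(np.int64),
            weights=adj.data.astype(np.int64),
            **kwargs,
        )


def normalize_library_size(layer: CountLayer, target_sum: float = 1e4) -> CountLayer:
    """Scale each cell's counts so its column sums to ``target_sum``.

    Cells with zero total count are dropped with a warning; an all-zero layer
    is an error.
    """
    totals = layer.counts.sum(axis=0)
    nonzero = totals > 0
    if not nonzero.any():
        raise GraphBuildError(f"layer {layer.layer_name!r} is all zeros")
    if not nonzero.all():
        dropped = [c for c, ok in zip(layer.cells, nonzero) if not ok]
        warnings.warn(
            f"dropping {len(dropped)} zero-count cell(s) from layer {layer.layer_name!r}"
        )
        layer = layer.subset_cells(nonzero)
        totals = totals[nonzero]
    scaled = layer.counts * (target_sum / totals)[None, :]
    return CountLayer(layer.layer_name, list(layer.genes), list(layer.cells), scaled)


def normalized_dispersion(layer: CountLayer, n_bins: int = 20) -> np.ndarray:
    """Per-gene dispersion (variance/mean), z-scored within mean bins.

    Genes with zero mean get dispersion 0; bins whose dispersions have zero
    spread yield z-scores of 0 (a flat gene can then never pass a positive
    threshold).
    """
    mean = layer.counts.mean(axis=1)
    var = layer.counts.var(axis=1)
    disp = np.zeros_like(mean)
    pos = mean > 0
    disp[pos] = var[pos] / mean[pos]

    if len(np.unique(mean)) < n_bins:
        warnings.warn("fewer distinct gene means than bins; falling back to a single bin")
        bins = np.zeros(len(mean), dtype=int)
    else:
        # equal-frequency bins on the mean, mirroring binned HVG selection
        quantiles = np.quantile(mean, np.linspace(0, 1, n_bins + 1))
        quantiles[0] -= 1e-12
        bins = np.searchsorted(quantiles, mean, side="right") - 1
        bins = np.clip(bins, 0, n_bins - 1)

    z = np.zeros_like(disp)
    for b in np.unique(bins):
        sel = bins == b
        mu, sd = disp[sel].mean(), disp[sel].std()
        if sd > 0:
            z[sel] = (disp[sel] - mu) / sd
    return z


def select_highly_variable(
    layer: CountLayer, min_disp: float = 0.5, n_bins: int = 20
) -> CountLayer:
    """Keep genes whose binned normalized dispersion exceeds ``min_disp``."""
    if layer.n_cells < 2:
        raise GraphBuildError("highly-variable selection needs at least 2 cells")
    z = normalized_dispersion(layer, n_bins=n_bins)
    keep = z > min_disp
    if not keep.any():
        raise GraphBuildError(
            f"no gene exceeds min_disp={min_disp} in layer {layer.layer_name!r}"
        )
    return layer.subset_genes(keep)


def _discretize(counts: np.ndarray, weight_mode: str) -> np.ndarray:
    if weight_mode == "raw-integer":
        rounded = np.rint(counts)
        if not np.allclose(counts, rounded, atol=1e-8):
            raise GraphBuildError(
                "weight_mode='raw-integer' requires integer-valued counts; "
                "use 'round' or 'floor' for normalized data"
            )
        return rounded.astype(np.int64)
    if weight_mode == "round":
        return np.rint(counts).astype(np.int64)  # round half to even
    if weight_mode == "floor":
        return np.floor(counts).astype(np.int64)
    raise GraphBuildError(f"unknown weight_mode: {weight_mode!r}")


def build_graph(
    layers: CountLayer | list[CountLayer],
    weight_mode: str = "raw-integer",
) -> HeterogeneousGraph:
    """Assemble the bipartite/tripartite multigraph from one or two layers.

    Edge multiplicity is the discretized count; entries discretizing to zero
    produce no edge.  Genes and cells left with zero degree are removed and
    reported in the graph's ``dropped_*`` manifest so downstream cluster
    tables stay aligned.
    """
    if isinstance(layers, CountLayer):
        layers = [layers]
    if not layers:
        raise GraphBuildError("need at least one layer")
    names = [l.layer_name for l in layers]
    if len(set(names)) != len(names):
        raise GraphBuildError("layer names must be distinct")
    cell_list = layers[0].cells
    for l in layers[1:]:
        if l.cells != cell_list:
            raise GraphBuildError("all layers must share an identical cell list")

    mats = {l.layer_name: _discretize(l.counts, weight_mode) for l in layers}

    cell_deg = np.zeros(len(cell_list), dtype=np.int64)
    for m in mats.values():
        cell_deg += m.sum(axis=0)
    keep_cells = cell_deg > 0
    dropped_cells = [c for c, ok in zip(cell_list, keep_cells) if not ok]

    kept_layers: list[tuple[str, list[str], np.ndarray]] = []
    dropped_genes: dict[str, list[str]] = {}
    for l in layers:
        m = mats[l.layer_name][:, keep_cells]
        keep_genes = m.sum(axis=1) > 0
        dropped_genes[l.layer_name] = [g for g, ok in zip(l.genes, keep_genes) if not ok]
        kept_names = [g for g, ok in zip(l.genes, keep_genes) if ok]
        kept_layers.append((l.layer_name, kept_names, m[keep_genes]))

    n_cells = int(keep_cells.sum())
    if n_cells == 0 or all(m.shape[0] == 0 for _, _, m in kept_layers):
        raise GraphBuildError("graph is empty after discretization")

    node_names: list[str] = [c for c, ok in zip(cell_list, keep_cells) if ok]
    node_type: list[int] = [CELL_TYPE] * n_cells
    type_names = ["cell"]
    gene_ranges: dict[str, tuple[int, int]] = {}
    layer_matrices: dict[str, scipy.sparse.csr_matrix] = {}
    edges: list[tuple[int, int, int]] = []

    offset = n_cells
    for t, (lname, kept_gene_names, m) in enumerate(kept_layers, start=1):
        type_names.append(f"gene@{lname}")
        gene_ranges[lname] = (offset, offset + m.shape[0])
        node_names.extend(kept_gene_names)
        node_type.extend([t] * m.shape[0])
        gi, ci = np.nonzero(m)
        for g, c in zip(gi, ci):
            edges.append((offset + int(g), int(c), int(m[g, c])))
        layer_matrices[lname] = scipy.sparse.csr_matrix(m.T)  # cells x genes
        offset += m.shape[0]

    g = HeterogeneousGraph.from_edges(
        node_names,
        node_type,
        type_names,
        edges,
        layer_matrices=layer_matrices,
        gene_ranges=gene_ranges,
        dropped_cells=dropped_cells,
        dropped_genes=dropped_genes,
    )
    g.validate()
    return g


def block_graph(state) -> tuple[HeterogeneousGraph, np.ndarray]:
    """Condense a fitted block state into its block-level multigraph.

    Returns the condensed graph plus an array mapping each node of the
    original graph to its node id in the condensed graph.  Used to build the
    agglomerative hierarchy: blocks become nodes, block-to-block edge counts
    become multiplicities.
    """
    g = state.g
    blocks = state.nonempty_blocks()
    # order: cell blocks first, then gene blocks by type then id
    blocks = sorted(blocks, key=lambda b: (state.btype[b], b))
    remap = {b: i for i, b in enumerate(blocks)}
    node_map = np.array([remap[b] for b in state.b], dtype=np.int64)
    node_type = np.array([state.btype[b] for b in blocks], dtype=np.int64)
    node_names = np.array([f"block{b}" for b in blocks], dtype=object)
    edges = []
    for r in blocks:
        if state.btype[r] != CELL_TYPE:
            continue
        for s, w in state.m[r].items():
            edges.append((remap[r], remap[s], int(w)))
    gene_ranges: dict[str, tuple[int, int]] = {}
    for t in range(1, g.n_types):
        sel = np.flatnonzero(node_type == t)
        if len(sel):
            layer = g.type_names[t].split("@", 1)[1]
            gene_ranges[layer] = (int(sel[0]), int(sel[-1]) + 1)
    bg = HeterogeneousGraph.from_edges(
        node_names, node_type, g.type_names, edges, gene_ranges=gene_ranges
    )
    return bg, node_map
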
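"""Readers and writers for count matrices, gene-set collections and results.

Count layers are stored either as Matrix Market triplet files with plain-text
companion name files (``<stem>_genes.txt`` / ``<stem>_cells.txt``) or as dense
tab/comma-delimited tables with genes on rows and cells on columns.  Gene-set
collections use the GMT format.  All pipeline outputs are TSV plus one JSON
metadata record, so that every artifact stays plain text.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class LoadError(ValueError):
    """Raised when an input file cannot be interpreted."""


class ValidationError(ValueError):
    """Raised when loaded data violates a container invariant."""


@dataclass
class CountLayer:
    """One omics layer: a genes x cells non-negative count matrix.

    Parameters
    ----------
    layer_name:
        Text label for the layer (e.g. ``"mrna"`` or ``"lncrna"``).
    genes, cells:
        Ordered, unique identifiers.  Identifiers are opaque strings; no
        Ensembl-version stripping is performed.
    counts:
        Dense ``(n_genes, n_cells)`` array of non-negative values.
    """

    layer_name: str
    genes: list[str]
    cells: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        self.cells = [str(c) for c in self.cells]
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise LoadError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"duplicate gene identifiers in layer {self.layer_name!r}")
        if len(set(self.cells)) != len(self.cells):
            raise ValidationError(f"duplicate cell identifiers in layer {self.layer_name!r}")
        if not np.all(np.isfinite(self.counts)):
            raise ValidationError("counts contain non-finite values")
        if (self.counts < 0).any():
            raise ValidationError("counts contain negative entries")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genes, columns=self.cells)

    def subset_genes(self, keep: Sequence[str] | np.ndarray) -> "CountLayer":
        """Return a copy restricted to ``keep`` (names or boolean mask)."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {g: i for i, g in enumerate(self.genes)}
            idx = np.array([pos[g] for g in keep], dtype=int)
        return CountLayer(
            self.layer_name,
            [self.genes[i] for i in idx],
            list(self.cells),
            self.counts[idx, :].copy(),
        )

    def subset_cells(self, keep: Sequence[str] | np.ndarray) -> "CountLayer":
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {c: i for i, c in enumerate(self.cells)}
            idx = np.array([pos[c] for c in keep], dtype=int)
        return CountLayer(
            self.layer_name,
            list(self.genes),
            [self.cells[i] for i in idx],
            self.counts[:, idx].copy(),
        )


@dataclass
class GeneSetCollection:
    """A named collection of gene sets (one GMT file)."""

    collection_name: str
    sets: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValidationError(f"gene set {name!r} is empty")

    @property
    def total_genes(self) -> int:
        """Number of distinct genes across the whole collection."""
        return len(self.gene_union())

    def gene_union(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.sets)


def _read_names(path: Path) -> list[str]:
    names = [line.strip() for line in path.read_text().splitlines() if line.strip()]
    return names


def read_count_layer(
    path: str | Path,
    format: str = "mtx-triplet",
    layer_name: str | None = None,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
    sep: str | None = None,
) -> CountLayer:
    """Read one count layer from disk, normalized to genes x cells orientation.

    For ``mtx-triplet`` the companion name files default to
    ``<stem>_genes.txt`` and ``<stem>_cells.txt`` next to the matrix.  The
    stored orientation is auto-detected from the name-file lengths; a square
    matrix with no matching dimension ordering is ambiguous and rejected.
    For ``delimited``, rows are genes and columns are cells (header row =
    cell ids, first column = gene ids).
    """
    path = Path(path)
    if not path.exists():
        raise LoadError(f"count file not found: {path}")
    name = layer_name if layer_name is not None else path.stem

    if format == "mtx-triplet":
        gpath = Path(genes_path) if genes_path else path.with_name(path.stem + "_genes.txt")
        cpath = Path(cells_path) if cells_path else path.with_name(path.stem + "_cells.txt")
        if not gpath.exists() or not cpath.exists():
            raise LoadError(f"companion name files missing for {path}")
        genes = _read_names(gpath)
        cells = _read_names(cpath)
        mat = scipy.io.mmread(str(path))
        mat = scipy.sparse.coo_matrix(mat)
        shape = mat.shape
        if shape == (len(genes), len(cells)):
            if len(genes) == len(cells):
                raise LoadError(
                    f"square matrix {shape}: orientation ambiguous, cannot auto-detect"
                )
            dense = np.asarray(mat.todense(), dtype=float)
        elif shape == (len(cells), len(genes)):
            dense = np.asarray(mat.T.todense(), dtype=float)
        else:
            raise LoadError(
                f"matrix shape {shape} matches neither {len(genes)} genes x "
                f"{len(cells)} cells nor its transpose"
            )
        return CountLayer(name, genes, cells, dense)

    if format == "delimited":
        df = pd.read_csv(path, sep=sep, index_col=0, engine="python")
        return CountLayer(
            name,
            [str(g) for g in df.index],
            [str(c) for c in df.columns],
            df.to_numpy(dtype=float),
        )

    raise LoadError(f"unknown count format: {format!r}")


def write_count_layer(layer: CountLayer, path: str | Path, format: str = "mtx-triplet") -> list[Path]:
    """Write a layer to disk in a format ``read_count_layer`` can load back."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "mtx-triplet":
        gpath = path.with_name(path.stem + "_genes.txt")
        cpath = path.with_name(path.stem + "_cells.txt")
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(layer.counts))
        gpath.write_text("\n".join(layer.genes) + "\n")
        cpath.write_text("\n".join(layer.cells) + "\n")
        return [path, gpath, cpath]
    if format == "delimited":
        layer.to_frame().to_csv(path, sep="\t")
        return [path]
    raise LoadError(f"unknown count format: {format!r}")


def read_gene_sets(path: str | Path, collection_name: str | None = None) -> GeneSetCollection:
    """Parse a GMT file (tab-separated: name, description, members...)."""
    path = Path(path)
    if not path.exists():
        raise LoadError(f"GMT file not found: {path}")
    name = collection_name if collection_name is not None else path.stem
    sets: dict[str, frozenset[str]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        set_name = parts[0].strip()
        members = frozenset(m.strip() for m in parts[2:] if m.strip())
        if not members:
            warnings.warn(f"{path.name}:{lineno}: gene set {set_name!r} is empty, skipped")
            continue
        if set_name in sets:
            raise LoadError(f"{path.name}:{lineno}: duplicate gene set name {set_name!r}")
        sets[set_name] = members
    return GeneSetCollection(name, sets)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [
        "\t".join([name, collection.collection_name] + sorted(members))
        for name, members in collection.sets.items()
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column TSV of cell id -> label."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].astype(str)


def write_results(
    result,
    assignment=None,
    out_dir: str | Path = ".",
    metadata: Mapping | None = None,
    create: bool = True,
) -> list[Path]:
    """Write a fitted topic model (and optional cluster-topic assignment).

    Emits, per hierarchy level and layer, ``L{level}_gene_topic_{layer}.tsv``
    and ``L{level}_topic_cell_{layer}.tsv``, plus ``L{level}_clusters.tsv``,
    the long-format assignment table, and ``run_metadata.json``.  Returns the
    manifest of written paths.
    """
    out_dir = Path(out_dir)
    if not out_dir.exists():
        if create:
            out_dir.mkdir(parents=True)
        else:
            raise IOError(f"output directory does not exist: {out_dir}")
    manifest: list[Path] = []

    for level in result.levels:
        for layer, table in level.gene_topic.items():
            p = out_dir / f"L{level.level}_gene_topic_{layer}.tsv"
            table.to_csv(p, sep="\t", float_format="%.17g")
            manifest.append(p)
        for layer, table in level.topic_cell.items():
            p = out_dir / f"L{level.level}_topic_cell_{layer}.tsv"
            table.to_csv(p, sep="\t", float_format="%.17g")
            manifest.append(p)
        p = out_dir / f"L{level.level}_clusters.tsv"
        level.clusters.rename("cluster").to_csv(p, sep="\t")
        manifest.append(p)

    if assignment is not None:
        p = out_dir / "cluster_topic_assignment.tsv"
        assignment.to_long().to_csv(p, sep="\t", index=False, float_format="%.17g")
        manifest.append(p)

    meta = dict(metadata or {})
    p = out_dir / "run_metadata.json"
    p.write_text(json.dumps(meta, indent=2, default=str) + "\n")
    manifest.append(p)
    return manifest


def read_probability_table(path: str | Path) -> pd.DataFrame:
    """Read back a probability table written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", index_col=0)
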
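"""Input/output for count matrices and gene-set collections, plus QC.

Count matrices are genes x cells with non-negative integer entries, read
either from a MatrixMarket triplet (matrix.mtx + features.tsv +
barcodes.tsv, the convention used by droplet pipelines) or from a dense
genes-in-rows TSV/CSV whose header carries the cell identifiers. Gene-set
collections use the GMT format (one set per tab-separated line: name,
description, member genes).

QC follows the standard two-step filter: drop cells detecting fewer than a
minimum number of genes, then drop genes left with zero total count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger("spherotype")

__all__ = [
    "CountMatrix",
    "GeneSet",
    "GeneSetCollection",
    "read_counts",
    "write_counts",
    "read_gmt",
    "write_gmt",
    "filter_qc",
]


@dataclass
class CountMatrix:
    """Genes x cells integer count matrix with a per-cell timepoint label."""

    counts: np.ndarray  # (n_genes, n_cells), non-negative integers
    gene_ids: list[str]
    cell_ids: list[str]
    timepoint: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D genes x cells matrix")
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"gene id count {len(self.gene_ids)} does not match "
                f"matrix rows {n_genes}"
            )
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"cell id count {len(self.cell_ids)} does not match "
                f"matrix columns {n_cells}"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene ids")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("duplicate cell ids")
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("negative counts")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("non-integer counts")
            self.counts = self.counts.astype(np.int64)
        if not self.timepoint:
            self.timepoint = ["NA"] * n_cells
        if len(self.timepoint) != n_cells:
            raise ValueError("one timepoint label required per cell")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]


@dataclass
class GeneSet:
    name: str
    description: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass
class GeneSetCollection:
    name: str
    sets: list[GeneSet]

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            raise ValueError("duplicate set names in collection")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)


# ---------------------------------------------------------------------------
# count-matrix readers/writers
# ---------------------------------------------------------------------------

def _read_id_file(path: Path) -> list[str]:
    # features.tsv may carry extra columns (ensembl id, symbol, type);
    # the first column is the identifier
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return df.iloc[:, 0].tolist()


def read_counts(
    path: str | Path,
    format: str = "dense",
    metadata: str | Path | None = None,
    barcode_timepoint_sep: str | None = None,
) -> CountMatrix:
    """Read a genes x cells count matrix.

    Parameters
    ----------
    path
        For ``format="mtx"``: the ``.mtx`` file, with ``features.tsv`` and
        ``barcodes.tsv`` alongside. For ``format="dense"``: a TSV/CSV with
        genes in rows, a header row of cell ids and the gene id as first
        column.
    metadata
        Optional TSV with columns ``cell_id`` and ``timepoint``.
    barcode_timepoint_sep
        If given, the timepoint is parsed from each barcode as the text
        after the last occurrence of this separator (e.g. ``"-"`` turns
        ``AAAC-D6`` into timepoint ``D6``).
    """
    path = Path(path)
    if format == "mtx":
        mat = spio.mmread(path)
        counts = np.asarray(sparse.coo_matrix(mat).todense())
        gene_ids = _read_id_file(path.parent / "features.tsv")
        cell_ids = _read_id_file(path.parent / "barcodes.tsv")
        if counts.shape[0] != len(gene_ids):
            raise ValueError(
                f"mtx has {counts.shape[0]} rows but features.tsv lists "
                f"{len(gene_ids)} genes"
            )
        if counts.shape[1] != len(cell_ids):
            raise ValueError(
                f"mtx has {counts.shape[1]} columns but barcodes.tsv lists "
                f"{len(cell_ids)} cells"
            )
    elif format == "dense":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        counts = df.to_numpy()
        gene_ids = [str(g) for g in df.index]
        cell_ids = [str(c) for c in df.columns]
    else:
        raise ValueError(f"unknown format {format!r}")

    if not np.allclose(counts, np.round(counts)):
        raise ValueError("count matrix contains non-integer entries")
    counts = counts.astype(np.int64)

    timepoint: list[str] = []
    if metadata is not None:
        meta = pd.read_csv(metadata, sep="\t", dtype=str).set_index("cell_id")
        timepoint = [meta.loc[c, "timepoint"] for c in cell_ids]
    elif barcode_timepoint_sep is not None:
        timepoint = [c.rsplit(barcode_timepoint_sep, 1)[-1] for c in cell_ids]

    return CountMatrix(counts, gene_ids, cell_ids, timepoint)


def write_counts(cm: CountMatrix, path: str | Path, format: str = "dense") -> None:
    """Write a count matrix in dense TSV/CSV or MatrixMarket triplet form."""
    path = Path(path)
    if format == "dense":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.DataFrame(cm.counts, index=cm.gene_ids, columns=cm.cell_ids)
        df.to_csv(path, sep=sep)
    elif format == "mtx":
        spio.mmwrite(path, sparse.coo_matrix(cm.counts), field="integer")
        pd.Series(cm.gene_ids).to_csv(
            path.parent / "features.tsv", sep="\t", header=False, index=False
        )
        pd.Series(cm.cell_ids).to_csv(
            path.parent / "barcodes.tsv", sep="\t", header=False, index=False
        )
    else:
        raise ValueError(f"unknown format {format!r}")


def write_cell_metadata(cm: CountMatrix, path: str | Path) -> None:
    pd.DataFrame({"cell_id": cm.cell_ids, "timepoint": cm.timepoint}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, name: str | None = None) -> GeneSetCollection:
    """Parse a GMT file into a collection; duplicate genes per line dedup."""
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one gene"
                )
            sets.append(GeneSet(fields[0], fields[1], frozenset(fields[2:])))
    return GeneSetCollection(name or path.stem, sets)


def write_gmt(gsc: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in gsc.sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.genes)]) + "\n")


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def filter_qc(cm: CountMatrix, min_genes_per_cell: int = 1000) -> CountMatrix:
    """Remove low-complexity cells, then all-zero genes.

    A cell is kept iff it detects (count > 0) at least ``min_genes_per_cell``
    genes; the default of 1000 reflects the usual lower bound for droplet
    scRNA-seq libraries. Genes with zero total count across the retained
    cells are then removed. Order of retained rows/columns is preserved.
    """
    genes_per_cell = (cm.counts > 0).sum(axis=0)
    keep_cells = genes_per_cell >= min_genes_per_cell
    if not keep_cells.any():
        raise ValueError(
            f"QC removed every cell (min_genes_per_cell={min_genes_per_cell})"
        )
    counts = cm.counts[:, keep_cells]
    keep_genes = counts.sum(axis=1) > 0
    counts = counts[keep_genes, :]
    out = CountMatrix(
        counts,
        [g for g, k in zip(cm.gene_ids, keep_genes) if k],
        [c for c, k in zip(cm.cell_ids, keep_cells) if k],
        [t for t, k in zip(cm.timepoint, keep_cells) if k],
    )
    logger.info(
        "QC: removed %d/%d cells (<%d detected genes) and %d/%d all-zero "
        "genes; kept %d genes x %d cells",
        int((~keep_cells).sum()), cm.n_cells, min_genes_per_cell,
        int((~keep_genes).sum()), cm.n_genes, out.n_genes, out.n_cells,
    )
    return out
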
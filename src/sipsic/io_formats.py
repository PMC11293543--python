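"""Readers and writers for every external format the pipeline touches.

Supported formats:

* 10x-style MTX triplets (``matrix.mtx`` + ``genes.tsv``/``features.tsv`` +
  ``barcodes.tsv``), MatrixMarket coordinate, genes as rows / cells as columns;
* dense TSV/CSV matrices with a header row of cell ids and a first column of
  gene ids;
* GMT gene-set files (Broad dialect: name, description, member symbols);
* two-column cell-to-group assignment tables;
* pathway-score and result tables (TSV).

The internal orientation is fixed: genes are rows, cells are columns.
Transposed dense input is handled only via an explicit ``transpose`` flag,
never guessed.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import ConsistencyError, FormatError, ValidationError

logger = logging.getLogger(__name__)

# Unit tags for an expression matrix.
TPM = "TPM"
CPM = "CPM"
COUNTS = "COUNTS"
LOG_UNKNOWN = "LOG_UNKNOWN"
_UNITS = (TPM, CPM, COUNTS, LOG_UNKNOWN)


@dataclass
class ExpressionMatrix:
    """A nonnegative genes x cells expression matrix.

    ``values`` may be dense (ndarray) or sparse (any scipy.sparse matrix);
    sparse inputs are kept sparse. ``unit_tag`` declares the units and is
    one of ``TPM``, ``CPM``, ``COUNTS``, ``LOG_UNKNOWN``.
    """

    values: "np.ndarray | sp.spmatrix"
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    unit_tag: str = COUNTS

    def __post_init__(self):
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.unit_tag not in _UNITS:
            raise ValidationError(f"unknown unit_tag {self.unit_tag!r}")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} gene ids x {len(self.cell_ids)} cell ids"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("gene ids are not unique")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("cell ids are not unique")
        data = self.values.data if sp.issparse(self.values) else self.values
        if data.size and np.min(data) < 0:
            raise ValidationError("expression matrix contains negative entries")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def is_sparse(self) -> bool:
        return sp.issparse(self.values)

    def tocsr(self) -> sp.csr_matrix:
        """Values as CSR, converting from dense if necessary."""
        if sp.issparse(self.values):
            return self.values.tocsr()
        return sp.csr_matrix(self.values)

    def toarray(self) -> np.ndarray:
        if sp.issparse(self.values):
            return self.values.toarray()
        return np.asarray(self.values)

    def gene_index(self) -> dict:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_genes(self, mask_or_idx) -> "ExpressionMatrix":
        vals = self.tocsr()[mask_or_idx, :] if self.is_sparse else self.values[mask_or_idx, :]
        return ExpressionMatrix(vals, self.gene_ids[mask_or_idx], self.cell_ids, self.unit_tag)

    def subset_cells(self, mask_or_idx) -> "ExpressionMatrix":
        vals = self.tocsr()[:, mask_or_idx] if self.is_sparse else self.values[:, mask_or_idx]
        return ExpressionMatrix(vals, self.gene_ids, self.cell_ids[mask_or_idx], self.unit_tag)


@dataclass
class GeneSet:
    """A named, single-direction list of gene identifiers."""

    name: str
    genes: list
    description: str = ""

    def __post_init__(self):
        self.genes = list(self.genes)
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"gene set {self.name!r} has duplicate genes")

    def __len__(self):
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """An ordered collection of uniquely named gene sets."""

    sets: list
    source_path: str = ""

    def __post_init__(self):
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate gene set names: {dupes}")

    def __len__(self):
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list:
        return [s.name for s in self.sets]


@dataclass
class GroupAssignment:
    """Mapping from cell id to group label."""

    mapping: dict = field(default_factory=dict)

    @property
    def labels(self) -> list:
        """Distinct group labels, in order of first appearance."""
        seen = []
        for v in self.mapping.values():
            if v not in seen:
                seen.append(v)
        return seen

    def cells_in(self, label: str) -> list:
        return [c for c, g in self.mapping.items() if g == label]

    def validate_against(self, cell_ids) -> None:
        known = set(cell_ids)
        missing = [c for c in self.mapping if c not in known]
        if missing:
            raise ValidationError(
                f"{len(missing)} assigned cells absent from the matrix "
                f"(first: {missing[0]!r})"
            )

    def __len__(self):
        return len(self.mapping)


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def _collapse_duplicate_genes(values, gene_ids):
    """Sum rows sharing a gene id (counts/CPM are additive). Returns new pair."""
    gene_ids = np.asarray(gene_ids, dtype=object)
    uniq, first_pos, inverse = np.unique(gene_ids, return_index=True, return_inverse=True)
    if len(uniq) == len(gene_ids):
        return values, gene_ids
    n_dup = len(gene_ids) - len(uniq)
    logger.warning("collapsing %d duplicate gene id(s) by summation", n_dup)
    # preserve first-occurrence order of the surviving ids
    order = np.argsort(first_pos)
    agg = sp.csr_matrix(
        (np.ones(len(gene_ids)), (inverse, np.arange(len(gene_ids)))),
        shape=(len(uniq), len(gene_ids)),
    )
    collapsed = agg @ (values.tocsr() if sp.issparse(values) else values)
    if sp.issparse(collapsed):
        collapsed = collapsed.tocsr()[order, :]
    else:
        collapsed = np.asarray(collapsed)[order, :]
    return collapsed, uniq[order]


def _read_id_file(path: str, n_expected: int, what: str) -> np.ndarray:
    with open(path, newline="") as fh:
        lines = [ln.rstrip("\r\n") for ln in fh]
    lines = [ln for ln in lines if ln != ""]
    if len(lines) != n_expected:
        raise ConsistencyError(
            f"{what} file {path!r} has {len(lines)} entries but the matrix "
            f"declares {n_expected}"
        )
    out = []
    for ln in lines:
        fields = ln.split("\t")
        # 10x features files carry (id, symbol[, type]); the symbol column is
        # what gene-set collections use, so prefer it when present.
        out.append(fields[1] if what == "genes" and len(fields) >= 2 else fields[0])
    return np.asarray(out, dtype=object)


def read_mtx_triplet(mtx_path: str, genes_path: str, barcodes_path: str,
                     unit_tag: str = COUNTS) -> ExpressionMatrix:
    """Read a 10x-style MatrixMarket triplet (genes x cells)."""
    try:
        values = scipy.io.mmread(mtx_path)
    except ValueError as exc:
        raise FormatError(f"malformed MTX file {mtx_path!r}: {exc}") from exc
    values = sp.csr_matrix(values)
    gene_ids = _read_id_file(genes_path, values.shape[0], "genes")
    cell_ids = _read_id_file(barcodes_path, values.shape[1], "barcodes")
    values, gene_ids = _collapse_duplicate_genes(values, gene_ids)
    return ExpressionMatrix(values, gene_ids, cell_ids, unit_tag)


def read_dense_matrix(path: str, unit_tag: str = COUNTS,
                      transpose: bool = False) -> ExpressionMatrix:
    """Read a dense TSV/CSV with cell ids in the header and gene ids in column 1."""
    sep = "," if path.endswith(".csv") else "\t"
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse dense matrix {path!r}: {exc}") from exc
    if transpose:
        df = df.T
    values, gene_ids = _collapse_duplicate_genes(
        df.to_numpy(dtype=float), df.index.to_numpy(dtype=object)
    )
    return ExpressionMatrix(values, gene_ids, df.columns.to_numpy(dtype=object), unit_tag)


def read_matrix(path, unit_tag: str = COUNTS, transpose: bool = False) -> ExpressionMatrix:
    """Dispatch on input kind: directory or .mtx path -> triplet, else dense table.

    ``path`` may also be a (mtx, genes, barcodes) tuple of paths.
    """
    if isinstance(path, (tuple, list)):
        return read_mtx_triplet(*path, unit_tag=unit_tag)
    if os.path.isdir(path):
        mtx = os.path.join(path, "matrix.mtx")
        genes = os.path.join(path, "genes.tsv")
        if not os.path.exists(genes):
            genes = os.path.join(path, "features.tsv")
        barcodes = os.path.join(path, "barcodes.tsv")
        return read_mtx_triplet(mtx, genes, barcodes, unit_tag=unit_tag)
    if path.endswith(".mtx"):
        base = os.path.dirname(path)
        genes = os.path.join(base, "genes.tsv")
        if not os.path.exists(genes):
            genes = os.path.join(base, "features.tsv")
        return read_mtx_triplet(path, genes, os.path.join(base, "barcodes.tsv"),
                                unit_tag=unit_tag)
    return read_dense_matrix(path, unit_tag=unit_tag, transpose=transpose)


def write_matrix(matrix: ExpressionMatrix, path: str) -> None:
    """Write a matrix: a directory path gets an MTX triplet, a file path a dense TSV."""
    if path.endswith(os.sep) or (os.path.isdir(path) if os.path.exists(path) else
                                 not path.endswith((".tsv", ".csv", ".txt"))):
        os.makedirs(path, exist_ok=True)
        scipy.io.mmwrite(os.path.join(path, "matrix.mtx"), matrix.tocsr())
        with open(os.path.join(path, "genes.tsv"), "w") as fh:
            for g in matrix.gene_ids:
                fh.write(f"{g}\t{g}\n")
        with open(os.path.join(path, "barcodes.tsv"), "w") as fh:
            for c in matrix.cell_ids:
                fh.write(f"{c}\n")
    else:
        df = pd.DataFrame(matrix.toarray(), index=matrix.gene_ids, columns=matrix.cell_ids)
        df.to_csv(path, sep="," if path.endswith(".csv") else "\t")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path: str, uppercase: bool = False) -> GeneSetCollection:
    """Parse a GMT file: one tab-separated line per set (name, description, genes).

    Duplicate genes within a line are dropped, keeping the first occurrence.
    Empty lines are skipped. ``uppercase`` folds gene symbols to upper case
    for matching collections against mixed-case matrices (opt-in).
    """
    sets = []
    with open(path, newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path!r} line {lineno}: GMT lines need >=3 tab-separated "
                    f"fields (name, description, genes), got {len(fields)}"
                )
            name, desc = fields[0], fields[1]
            seen, genes = set(), []
            for g in fields[2:]:
                if not g:
                    continue
                if uppercase:
                    g = g.upper()
                if g not in seen:
                    seen.add(g)
                    genes.append(g)
            if not genes:
                raise FormatError(f"{path!r} line {lineno}: set {name!r} has no genes")
            sets.append(GeneSet(name=name, genes=genes, description=desc))
    return GeneSetCollection(sets=sets, source_path=path)


def write_gmt(collection: GeneSetCollection, path: str) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description or "na", *s.genes]) + "\n")


# ---------------------------------------------------------------------------
# Group assignments
# ---------------------------------------------------------------------------

def read_groups(path: str) -> GroupAssignment:
    """Read a two-column TSV: cell_id<TAB>group. Lines starting with # are skipped."""
    mapping = {}
    with open(path, newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path!r} line {lineno}: expected cell_id<TAB>group")
            if fields[0] in mapping:
                raise ValidationError(f"{path!r} line {lineno}: duplicate cell id {fields[0]!r}")
            mapping[fields[0]] = fields[1]
    return GroupAssignment(mapping=mapping)


def write_groups(groups: GroupAssignment, path: str) -> None:
    with open(path, "w") as fh:
        for cell, label in groups.mapping.items():
            fh.write(f"{cell}\t{label}\n")


# ---------------------------------------------------------------------------
# Score tables
# ---------------------------------------------------------------------------

def write_scores(scores, path: str) -> None:
    """Write a pathway x cell score table as TSV at full float precision.

    Accepts a PathwayScoreMatrix (its ``frame`` attribute is used) or a
    pathways x cells DataFrame. NaN or infinite scores are rejected.
    """
    frame = getattr(scores, "frame", scores)
    if frame.shape[0] and not np.isfinite(frame.to_numpy()).all():
        raise ValidationError("score matrix contains NaN or infinite values")
    frame.to_csv(path, sep="\t", index_label="pathway", float_format="%.17g")


def read_scores(path: str) -> pd.DataFrame:
    """Read a pathway x cell score TSV back into a DataFrame."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.shape[0] and not np.isfinite(df.to_numpy()).all():
        raise ValidationError(f"score table {path!r} contains non-finite values")
    return df
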
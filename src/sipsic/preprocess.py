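"""Filtering and normalization of raw expression matrices before scoring.

The fixed order of the full pipeline is: de-log (only for matrices published
on a log scale) -> cell filter -> gene filter -> CPM conversion (only for raw
counts). Threshold comparisons are strict-less for removal: a cell expressing
exactly ``min_genes`` genes is kept, a gene expressed in exactly the minimum
cell fraction is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .errors import EmptyResultError, ParameterError
from .io_formats import CPM, COUNTS, LOG_UNKNOWN, TPM, ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """What a filtering step did: in/out counts and the thresholds used."""

    n_cells_in: int
    n_cells_out: int
    n_genes_in: int
    n_genes_out: int
    thresholds: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_cells_in": self.n_cells_in,
            "n_cells_out": self.n_cells_out,
            "n_genes_in": self.n_genes_in,
            "n_genes_out": self.n_genes_out,
            "thresholds": dict(self.thresholds),
        }


def delog(matrix: ExpressionMatrix, base: float = 2.0, pseudocount: float = 1.0,
          target_unit: str = TPM) -> ExpressionMatrix:
    """Convert a log-scale matrix back to linear scale.

    Applies ``base ** x - pseudocount`` entrywise, clipping at zero. With the
    common log2(x + 1) convention (the default), zero is a fixed point, so a
    sparse matrix stays sparse. ``target_unit`` declares what the linear
    values are (TPM or CPM) — the log transform does not record it.
    """
    if base <= 1:
        raise ParameterError(f"delog base must be > 1, got {base}")
    if pseudocount < 0:
        raise ParameterError(f"pseudocount must be >= 0, got {pseudocount}")
    if matrix.unit_tag != LOG_UNKNOWN:
        logger.warning("delog applied to a matrix tagged %s, not LOG_UNKNOWN",
                       matrix.unit_tag)
    if target_unit not in (TPM, CPM):
        raise ParameterError(f"target_unit must be TPM or CPM, got {target_unit!r}")

    zero_maps_to = base ** 0.0 - pseudocount  # what a stored zero becomes
    if matrix.is_sparse and zero_maps_to <= 0:
        vals = matrix.tocsr().copy()
        new = np.power(base, vals.data) - pseudocount
        clipped = int(np.sum(new < 0))
        vals.data = np.maximum(new, 0.0)
        vals.eliminate_zeros()
    else:
        new = np.power(base, matrix.toarray()) - pseudocount
        clipped = int(np.sum(new < 0))
        vals = np.maximum(new, 0.0)
    if clipped:
        logger.warning("delog clipped %d negative value(s) to zero", clipped)
    return ExpressionMatrix(vals, matrix.gene_ids, matrix.cell_ids, target_unit)


def _genes_per_cell(matrix: ExpressionMatrix) -> np.ndarray:
    if matrix.is_sparse:
        m = matrix.tocsr()
        return np.asarray((m > 0).sum(axis=0)).ravel()
    return np.count_nonzero(matrix.values > 0, axis=0)


def _cells_per_gene(matrix: ExpressionMatrix) -> np.ndarray:
    if matrix.is_sparse:
        m = matrix.tocsr()
        return np.asarray((m > 0).sum(axis=1)).ravel()
    return np.count_nonzero(matrix.values > 0, axis=1)


def filter_cells(matrix: ExpressionMatrix, min_genes: int = 1000):
    """Remove cells expressing fewer than ``min_genes`` genes (>=1 read each).

    Returns (filtered matrix, FilterReport). Cells with exactly ``min_genes``
    expressed genes are kept; survivor order is preserved.
    """
    if min_genes < 0:
        raise ParameterError("min_genes must be >= 0")
    keep = _genes_per_cell(matrix) >= min_genes
    report = FilterReport(
        n_cells_in=matrix.n_cells, n_cells_out=int(keep.sum()),
        n_genes_in=matrix.n_genes, n_genes_out=matrix.n_genes,
        thresholds={"min_genes": min_genes},
    )
    if not keep.any():
        raise EmptyResultError(
            f"cell filter (min_genes={min_genes}) removed all {matrix.n_cells} cells",
            report=report,
        )
    return matrix.subset_cells(keep), report


def filter_genes(matrix: ExpressionMatrix, min_cell_fraction: float = 0.10):
    """Remove genes expressed in less than ``min_cell_fraction`` of cells.

    Intended to run after :func:`filter_cells`, so the fraction refers to the
    remaining cells. Genes at exactly the threshold are kept.
    """
    if not 0.0 <= min_cell_fraction <= 1.0:
        raise ParameterError("min_cell_fraction must be in [0, 1]")
    if matrix.n_cells == 0 or matrix.n_genes == 0:
        raise EmptyResultError("cannot gene-filter an empty matrix")
    frac = _cells_per_gene(matrix) / matrix.n_cells
    keep = frac >= min_cell_fraction
    report = FilterReport(
        n_cells_in=matrix.n_cells, n_cells_out=matrix.n_cells,
        n_genes_in=matrix.n_genes, n_genes_out=int(keep.sum()),
        thresholds={"min_cell_fraction": min_cell_fraction},
    )
    if not keep.any():
        raise EmptyResultError(
            f"gene filter (min_cell_fraction={min_cell_fraction}) removed all genes",
            report=report,
        )
    return matrix.subset_genes(keep), report


def cpm_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Counts-per-million: divide each cell by its total counts, times 1e6."""
    if matrix.unit_tag != COUNTS:
        logger.warning("cpm_normalize applied to a matrix tagged %s, not COUNTS",
                       matrix.unit_tag)
    if matrix.is_sparse:
        m = matrix.tocsr().astype(float)
        totals = np.asarray(m.sum(axis=0)).ravel()
    else:
        m = matrix.values.astype(float)
        totals = m.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise EmptyResultError(
            f"cell(s) with zero total counts cannot be CPM-normalized: "
            f"{list(matrix.cell_ids[zero[:5]])}"
        )
    scale = 1e6 / totals
    if sp.issparse(m):
        vals = m @ sp.diags(scale)
        vals = vals.tocsr()
    else:
        vals = m * scale[np.newaxis, :]
    return ExpressionMatrix(vals, matrix.gene_ids, matrix.cell_ids, CPM)


def preprocess_pipeline(matrix: ExpressionMatrix, *, min_genes: int = 1000,
                        min_cell_fraction: float = 0.10,
                        delog_base: float = 2.0, delog_pseudocount: float = 1.0,
                        delog_target_unit: str = TPM):
    """Full preprocessing in the fixed order; returns (matrix, list of reports).

    De-log runs only when the input is tagged LOG_UNKNOWN; CPM conversion runs
    only when the (filtered) matrix is raw counts.
    """
    reports = []
    if matrix.unit_tag == LOG_UNKNOWN:
        matrix = delog(matrix, base=delog_base, pseudocount=delog_pseudocount,
                       target_unit=delog_target_unit)
    matrix, rep = filter_cells(matrix, min_genes=min_genes)
    reports.append(rep)
    matrix, rep = filter_genes(matrix, min_cell_fraction=min_cell_fraction)
    reports.append(rep)
    if matrix.unit_tag == COUNTS:
        matrix = cpm_normalize(matrix)
    return matrix, reports
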
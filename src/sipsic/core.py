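"""The pathway-scoring algorithm: robust per-gene normalization and
expression-rank weighting.

For a preprocessed expression matrix X (genes x cells, TPM or CPM) and a gene
set of size n_P (after intersection with the matrix), the per-cell pathway
score is computed in two steps:

1. **Normalized gene scores.** For each gene i, take the median of the top
   tau% highest-expressing cells (default tau = 5%). If that median is
   positive it is the normalization factor NF_i; if it is zero, NF_i is the
   gene's maximum value instead. Then S_ij = X_ij / NF_i. Genes that are zero
   everywhere get NF_i = 0 and S_ij = 0 for all cells.

   The top-tau% median is a robust "high quantile" anchor: in sparse
   single-cell data it is usually positive yet insensitive to single-cell
   outliers, so every gene contributes on a comparable scale.

2. **Rank-weighted aggregation.** Rank the set's genes by total raw
   expression across all cells (highest total -> rank n_P, ties get
   midranks), and score each cell j as

       P_j = (1 / n_P^2) * sum_i rank_i * S_ij.

   Weighting by expression rank exploits the higher information content of
   highly expressed genes. The 1/n_P^2 denominator is the default; a
   variant denominator n_P (n_P + 1) / 2, which makes the weights sum to 1,
   is available via ``weight_denominator="weighted_mean"``. The two differ
   only by a per-pathway positive constant and change no downstream test,
   Z-score or ordering.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata

from .errors import CoverageError, EmptyResultError, ParameterError
from .io_formats import LOG_UNKNOWN, ExpressionMatrix, GeneSet, GeneSetCollection

logger = logging.getLogger(__name__)

DENOM_NP_SQUARED = "np_squared"
DENOM_WEIGHTED_MEAN = "weighted_mean"


@dataclass
class NormalizationFactors:
    """Per-gene normalization factors NF_i for a given tau."""

    factors: np.ndarray          # aligned with gene_ids
    gene_ids: np.ndarray
    tau: float
    k_top: int                   # number of top cells in the median window

    def __post_init__(self):
        self.factors = np.asarray(self.factors, dtype=float)


@dataclass
class RankWeights:
    """Midranks of a gene set's genes by total expression across cells."""

    ranks: np.ndarray            # in [1, n_set], midranks allowed
    gene_ids: np.ndarray         # set genes present in the matrix
    total_expression: np.ndarray
    n_set: int                   # intersection size n_P
    genes_missing: list = field(default_factory=list)


@dataclass
class PathwayInfo:
    """Per-pathway scoring metadata."""

    n_set: int
    genes_used: list
    genes_missing: list
    tau: float

    @property
    def coverage(self) -> float:
        n_total = self.n_set + len(self.genes_missing)
        return self.n_set / n_total if n_total else 0.0


@dataclass
class PathwayScoreMatrix:
    """Pathways x cells score matrix plus per-pathway metadata."""

    frame: pd.DataFrame                      # index: pathway names, columns: cell ids
    info: dict = field(default_factory=dict)  # pathway name -> PathwayInfo
    skipped: list = field(default_factory=list)  # (name, reason)
    tau: float = 5.0

    @property
    def pathways(self) -> list:
        return list(self.frame.index)

    @property
    def cell_ids(self) -> list:
        return list(self.frame.columns)


def top_tau_count(n_cells: int, tau: float) -> int:
    """Number of cells in the top-tau% window: max(1, ceil(tau/100 * n))."""
    if n_cells < 1:
        raise ParameterError("n_cells must be >= 1")
    if not 0 < tau <= 100:
        raise ParameterError(f"tau must be in (0, 100], got {tau}")
    return max(1, math.ceil(tau / 100.0 * n_cells))


def normalization_factor(gene_values: np.ndarray, tau: float = 5.0) -> float:
    """NF for one gene: median of the k largest values, falling back to the max.

    An all-zero gene yields 0.0; division is handled downstream.
    """
    values = np.asarray(gene_values, dtype=float)
    k = top_tau_count(values.size, tau)
    top = np.partition(values, values.size - k)[values.size - k:]
    med = float(np.median(top))
    if med > 0:
        return med
    return float(values.max())


def _nf_from_sparse_row(data: np.ndarray, n_cells: int, k: int) -> float:
    """NF from a CSR row's stored values: implicit zeros fill the window."""
    nnz = data.size
    if nnz == 0:
        return 0.0
    if nnz >= k:
        top = np.partition(data, nnz - k)[nnz - k:]
    else:
        top = np.concatenate([data, np.zeros(k - nnz)])
    med = float(np.median(top))
    if med > 0:
        return med
    return float(data.max())


def normalization_factors(matrix: ExpressionMatrix, tau: float = 5.0,
                          gene_indices=None) -> NormalizationFactors:
    """NF_i for the requested genes (all genes when ``gene_indices`` is None)."""
    k = top_tau_count(matrix.n_cells, tau)
    if gene_indices is None:
        gene_indices = np.arange(matrix.n_genes)
    gene_indices = np.asarray(gene_indices)
    factors = np.empty(gene_indices.size, dtype=float)
    if matrix.is_sparse:
        csr = matrix.tocsr()
        for out_i, gi in enumerate(gene_indices):
            row = csr.data[csr.indptr[gi]:csr.indptr[gi + 1]]
            factors[out_i] = _nf_from_sparse_row(row, matrix.n_cells, k)
    else:
        for out_i, gi in enumerate(gene_indices):
            factors[out_i] = normalization_factor(matrix.values[gi, :], tau)
    return NormalizationFactors(factors=factors, gene_ids=matrix.gene_ids[gene_indices],
                                tau=tau, k_top=k)


def normalize_genes(matrix: ExpressionMatrix, nf: NormalizationFactors):
    """S_ij = X_ij / NF_i; rows with NF_i = 0 (all-zero genes) stay zero.

    Returns values in the same representation (sparse stays sparse) for the
    genes covered by ``nf`` (assumed aligned with the matrix rows).
    """
    idx = matrix.gene_index()
    rows = np.array([idx[g] for g in nf.gene_ids])
    inv = np.zeros(nf.factors.size)
    pos = nf.factors > 0
    inv[pos] = 1.0 / nf.factors[pos]
    if matrix.is_sparse:
        sub = matrix.tocsr()[rows, :]
        return sp.diags(inv) @ sub
    return matrix.values[rows, :] * inv[:, np.newaxis]


def rank_weights(matrix: ExpressionMatrix, gene_set: GeneSet) -> RankWeights:
    """Rank the set's genes by total raw expression across all cells.

    The highest total receives the largest rank (n_P); ties receive midranks,
    so the ranking is invariant to gene order. Raises CoverageError when the
    set and the matrix share no genes.
    """
    idx = matrix.gene_index()
    present = [g for g in gene_set.genes if g in idx]
    missing = [g for g in gene_set.genes if g not in idx]
    if not present:
        raise CoverageError(
            f"gene set {gene_set.name!r}: none of its {len(gene_set)} genes "
            f"are in the matrix"
        )
    rows = np.array([idx[g] for g in present])
    if matrix.is_sparse:
        totals = np.asarray(matrix.tocsr()[rows, :].sum(axis=1)).ravel()
    else:
        totals = matrix.values[rows, :].sum(axis=1)
    ranks = rankdata(totals, method="average")
    return RankWeights(ranks=ranks, gene_ids=np.asarray(present, dtype=object),
                       total_expression=totals, n_set=len(present),
                       genes_missing=missing)


def _denominator(n_set: int, weight_denominator: str) -> float:
    if weight_denominator == DENOM_NP_SQUARED:
        return float(n_set) ** 2
    if weight_denominator == DENOM_WEIGHTED_MEAN:
        return n_set * (n_set + 1) / 2.0
    raise ParameterError(f"unknown weight_denominator {weight_denominator!r}")


def score_pathway(matrix: ExpressionMatrix, gene_set: GeneSet, tau: float = 5.0,
                  weight_denominator: str = DENOM_NP_SQUARED) -> np.ndarray:
    """Per-cell pathway scores P_j for one gene set.

    Identical for sparse and dense representations of the same matrix.
    """
    if matrix.unit_tag == LOG_UNKNOWN:
        logger.warning("scoring a matrix with unit_tag LOG_UNKNOWN; linear-scale "
                       "TPM/CPM is recommended")
    rw = rank_weights(matrix, gene_set)
    idx = matrix.gene_index()
    rows = np.array([idx[g] for g in rw.gene_ids])
    nf = normalization_factors(matrix, tau=tau, gene_indices=rows)
    inv = np.zeros(nf.factors.size)
    pos = nf.factors > 0
    inv[pos] = 1.0 / nf.factors[pos]
    weights = rw.ranks * inv  # rank_i / NF_i per set gene; 0 for all-zero genes
    if matrix.is_sparse:
        sub = matrix.tocsr()[rows, :]
        scores = np.asarray(weights @ sub).ravel()
    else:
        scores = weights @ matrix.values[rows, :]
    return scores / _denominator(rw.n_set, weight_denominator)


def score_collection(matrix: ExpressionMatrix, sets: GeneSetCollection,
                     tau: float = 5.0,
                     weight_denominator: str = DENOM_NP_SQUARED) -> PathwayScoreMatrix:
    """Score every set in a collection; sets with zero coverage are skipped
    with a logged warning and recorded in the result, never silently dropped.
    """
    rows, info, skipped, names = [], {}, [], []
    for gene_set in sets:
        try:
            scores = score_pathway(matrix, gene_set, tau=tau,
                                   weight_denominator=weight_denominator)
        except CoverageError as exc:
            logger.warning("skipping gene set %r: %s", gene_set.name, exc)
            skipped.append((gene_set.name, str(exc)))
            continue
        rw = rank_weights(matrix, gene_set)
        info[gene_set.name] = PathwayInfo(
            n_set=rw.n_set, genes_used=list(rw.gene_ids),
            genes_missing=rw.genes_missing, tau=tau,
        )
        names.append(gene_set.name)
        rows.append(scores)
    if not rows:
        raise EmptyResultError("all gene sets had zero coverage; nothing scored")
    frame = pd.DataFrame(np.vstack(rows), index=names,
                         columns=list(matrix.cell_ids))
    return PathwayScoreMatrix(frame=frame, info=info, skipped=skipped, tau=tau)
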
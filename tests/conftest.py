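"""Shared fixtures and the independent brute-force scoring oracle.

The oracle below is deliberately written in plain Python (sorting, explicit
loops, a hand-rolled median and midrank) so that it shares no code path with
the package implementation it checks.
"""

import math

import numpy as np
import pytest

from sipsic import CPM, ExpressionMatrix, GeneSet


def _median(values):
    s = sorted(values)
    n = len(s)
    mid = n // 2
    if n % 2:
        return s[mid]
    return (s[mid - 1] + s[mid]) / 2.0


def naive_score_pathway(x_rows, tau):
    """Brute-force per-cell pathway scores from a genes x cells list of lists.

    Steps: per-gene top-tau% median (fallback to the max when that median is
    zero) as normalization factor; normalized scores x/NF; midranks of
    per-gene totals; score = sum(rank * S) / n_genes**2.
    """
    n_genes = len(x_rows)
    n_cells = len(x_rows[0])
    k = max(1, math.ceil(tau / 100.0 * n_cells))
    nf = []
    for row in x_rows:
        top = sorted(row)[-k:]
        med = _median(top)
        nf.append(med if med > 0 else max(row))
    s = [[(x / f if f > 0 else 0.0) for x in row] for row, f in zip(x_rows, nf)]
    totals = [sum(row) for row in x_rows]
    ranks = []
    for t in totals:
        below = sum(1 for u in totals if u < t)
        tied = sum(1 for u in totals if u == t)
        ranks.append(below + (tied + 1) / 2.0)
    return [
        sum(ranks[i] * s[i][j] for i in range(n_genes)) / n_genes**2
        for j in range(n_cells)
    ]


def random_case(rng, max_genes=20, max_cells=10, max_set=6, sparsity=0.6):
    """One random (ExpressionMatrix, GeneSet) pair with at least one nonzero
    value per set gene guaranteed not required — all-zero genes are legal."""
    n_genes = rng.integers(2, max_genes + 1)
    n_cells = rng.integers(2, max_cells + 1)
    x = rng.random((n_genes, n_cells)) * 100
    x[rng.random((n_genes, n_cells)) < sparsity] = 0.0
    gene_ids = [f"g{i}" for i in range(n_genes)]
    matrix = ExpressionMatrix(x, gene_ids, [f"c{j}" for j in range(n_cells)], CPM)
    set_size = rng.integers(1, min(max_set, n_genes) + 1)
    members = list(rng.choice(gene_ids, size=set_size, replace=False))
    return matrix, GeneSet("RANDOM", members)


@pytest.fixture
def worked_matrix():
    """The two-gene, three-cell matrix used in the worked example."""
    return ExpressionMatrix(
        np.array([[1.0, 2.0, 3.0], [0.0, 1.0, 6.0]]),
        ["A", "B"], ["c1", "c2", "c3"], CPM,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
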
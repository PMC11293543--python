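"""Cells represented in pathway-score space.

Pathway scores collapse thousands of genes to a few dozen biologically
interpretable axes; clustering and embedding in this space emphasizes shared
biology over per-sample technical structure. This module provides per-pathway
Z-scoring, heatmap cell/pathway ordering, community-detection clustering on a
kNN graph in pathway-Z space, and a 2-D UMAP embedding, plus the
cluster-by-label composition summary used to quantify sample (patient)
dominance of clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .differential import UP
from .errors import AnalysisError, ParameterError

logger = logging.getLogger(__name__)


@dataclass
class ZScoreMatrix:
    """Row-standardized pathway x cell matrix.

    Constant rows cannot be standardized; they are set to all-zero and listed
    in ``constant_rows``.
    """

    frame: pd.DataFrame
    means: pd.Series
    sds: pd.Series
    constant_rows: list = field(default_factory=list)


@dataclass
class ClusterAssignment:
    """Cell -> integer cluster label, with the parameters that produced it."""

    labels: pd.Series            # index: cell ids, values: int, contiguous from 0
    n_neighbors: int
    resolution: float
    seed: int

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0


def zscore(scores) -> ZScoreMatrix:
    """Standardize each pathway row to mean 0, sd 1 (sd with denominator n-1)."""
    frame = getattr(scores, "frame", scores)
    x = frame.to_numpy(dtype=float)
    if x.size and not np.isfinite(x).all():
        raise AnalysisError("scores must be finite for Z-scoring")
    means = x.mean(axis=1)
    sds = x.std(axis=1, ddof=1) if x.shape[1] > 1 else np.zeros(x.shape[0])
    constant = sds == 0
    safe = np.where(constant, 1.0, sds)
    z = (x - means[:, None]) / safe[:, None]
    z[constant, :] = 0.0
    const_rows = [frame.index[i] for i in np.flatnonzero(constant)]
    if const_rows:
        logger.warning("%d constant pathway row(s) set to zero: %s",
                       len(const_rows), const_rows[:5])
    return ZScoreMatrix(
        frame=pd.DataFrame(z, index=frame.index, columns=frame.columns),
        means=pd.Series(means, index=frame.index),
        sds=pd.Series(sds, index=frame.index),
        constant_rows=const_rows,
    )


def heatmap_order(z: ZScoreMatrix, calls, groups):
    """Cell and pathway orders for a grouped differential-pathway heatmap.

    Within each group, cells are sorted in ascending order of their mean
    Z-score over the pathways called up in that group; a group with no
    upregulated pathways keeps its input cell order (with a warning).
    Pathways appear in group blocks, each block sorted by ascending max FDR
    (most significant first). Only upregulated pathways are listed. Returns
    (cell_order, pathway_order) as lists of ids.
    """
    up_by_group = {}
    for c in calls:
        if c.direction == UP:
            up_by_group.setdefault(c.focal_group, []).append((c.max_fdr, c.pathway))

    cell_order, pathway_order = [], []
    for label in groups.labels:
        cells = [c for c in groups.cells_in(label) if c in z.frame.columns]
        ups = sorted(up_by_group.get(label, []))
        if not ups:
            logger.warning("group %r has no upregulated pathways; keeping input "
                           "cell order", label)
            cell_order.extend(cells)
            continue
        up_paths = [p for _, p in ups]
        mean_z = z.frame.loc[up_paths, cells].mean(axis=0)
        cell_order.extend(mean_z.sort_values(kind="stable").index.tolist())
        pathway_order.extend(p for p in up_paths if p not in pathway_order)
    return cell_order, pathway_order


def _knn_graph(x: np.ndarray, n_neighbors: int) -> ig.Graph:
    """Undirected kNN graph (union of directed neighborhoods) in Euclidean space."""
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(x)
    _, idx = nn.kneighbors(x)
    edges = set()
    for i, row in enumerate(idx):
        for j in row:
            if i != j:
                edges.add((min(i, int(j)), max(i, int(j))))
    g = ig.Graph(n=x.shape[0], edges=sorted(edges), directed=False)
    return g


def cluster_cells(scores, n_neighbors: int = 20, resolution: float = 0.5,
                  seed: int = 0) -> ClusterAssignment:
    """Community detection on a kNN graph built in pathway-Z space.

    Scores are standardized per pathway, a Euclidean k-nearest-neighbor graph
    is built over cells, and communities are found by Leiden optimization of
    RB-configuration modularity at the given resolution. Deterministic for a
    fixed seed. Labels are relabeled contiguously from 0 in order of first
    appearance.
    """
    frame = getattr(scores, "frame", scores)
    n_cells = frame.shape[1]
    if n_cells < n_neighbors + 1:
        raise ParameterError(
            f"need >= n_neighbors+1 = {n_neighbors + 1} cells, got {n_cells}"
        )
    z = zscore(frame)
    x = z.frame.to_numpy().T
    g = _knn_graph(x, n_neighbors)
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed, n_iterations=2,
    )
    raw = np.asarray(part.membership)
    relabel, next_id = {}, 0
    labels = np.empty(raw.size, dtype=int)
    for i, r in enumerate(raw):
        if r not in relabel:
            relabel[r] = next_id
            next_id += 1
        labels[i] = relabel[r]
    return ClusterAssignment(
        labels=pd.Series(labels, index=frame.columns),
        n_neighbors=n_neighbors, resolution=resolution, seed=seed,
    )


def embed_cells(scores, seed: int = 0, n_neighbors: int = 15) -> pd.DataFrame:
    """2-D UMAP embedding of cells in pathway-Z space.

    Returns a cells x (umap1, umap2) DataFrame. Deterministic for a fixed
    seed on one platform/library version.
    """
    frame = getattr(scores, "frame", scores)
    n_cells = frame.shape[1]
    if n_cells < 3:
        raise ParameterError("embedding needs >= 3 cells")
    z = zscore(frame)
    x = z.frame.to_numpy().T
    if np.allclose(x, 0):
        raise AnalysisError("all pathway rows are constant; nothing to embed")
    import umap  # deferred: numba compilation is slow at import

    reducer = umap.UMAP(n_components=2, n_neighbors=min(n_neighbors, n_cells - 1),
                        random_state=seed)
    coords = reducer.fit_transform(x)
    if not np.isfinite(coords).all():
        raise AnalysisError("embedding produced non-finite coordinates")
    return pd.DataFrame(coords, index=frame.columns, columns=["umap1", "umap2"])


def cluster_composition(clusters: ClusterAssignment, labels):
    """Cluster x label contingency table and per-cluster dominant-label fraction.

    ``labels`` is a GroupAssignment (e.g. patient of origin). Returns
    (table, summary) where summary has columns ``dominant_label`` and
    ``dominant_fraction`` indexed by cluster.
    """
    lab = pd.Series({c: labels.mapping[c] for c in clusters.labels.index})
    table = pd.crosstab(clusters.labels, lab)
    table.index.name = "cluster"
    table.columns.name = "label"
    dominant = table.idxmax(axis=1)
    fractions = table.max(axis=1) / table.sum(axis=1)
    summary = pd.DataFrame({"dominant_label": dominant,
                            "dominant_fraction": fractions})
    return table, summary
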
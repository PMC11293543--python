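"""Synthetic scRNA-seq count matrices with known ground truth.

The generator draws per-gene, per-cell counts from a negative binomial
(mean ``nb_mean``, dispersion theta = ``nb_dispersion``, so the variance is
mean + mean^2/theta), multiplies the mean by a planted fold change for
pathway genes in an affected cell group, zeroes entries independently with
probability ``dropout_rate`` to emulate capture dropout, and optionally adds
Poisson-distributed extra counts on chosen gene/cell blocks to emulate
sample-specific (batch/patient) artifacts. This is deliberately the simplest
generator reproducing the sparsity and group structure the scoring method is
designed for; it makes no claim to model real library-size or gene-length
variation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from .core import score_collection
from .differential import NS, pairwise_analysis
from .errors import ValidationError
from .io_formats import COUNTS, ExpressionMatrix, GeneSet, GeneSetCollection, GroupAssignment
from .preprocess import cpm_normalize, filter_cells, filter_genes

logger = logging.getLogger(__name__)


@dataclass
class PathwayDef:
    """A planted pathway: which genes, which group is shifted, and how much.

    ``fold_change`` multiplies the NB mean for the pathway's genes in the
    affected group: > 1 plants upregulation, < 1 downregulation, 1 a null
    pathway. ``affected_group`` may be None for a pure null pathway.
    """

    name: str
    gene_indices: list
    affected_group: str | None = None
    fold_change: float = 1.0


@dataclass
class BatchDef:
    """An additive sample-specific artifact on a gene x cell block."""

    name: str
    cell_indices: list
    gene_indices: list
    offset: float          # mean extra counts added (Poisson-distributed)


@dataclass
class SyntheticSpec:
    """Full description of one synthetic data set."""

    n_genes: int
    group_sizes: list
    nb_mean: float = 2.0
    nb_dispersion: float = 0.5
    dropout_rate: float = 0.7
    pathway_defs: list = field(default_factory=list)
    batch_defs: list = field(default_factory=list)
    group_labels: list | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if any(s < 2 for s in self.group_sizes):
            raise ValidationError("every group size must be >= 2")
        if self.nb_mean <= 0 or self.nb_dispersion <= 0:
            raise ValidationError("nb_mean and nb_dispersion must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValidationError("dropout_rate must be in [0, 1)")
        if self.group_labels is None:
            self.group_labels = [f"group{i + 1}" for i in range(len(self.group_sizes))]
        if len(self.group_labels) != len(self.group_sizes):
            raise ValidationError("group_labels must match group_sizes")
        for pdef in self.pathway_defs:
            if pdef.fold_change <= 0:
                raise ValidationError(f"pathway {pdef.name!r}: fold_change must be > 0")
            if any(not 0 <= g < self.n_genes for g in pdef.gene_indices):
                raise ValidationError(f"pathway {pdef.name!r}: gene index out of range")
            if pdef.affected_group is not None and pdef.affected_group not in self.group_labels:
                raise ValidationError(f"pathway {pdef.name!r}: unknown group "
                                      f"{pdef.affected_group!r}")
        for bdef in self.batch_defs:
            if any(not 0 <= g < self.n_genes for g in bdef.gene_indices):
                raise ValidationError(f"batch {bdef.name!r}: gene index out of range")

    @property
    def n_cells(self) -> int:
        return int(sum(self.group_sizes))

    def gene_ids(self) -> np.ndarray:
        width = len(str(self.n_genes))
        return np.array([f"G{i:0{width}d}" for i in range(self.n_genes)], dtype=object)

    def cell_ids(self) -> np.ndarray:
        width = len(str(self.n_cells))
        return np.array([f"C{i:0{width}d}" for i in range(self.n_cells)], dtype=object)

    def cell_groups(self) -> np.ndarray:
        out = []
        for label, size in zip(self.group_labels, self.group_sizes):
            out.extend([label] * size)
        return np.array(out, dtype=object)

    def gene_sets(self) -> GeneSetCollection:
        """The planted pathways as a gene-set collection over the generated ids."""
        gids = self.gene_ids()
        sets = [GeneSet(name=p.name, genes=[gids[i] for i in p.gene_indices])
                for p in self.pathway_defs]
        return GeneSetCollection(sets=sets, source_path="<synthetic>")


@dataclass
class GroundTruth:
    """What was planted: per-pathway effect and per-cell group/batch labels."""

    pathways: list               # (name, affected_group, direction, fold_change)
    cell_groups: dict            # cell id -> group label
    cell_batches: dict           # cell id -> batch name (or "none")

    def planted(self) -> list:
        return [p for p in self.pathways if p[2] != "null"]

    def null_pathways(self) -> list:
        return [p[0] for p in self.pathways if p[2] == "null"]


def generate(spec: SyntheticSpec):
    """Draw one count matrix from the spec.

    Returns (ExpressionMatrix of counts, GroundTruth, GroupAssignment);
    bit-reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_g, n_c = spec.n_genes, spec.n_cells
    groups = spec.cell_groups()

    mean = np.full((n_g, n_c), float(spec.nb_mean))
    for pdef in spec.pathway_defs:
        if pdef.affected_group is None or pdef.fold_change == 1.0:
            continue
        cols = np.flatnonzero(groups == pdef.affected_group)
        mean[np.ix_(pdef.gene_indices, cols)] *= pdef.fold_change

    theta = spec.nb_dispersion
    p = theta / (theta + mean)
    counts = rng.negative_binomial(theta, p).astype(np.int64)
    if spec.dropout_rate > 0:
        counts[rng.random((n_g, n_c)) < spec.dropout_rate] = 0

    batch_of = np.full(n_c, "none", dtype=object)
    for bdef in spec.batch_defs:
        cols = np.asarray(bdef.cell_indices, dtype=int)
        rows = np.asarray(bdef.gene_indices, dtype=int)
        counts[np.ix_(rows, cols)] += rng.poisson(bdef.offset, (rows.size, cols.size))
        batch_of[cols] = bdef.name

    gids, cids = spec.gene_ids(), spec.cell_ids()
    matrix = ExpressionMatrix(sp.csr_matrix(counts), gids, cids, COUNTS)
    truth = GroundTruth(
        pathways=[(p_.name, p_.affected_group,
                   ("up" if p_.fold_change > 1 else "down") if
                   (p_.affected_group is not None and p_.fold_change != 1.0) else "null",
                   p_.fold_change)
                  for p_ in spec.pathway_defs],
        cell_groups=dict(zip(cids, groups)),
        cell_batches=dict(zip(cids, batch_of)),
    )
    return matrix, truth, GroupAssignment(mapping=dict(zip(cids, groups)))


# ---------------------------------------------------------------------------
# Standard study specs
# ---------------------------------------------------------------------------

def standard_recovery_spec(seed: int = 0) -> SyntheticSpec:
    """Two groups of 100 cells, ten 20-gene pathways over 600 genes.

    Pathway PW_UP is tripled and PW_DOWN is divided by three in the
    "treated" group; the other eight pathways are null. Negative-binomial
    mean 2, dispersion 0.5, dropout 0.7 — a sparse regime (roughly 83%
    zeros) typical of droplet data at shallow depth.
    """
    defs = [
        PathwayDef("PW_UP", list(range(0, 20)), "treated", 3.0),
        PathwayDef("PW_DOWN", list(range(20, 40)), "treated", 1 / 3.0),
    ]
    defs += [PathwayDef(f"PW_NULL{i:02d}", list(range(40 + 20 * i, 60 + 20 * i)))
             for i in range(8)]
    return SyntheticSpec(
        n_genes=600, group_sizes=[100, 100], group_labels=["control", "treated"],
        nb_mean=2.0, nb_dispersion=0.5, dropout_rate=0.7,
        pathway_defs=defs, seed=seed,
    )


def null_calibration_spec(seed: int = 0, n_null: int = 50,
                          genes_per_pathway: int = 10) -> SyntheticSpec:
    """Two exchangeable groups of 100 cells and only null pathways."""
    defs = [PathwayDef(f"NULL{i:02d}",
                       list(range(i * genes_per_pathway, (i + 1) * genes_per_pathway)))
            for i in range(n_null)]
    return SyntheticSpec(
        n_genes=n_null * genes_per_pathway + 100,
        group_sizes=[100, 100], group_labels=["g1", "g2"],
        nb_mean=2.0, nb_dispersion=0.5, dropout_rate=0.7,
        pathway_defs=defs, seed=seed,
    )


def patient_confounded_spec(seed: int = 0, cells_per_group: int = 80,
                            batch_offset: float = 5.0,
                            genes_per_pathway: int = 150) -> SyntheticSpec:
    """Three functional groups crossed with three synthetic patients.

    Each functional group has one strongly upregulated pathway (fold 4 over
    ``genes_per_pathway`` genes, sized like a typical hallmark set); three
    null pathways are shared. Cells are assigned to patients round-robin
    within each group, so patients cut across the functional structure, and
    each patient carries a Poisson(offset) additive artifact on its own
    60-gene block of non-pathway genes. In gene space the patient blocks
    dominate; in pathway space only the functional signal survives.
    """
    n_groups, n_patients = 3, 3
    g = genes_per_pathway
    defs = [PathwayDef(f"PW_GROUP{k + 1}", list(range(g * k, g * (k + 1))),
                       f"type{k + 1}", 4.0) for k in range(n_groups)]
    defs += [PathwayDef(f"PW_NULL{i}", list(range(3 * g + g * i, 3 * g + g * (i + 1))))
             for i in range(3)]
    pw_end = 6 * g
    n_cells = n_groups * cells_per_group
    batch_defs = []
    for pidx in range(n_patients):
        cells = [i for i in range(n_cells) if i % n_patients == pidx]
        genes = list(range(pw_end + 60 * pidx, pw_end + 60 * (pidx + 1)))
        batch_defs.append(BatchDef(f"patient{pidx + 1}", cells, genes, batch_offset))
    return SyntheticSpec(
        n_genes=pw_end + 60 * n_patients + 60,
        group_sizes=[cells_per_group] * n_groups,
        group_labels=[f"type{k + 1}" for k in range(n_groups)],
        nb_mean=2.0, nb_dispersion=0.5, dropout_rate=0.7,
        pathway_defs=defs, batch_defs=batch_defs, seed=seed,
    )


# ---------------------------------------------------------------------------
# Recovery experiments
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    """Power and type-I summary over generator replicates."""

    n_replicates: int
    power: dict                  # planted pathway name -> correct-direction call rate
    type_i_rate: float           # fraction of (null pathway, replicate) false calls
    n_null_pathways: int
    tau: float
    fdr_threshold: float

    def to_dict(self) -> dict:
        return {
            "n_replicates": self.n_replicates,
            "power": dict(self.power),
            "type_i_rate": self.type_i_rate,
            "n_null_pathways": self.n_null_pathways,
            "tau": self.tau,
            "fdr_threshold": self.fdr_threshold,
        }


def run_pipeline_once(spec: SyntheticSpec, tau: float = 5.0,
                      fdr_threshold: float = 0.01, min_genes: int | None = None,
                      min_cell_fraction: float = 0.10):
    """generate -> filter -> CPM -> score -> pairwise analysis, one replicate.

    ``min_genes`` defaults to 10% of the spec's gene count: the cell filter
    scaled to the synthetic matrix size.
    """
    if min_genes is None:
        min_genes = spec.n_genes // 10
    matrix, truth, groups = generate(spec)
    matrix, _ = filter_cells(matrix, min_genes=min_genes)
    matrix, _ = filter_genes(matrix, min_cell_fraction=min_cell_fraction)
    matrix = cpm_normalize(matrix)
    scores = score_collection(matrix, spec.gene_sets(), tau=tau)
    groups = GroupAssignment({c: g for c, g in groups.mapping.items()
                              if c in scores.frame.columns})
    calls = pairwise_analysis(scores, groups, fdr_threshold=fdr_threshold)
    return calls, truth, scores


def recovery_experiment(spec: SyntheticSpec, tau: float = 5.0,
                        n_replicates: int = 20, fdr_threshold: float = 0.01,
                        min_genes: int | None = None,
                        min_cell_fraction: float = 0.10) -> RecoveryReport:
    """Replicate the full pipeline and summarize detection of planted effects.

    Power for a planted pathway = fraction of replicates in which it is
    called in the correct direction in the affected group. The type-I rate
    pools null pathways: fraction of (null pathway, replicate, group) calls
    that are not "ns" in any group.
    """
    planted = {p.name: p for p in spec.pathway_defs
               if p.affected_group is not None and p.fold_change != 1.0}
    nulls = [p.name for p in spec.pathway_defs if p.name not in planted]
    hits = {name: 0 for name in planted}
    false_calls, null_trials = 0, 0
    for rep in range(n_replicates):
        rep_spec = replace(spec, seed=spec.seed + rep)
        calls, _, _ = run_pipeline_once(rep_spec, tau=tau,
                                        fdr_threshold=fdr_threshold,
                                        min_genes=min_genes,
                                        min_cell_fraction=min_cell_fraction)
        by_key = {(c.pathway, c.focal_group): c for c in calls}
        for name, pdef in planted.items():
            want = "up" if pdef.fold_change > 1 else "down"
            call = by_key.get((name, pdef.affected_group))
            if call is not None and call.direction == want:
                hits[name] += 1
        for name in nulls:
            null_trials += 1
            if any(c.direction != NS for c in calls if c.pathway == name):
                false_calls += 1
    return RecoveryReport(
        n_replicates=n_replicates,
        power={name: hits[name] / n_replicates for name in planted},
        type_i_rate=false_calls / null_trials if null_trials else 0.0,
        n_null_pathways=len(nulls), tau=tau, fdr_threshold=fdr_threshold,
    )
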
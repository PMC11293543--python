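# Methods

## The scoring model

The score of a gene set in cell $j$ is
$P_j = n_P^{-2} \sum_i \mathrm{rank}_i S_{ij}$ with
$S_{ij} = X_{ij}/NF_i$, computed on linear-scale TPM or CPM. The two design
ingredients address the two dominant pathologies of single-cell data:

- **Sparsity.** A per-gene scale estimate must be positive for almost all
  genes despite a large zero fraction, and robust to outlier cells. The
  median of the top-$\tau\%$ cells satisfies both: for a gene expressed in
  more than $\tau/2\%$ of cells it is positive, and it is a median, so a
  single extreme cell cannot move it. When even that median is zero (a gene
  expressed in very few cells) the gene's maximum is used so the gene still
  contributes rather than being dropped; an all-zero gene has no
  information and is assigned $NF_i = 0$ with $S_{ij} \equiv 0$.
- **Unequal information content.** Highly expressed genes are measured with
  better relative precision. Weighting by the rank of total expression
  (not by the magnitude itself) upweights them while bounding any single
  gene's influence by $n_P / n_P^2$.

Scores are nonnegative, finite, equivariant under cell permutation, and
invariant to per-gene rescaling that preserves the total-expression order.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `tau` | 5 (%) | top-cell window for the normalization median; the window is `max(1, ceil(tau/100 * n_cells))` cells |
| `weight_denominator` | `np_squared` | `np_squared` divides by $n_P^2$; `weighted_mean` divides by $n_P(n_P+1)/2$ so weights sum to 1 |
| `min_genes` | 1000 | cell filter: keep cells expressing at least this many genes |
| `min_cell_fraction` | 0.10 | gene filter: keep genes expressed in at least this fraction of the remaining cells |
| `fdr_threshold` | 0.01 | significance threshold on the per-group maximum FDR |
| `resolution` | 0.5 | Leiden resolution for pathway-space clustering |

Numerical conventions fixed for reproducibility: the median of an
even-sized window is the mean of the two central order statistics; ties in
total expression receive midranks, making ranking independent of gene
order; `ceil` rounding with a floor of one cell keeps the top-$\tau\%$
window nonempty on arbitrarily small data sets (groups of a handful of
cells are common in practice). The two denominators differ by a
per-pathway positive constant, so t-tests, FDRs, Z-scores, orderings and
clusterings are identical under either — only absolute score values change.

The tool warns (it does not refuse) when asked to score a matrix tagged as
log-scale: scores are only meaningful on linear TPM/CPM. Gene sets are
assumed single-direction: a set mixing induced and repressed genes averages
its signal away, so collections should be split by direction of change
before scoring.

## Preprocessing

Fixed order: de-log (only for matrices published on a log scale) → cell
filter → gene filter → CPM conversion (only for raw counts, after
filtering). Removal thresholds are strict-less: a cell expressing exactly
`min_genes` genes, or a gene expressed in exactly the minimum fraction of
cells, is kept. The de-log transform is $b^x - c$ clipped at zero, with
defaults $b = 2$, $c = 1$ — the $\log_2(x+1)$ convention that dominates
published matrices; since the publishing convention is rarely recorded, the
base and pseudocount are explicit configuration, and the target unit (TPM
vs CPM) must be declared by the caller. Per-cell-type filtering is done by
running the pipeline once per cell-type subset rather than through a
special code path.

## Differential protocol

For each pair of groups, each pathway's per-cell scores are compared with
an unpaired two-sided Student's t-test (pooled variance; Welch behind a
flag for heteroskedastic groups — "Student" is the literal protocol, the
flag an escape hatch). P-values are Benjamini–Hochberg-adjusted across
pathways *within each pair*; the per-(pathway, group) summary takes the
largest FDR over that group's pairs, and a direction is called only when
the median difference has a consistent sign against every other group and
that max FDR is below threshold. Direction comes from medians, not from
the t statistic's sign, so a skewed score distribution cannot flip a call.
Two conventions worth noting: BH is the adjustment procedure (the family
could alternatively be pooled across pairs; per-pair was chosen because the
max-over-pairs rule presupposes per-pair FDRs), and zero pooled variance
with equal means yields $t = 0$, $p = 1$ rather than NaN, while zero
variance with unequal means is an error, because the statistic is then
unbounded.

Calls are invariant to any per-pathway positive rescaling of scores —
which is also why the denominator choice above is downstream-neutral.

## Pathway space

Scores are standardized per pathway ($Z$-scores, sd with denominator
$n - 1$; constant rows become zeros and are flagged). Heatmap ordering
follows the protocol: within each group, cells ascend by mean $Z$ over the
group's upregulated pathways; pathway blocks are grouped by the calling
group and sorted by ascending max FDR. Clustering builds a Euclidean
k-nearest-neighbor graph on the cell vectors in $Z$-space (no PCA — the
space is at most a few dozen dimensions) and runs Leiden optimization of
RB-configuration modularity, which at a given resolution is the seeded,
deterministic equivalent of the Louvain modularity clustering standard in
single-cell toolkits. The 2-D embedding is UMAP on the same vectors.
Seeded determinism is a contract on one platform and library version, not
across versions.

## The synthetic generator

`synthetic.generate` draws counts $X_{ij} \sim \mathrm{NB}(\mu_{ij},
\theta)$ with $\mathrm{Var} = \mu + \mu^2/\theta$, where $\mu_{ij}$ is a
global mean multiplied by a planted fold change for pathway genes in an
affected group; entries are then zeroed independently with the dropout
probability, and sample-specific artifacts add Poisson-distributed extra
counts on designated gene × cell blocks (Poisson rather than a constant so
the artifact is count-valued and noisy like real ambient contamination).
Defaults — NB mean 2, dispersion 0.5, dropout 0.7 — give roughly 83%
zeros, a sparse droplet-like regime. What the generator deliberately does
**not** model: library-size variation between cells, gene-length effects,
mean–dispersion trends, correlated gene modules beyond the planted blocks,
and doublets. Passing tests therefore demonstrate correctness of the
algorithmic pipeline and its statistical calibration under idealized
sparsity, not performance on any real data set.

Three standard study conditions are provided:

- `standard_recovery_spec`: 600 genes, 2 × 100 cells, ten 20-gene
  pathways, one tripled and one divided by three in the treated group —
  the default power/robustness benchmark.
- `null_calibration_spec`: 50 disjoint 10-gene null pathways, 2 × 100
  exchangeable cells — type-I calibration.
- `patient_confounded_spec`: three functional groups (80 cells each), each
  with one fold-4 150-gene pathway (sized like a typical hallmark set and
  strong like a cell-state program, so groups are separable per cell, not
  just on average), crossed round-robin with three "patients" whose
  artifacts sit on disjoint 60-gene non-pathway blocks. In gene space the
  patient blocks dominate the geometry; in pathway space only the
  functional signal survives — the clustering benchmark.

In recovery experiments the cell filter is scaled to the generated matrix:
`min_genes` defaults to 10% of the gene count, the same proportion the
1000-gene default represents for a typical real matrix. Replicate $r$ uses
seed `spec.seed + r`; every stage is deterministic given the spec.

Problem sizes used by the test suite and the acceptance script (200 oracle
cases, 100 null replicates, 50 power replicates, a 5 000 × 10 000 sparse
scoring run) were chosen so the whole validation completes in about a
minute on a laptop-class CPU while keeping binomial sampling error on the
reported rates small.

## Known limitations

- Scores depend on the unit of the input; mixing TPM and CPM across cells,
  or scoring log-scale data, silently degrades results (a warning is
  emitted for the latter).
- The method is sensitive to extreme outlier cells through the max
  fallback; the preprocessing filters are part of the protocol, not
  optional hygiene.
- Bidirectional gene sets are out of scope by design (see above).
- The t-test assumes approximate normality of per-group score
  distributions; with very few cells per group the calls inherit the
  t-test's small-sample behavior.
- GMT gene matching is exact and case-sensitive by default; cross-species
  use requires the explicit uppercase-fold flag or pre-mapped identifiers.
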
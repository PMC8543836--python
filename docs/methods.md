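# Methods

## Model

TPSC treats a gene co-expression network as a physical field.  Nodes
(genes) carry masses `m_i > 0`; the strength of association between two
nodes is an edge weight `w_ij` (the Pearson correlation of their
expression profiles), converted to a distance `d_ij = 1/|w_ij|` (zero
weight → infinite distance).  Node `j` sitting in the field of node `i`
has topology potential energy

    e_p(i, j) = m_i m_j exp(−(d_ij/σ)²),   e_p(i, i) = 0.

Two properties of this definition matter.  First, it is symmetric in
the two masses, so the matrix `E_p` of pairwise energies is symmetric
even when masses differ — the classical one-sided potential component
`m_i exp(−(d_ij/σ)²)` is not, and a Laplacian normalized by it would
lose symmetry the moment prior knowledge is attached to nodes.  Second,
with unit masses it reduces exactly to the classical component, so the
unit-mass variant (TPSC-1) is a strict special case of the weighted
variant (TPSC-w), and the whole spectral machinery below coincides with
standard normalized spectral clustering of the Gaussian-kernel graph.
Both facts are asserted by the test suite.

With `E_Σ = diag(Σ_j e_p(i, j))`, the energy-corrected normalized
Laplacian is

    L = I − E_Σ^{−1/2} E_p E_Σ^{−1/2}.

Because `E_Σ` is exactly the row sum of the symmetric nonnegative
`E_p`, `L` is the symmetric normalized Laplacian of the weighted graph
with adjacency `E_p`: unit diagonal, positive semidefinite, spectrum in
[0, 2], `√E_Σ` in its null space, and — since a global mass rescaling
`m → c·m` multiplies `E_p` and `E_Σ` by `c²` alike — invariant under
uniform rescaling of all masses.  Only *relative* masses influence the
partition.

The classical per-node potential `φ_i = m_i Σ_{j≠i} exp(−(d_ij/σ)²)`
is also computed (as `PotentialField.phi`) but is not on the critical
path: the pipeline ranks candidate centers by the total energy `E_Σ`,
which is the quantity the Laplacian actually normalizes by.  For unit
masses the two rankings coincide; for heterogeneous masses we prefer
the symmetric quantity.

## Parameters

| parameter | default | units | meaning |
|-----------|---------|-------|---------|
| `r`       | 0.3     | —     | hard-threshold weight cutoff; edges with `|w| > r` survive into the binary graph used for center search.  0.3 is the conventional "meaningful linear correlation" cutoff for expression data. |
| `σ`       | `√2/(3r)` ≈ 1.5713 | distance | Gaussian impact factor.  Derived, not free: the field's influence range is `3σ/√2`, and its inverse is pinned to `r` so that pairs below the correlation cutoff sit beyond the influence range.  A user-supplied `σ` that breaks this identity triggers a consistency warning. |
| `d_min`   | 5       | edges | minimum degree (in the thresholded graph) a greedy center must have.  Raising it prunes peripheral centers; `k(d_min)` is non-increasing, and a plateau in that profile (inspectable with `tpsc profile-dmin`) indicates a stable module count. |
| `seed`    | 1       | —     | k-means seed; with center initialization the assignment is deterministic and the seed is immaterial. |

Prefiltering defaults (genes with zeros in > 50% of samples, then the
lowest 20% of means, then the lowest 10% of variances among survivors)
match common practice for tumor expression matrices.  The three filters
are applied sequentially, each to the survivors of the previous one;
quantile cutoffs use linear-interpolation empirical quantiles and ties
at the cutoff are kept, so the result is deterministic and
conservative.  Only the zero filter is idempotent — the quantile
filters are relative to the current gene set by construction.

## Cluster count and assignment

The greedy center search freezes node degrees at thresholding time.
This is a deliberate choice where the procedure was genuinely open:
frozen degrees make `k(d_min)` provably non-increasing (raising the
threshold can only truncate the greedy sequence earlier), keep the
default `d_min = 5` interpretable against the original graph, and are
what the monotone-profile heuristic assumes.  A `dynamic_degree` flag
recomputes degrees on the shrinking subgraph for comparison.  Likewise
the termination rule — encountering *any* top-ranked candidate below
`d_min` halts the whole search — is the default, with a
`skip_low_degree` flag for the variant that skips the candidate and
continues.  Score ties are broken by smallest node index.

The spectral stage is the standard symmetric-Laplacian pipeline: dense
eigendecomposition (`scipy.linalg.eigh`; networks here are fully
connected and of order 10³–10⁴ nodes, so sparse solvers buy nothing),
eigenvalues clamped into [0, 2] within 1e−8, the `k` smallest
eigenvectors row-normalized to unit length (a flag disables row
normalization), then k-means.  When greedy centers are available their
embedding rows initialize the centroids and a single k-means run is
performed — deterministic by construction; without centers, k-means++
with 10 restarts at a fixed seed.  scikit-learn's k-means reassigns any
empty cluster internally, so `k` is never silently reduced; a guard
raises if that invariant were ever violated.  Modules are renamed
`M1, M2, …` in decreasing size order, ties broken by the
lexicographically smallest member gene id, so output labels are stable
across runs and platforms.

## Downstream statistics

The module eigengene is the first right singular vector of the
per-gene standardized (zero-mean, unit-variance) module submatrix —
the established summary for co-expression modules — with its sign
chosen so that it correlates nonnegatively with the module's mean
standardized profile; this makes "up-regulated" (eigengene entry > 0)
well defined.  Zero-variance genes are dropped from the computation
with a warning.  Exactly-zero eigengene entries are assigned to the
down group: a probability-zero event for continuous data, but the tie
rule must be deterministic.

The two-group log-rank test is computed from first principles over the
pooled distinct event times (observed minus expected deaths with the
hypergeometric variance at each time, chi-square with 1 df); the test
suite checks it against a hand-computed six-subject table to 1e−10 and
against lifelines on 100 random datasets.  Benjamini–Hochberg
adjustment is the plain step-up arithmetic with monotonicity
enforcement, cross-checked against statsmodels.  Module overlaps use
the one-sided hypergeometric upper tail (enrichment), the convention
under which overlap p-values measure similarity between partitions.

## Synthetic data

`make_planted_expression` draws a latent factor per block and sets gene
`g` in block `b` to `√w·f_b + √(1−w)·ε_g`, so the population
within-block correlation is exactly `w` (`within_cor`, default 0.81);
block factors share a common component giving factor correlation
`between_cor` (hence gene-level cross-block correlation
`w · between_cor`).  `noise_sd` adds optional extra measurement noise
on top of the factor model (default 0, in which case the stated
correlations are exact).  The default design — three 20-gene blocks,
200 samples — gives empirical correlations within a few standard
errors of the population values, and the full pipeline recovers the
blocks exactly at the default parameters.

`make_planted_network` emits the corresponding *exact* block weight
matrix without sampling, for hand-traceable tests of the potential,
cluster-count and spectral stages.  `make_survival` draws exponential
event times with a group hazard ratio and independent exponential
censoring.

What the generator deliberately does not emulate: real expression
marginals (library-size effects, count noise, skewness), overlapping or
hierarchical modules, copy-number-driven positional correlation, or
hub-dominated scale-free degree structure.  Passing the recovery tests
therefore demonstrates correctness of the algorithmic chain under its
own model assumptions, not performance on tumor cohorts.

## Numerical choices and edge cases

- Zero edge weight → infinite distance → exactly zero energy (handled
  explicitly, not through floating-point overflow).
- A node whose total energy falls below 1e−300 is reported as isolated
  (it cannot be normalized) rather than yielding infinities.
- Thresholding is strict (`|w| > r`); boundary-equal weights carry no
  edge.
- Negative correlations: distances and thresholding use `|w|` by
  default (`correlation_mode="absolute"`), so anti-correlated genes are
  treated as strongly associated; `correlation_mode="positive-only"`
  instead zeroes negative weights.  Which convention is biologically
  right depends on whether repression should co-modularize with
  activation — the package exposes both.
- Problem sizes in the test suite (networks ≤ 60 nodes, ≤ 200 samples,
  ≤ 500 survival simulations) were chosen so the planted structure is
  recovered with comfortable statistical margins while the whole suite
  runs in seconds.

## Known limitations

- The distance `1/|w|` is undefined in spirit for `w = 0` pairs; they
  simply contribute nothing to any node's field, which is the intended
  limit but means extremely sparse correlation structures can produce
  isolated-node errors at small `σ`.
- `k` is bounded above by the number of greedy centers the thresholded
  graph supports; on graphs with no node of degree ≥ `d_min` the
  pipeline refuses to run rather than guessing a cluster count.
- The eigengene summarizes a module by one dimension; modules whose
  expression is genuinely multi-factorial will have low explained
  variance fraction (reported on the `Eigengene` object) and their
  survival split should be interpreted with care.
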
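# tpsc — topology-potential-based spectral clustering

`tpsc` detects co-expression modules in fully connected weighted gene
networks — and, more generally, partitions any weighted network — by
combining a field-theoretic node score (the *topology potential*) with
spectral clustering.  It is aimed at computational biologists who want
module detection with complete gene coverage, balanced module sizes, and
the option to steer the partition with prior knowledge such as
gene–disease-association (GDA) scores.

## The method

Given genes with pairwise Pearson correlations `w_ij`, define distances
`d_ij = 1/|w_ij|` and a Gaussian impact factor `σ`.  Each node carries a
mass `m_i > 0` (all ones for the **TPSC-1** variant; prior-knowledge
scores in (0, 1] for **TPSC-w**).  The pairwise *topology potential
energy*

    e_p(i, j) = m_i · m_j · exp(−(d_ij/σ)²),    e_p(i, i) = 0,

is symmetric in its two masses, so the energy-corrected normalized
Laplacian

    L = I − E_Σ^{−1/2} E_p E_Σ^{−1/2},   E_Σ = diag(Σ_j e_p(i, j)),

stays symmetric even with heterogeneous node masses, with spectrum in
[0, 2] and `√E_Σ` in its null space.

The number of modules `k` is not a user guess: the network is
hard-thresholded (`|w_ij| > r`, default `r = 0.3`), and a greedy search
repeatedly takes the highest-energy remaining node as a module center,
dropping it and its first-order neighbors from the pool; a candidate
whose degree falls below `d_min` (default 5) terminates the search.  The
cutoff and the field scale are tied together: the inverse of the field's
influence range `3σ/√2` is kept equal to `r`, so `σ = √2/(3r) ≈ 1.57` at
the default cutoff.  The centers seed k-means on the row-normalized
smallest-`k` eigenvector embedding of `L`, which makes the partition
deterministic and guarantees every gene lands in exactly one module.

Downstream, each module is summarized by its *eigengene* (first singular
vector of the standardized module submatrix); the sign of each patient's
eigengene entry splits the cohort into up-/down-regulated groups whose
survival curves are compared with a log-rank test (Benjamini–Hochberg
adjusted across modules), and partitions are compared module-by-module
with one-sided Fisher exact overlap tests.

## Worked example

```python
from tpsc import PlantedDesign, make_planted_expression, make_survival, \
    module_survival_table, tpsc

design = PlantedDesign(block_sizes=[20, 20, 20], within_cor=0.81,
                       between_cor=0.0, n_samples=200, seed=1)
expr, true_labels, _ = make_planted_expression(design)

result = tpsc(expr=expr, seed=1)
print(f"variant={result.variant}  k={result.k}  sigma={result.sigma:.4f}")
print("module sizes:", result.partition.module_sizes())
```

prints

```
variant=tpsc1  k=3  sigma=1.5713
module sizes: {'M1': 20, 'M2': 20, 'M3': 20}
```

The three planted 20-gene blocks are recovered exactly (adjusted Rand
index 1.0 against `true_labels`), `k = 3` was selected automatically by
the greedy center search, and `σ = 1.5713` is the impact factor derived
from the default cutoff `r = 0.3`.  Adding synthetic survival data
screens each module's eigengene split:

```python
groups = {s: int(i >= 100) for i, s in enumerate(expr.sample_ids)}
surv = make_survival(groups, hazard_ratio=2.0, seed=1)
print(module_survival_table(expr, result.partition, surv).to_string(index=False))
```

```
module  size  n_up  n_down  logrank_stat  p_value  q_value
    M1    20    98     102      0.238155 0.625542 0.760832
    M2    20   101      99      0.092652 0.760832 0.760832
    M3    20    96     104      6.147229 0.013162 0.039485
```

Here the synthetic hazard split is unrelated to the planted blocks, so
most modules are null; M3's eigengene happens to track the group split
for this seed.  The same pipeline runs from the shell:

```
tpsc simulate --blocks 20,20,20 --samples 200 --seed 1 --out-prefix demo
tpsc run --expr demo_expression.tsv --survival demo_survival.tsv \
         --mean-pct 0 --var-pct 0 --seed 1 --out demo_modules.tsv
```

which writes the module table, a per-module survival summary, and a JSON
manifest recording every parameter and seed.  Real data enters as a
genes × samples expression TSV (optionally with `--node-weights` for a
gene-mass table, which switches to TPSC-w).

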
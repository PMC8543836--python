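"""Module-level summaries: eigengenes, survival stratification, and
module-overlap testing.

The eigengene of a module is the first right singular vector of its
per-gene standardized expression submatrix, signed so that it correlates
nonnegatively with the module's mean standardized profile.  The sign of
each sample's eigengene entry splits the cohort into "up-regulated" and
"down-regulated" groups, whose survival curves are compared with a
two-group log-rank test; module overlaps between two partitions are
scored with a one-sided Fisher exact (hypergeometric upper-tail) test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "Eigengene",
    "SurvivalComparison",
    "OverlapTest",
    "eigengene",
    "split_by_eigengene",
    "logrank_test",
    "bh_fdr",
    "overlap_fisher",
    "module_survival_table",
    "overlap_matrix",
]


@dataclass
class Eigengene:
    """First singular vector summarizing one module's expression."""

    module_label: str
    sample_ids: list
    values: np.ndarray
    explained_variance_fraction: float

    def series(self) -> pd.Series:
        return pd.Series(self.values, index=self.sample_ids)


@dataclass
class SurvivalComparison:
    """Two-group log-rank comparison for one module's eigengene split."""

    module_label: str
    n_up: int
    n_down: int
    statistic: float
    p_value: float
    q_value: float = None


@dataclass
class OverlapTest:
    """One-sided Fisher exact test of the overlap of two gene sets."""

    module_a: str
    module_b: str
    overlap_count: int
    size_a: int
    size_b: int
    universe_size: int
    p_value: float


def eigengene(expr_sub: ExpressionMatrix, module_label: str = "M1") -> Eigengene:
    """Compute the module eigengene.

    Genes are standardized (zero mean, unit variance across samples);
    the eigengene is the first right singular vector of the resulting
    genes x samples matrix, unit norm, with sign chosen so its
    correlation with the per-sample mean standardized expression is
    nonnegative.  Zero-variance genes are dropped with a warning.
    """
    if expr_sub.n_samples < 2:
        raise ValidationError("eigengene needs >= 2 samples")
    X = expr_sub.values
    sd = X.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        logger.warning(
            "module %s: dropping %d zero-variance genes from eigengene",
            module_label, int((~keep).sum()),
        )
        X, sd = X[keep], sd[keep]
    if X.shape[0] == 0:
        raise ValidationError("no genes with nonzero variance in module")
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    _, s, Vt = np.linalg.svd(Z, full_matrices=False)
    v = Vt[0]
    mean_profile = Z.mean(axis=0)
    if float(v @ mean_profile) < 0:
        v = -v
    ev = float(s[0] ** 2 / (s**2).sum())
    return Eigengene(
        module_label=module_label,
        sample_ids=list(expr_sub.sample_ids),
        values=v,
        explained_variance_fraction=ev,
    )


def split_by_eigengene(eig: Eigengene, survival: pd.DataFrame):
    """Split samples with survival data by eigengene sign.

    Returns ``(up_ids, down_ids)``: samples with eigengene entry > 0 vs
    <= 0 (exact zeros, probability-zero in continuous data, go to the
    down group for determinism).  Raises if either group is empty.
    """
    es = eig.series()
    common = [s for s in es.index if s in survival.index]
    if not common:
        raise ValidationError("no samples shared between eigengene and survival")
    vals = es.loc[common]
    n_zero = int((vals == 0).sum())
    if n_zero:
        logger.warning("%d exactly-zero eigengene entries assigned to down group",
                       n_zero)
    up = [s for s in common if vals[s] > 0]
    down = [s for s in common if vals[s] <= 0]
    if not up or not down:
        raise ValidationError(
            "eigengene sign puts every sample in one group; log-rank undefined"
        )
    return up, down


def logrank_test(group_a, group_b, survival: pd.DataFrame,
                 module_label: str = "") -> SurvivalComparison:
    """Two-group log-rank test (1 df chi-square) from pooled event times.

    At each distinct event time t, with n_a(t) at risk in group A of
    n(t) total and d(t) pooled deaths, the observed-minus-expected
    contribution for A is d_a(t) - d(t) n_a(t)/n(t) with hypergeometric
    variance d(t) (n_a/n) (1 - n_a/n) (n - d)/(n - 1).
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValidationError("both groups must be nonempty")
    if set(group_a) & set(group_b):
        raise ValidationError("groups overlap")
    missing = [s for s in group_a + group_b if s not in survival.index]
    if missing:
        raise ValidationError(f"samples without survival data: {missing[:5]}")

    t_a = survival.loc[group_a, "time"].to_numpy(float)
    e_a = survival.loc[group_a, "event"].to_numpy(int)
    t_b = survival.loc[group_b, "time"].to_numpy(float)
    e_b = survival.loc[group_b, "event"].to_numpy(int)
    if e_a.sum() + e_b.sum() == 0:
        raise ValidationError("no observed events; log-rank undefined")

    event_times = np.unique(np.concatenate([t_a[e_a == 1], t_b[e_b == 1]]))
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        na = int((t_a >= t).sum())
        nb = int((t_b >= t).sum())
        n = na + nb
        da = int(((t_a == t) & (e_a == 1)).sum())
        db = int(((t_b == t) & (e_b == 1)).sum())
        d = da + db
        if n <= 1 or d == 0:
            continue
        o_minus_e += da - d * na / n
        var += d * (na / n) * (1 - na / n) * (n - d) / (n - 1)
    if var == 0:
        stat, p = 0.0, 1.0
    else:
        stat = o_minus_e**2 / var
        p = float(stats.chi2.sf(stat, df=1))
    return SurvivalComparison(
        module_label=module_label, n_up=len(group_a), n_down=len(group_b),
        statistic=float(stat), p_value=p,
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def overlap_fisher(genes_a, genes_b, universe) -> OverlapTest:
    """One-sided (enrichment) Fisher exact test of two gene sets.

    p = P[overlap >= observed] under the hypergeometric null of drawing
    |b| genes from the universe with |a| marked.
    """
    a, b, u = set(genes_a), set(genes_b), set(universe)
    if not a or not b:
        raise ValidationError("gene sets must be nonempty")
    if not (a <= u and b <= u):
        raise ValidationError("gene sets must be subsets of the universe")
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, len(u), len(a), len(b)))
    return OverlapTest(
        module_a="A", module_b="B", overlap_count=k,
        size_a=len(a), size_b=len(b), universe_size=len(u),
        p_value=min(p, 1.0),
    )


def module_survival_table(expr: ExpressionMatrix, partition,
                          survival: pd.DataFrame) -> pd.DataFrame:
    """Per-module eigengene survival screen.

    For each module: compute its eigengene, split patients by sign,
    run the log-rank test, then adjust all module p-values by
    Benjamini-Hochberg.  Modules whose split degenerates (one empty
    group) are reported with NaN statistics.
    """
    rows = []
    for lab in range(1, partition.k + 1):
        name = f"M{lab}"
        genes = partition.members(lab)
        eig = eigengene(expr.subset(genes), module_label=name)
        try:
            up, down = split_by_eigengene(eig, survival)
            res = logrank_test(up, down, survival, module_label=name)
            rows.append((name, len(genes), len(up), len(down),
                         res.statistic, res.p_value))
        except ValidationError as exc:
            logger.warning("module %s survival split failed: %s", name, exc)
            rows.append((name, len(genes), np.nan, np.nan, np.nan, np.nan))
    df = pd.DataFrame(
        rows, columns=["module", "size", "n_up", "n_down", "logrank_stat", "p_value"]
    )
    ok = df["p_value"].notna()
    q = np.full(len(df), np.nan)
    if ok.any():
        q[ok.to_numpy()] = bh_fdr(df.loc[ok, "p_value"].to_numpy())
    df["q_value"] = q
    return df


def overlap_matrix(partition_a, partition_b, universe=None) -> pd.DataFrame:
    """Pairwise overlap Fisher p-values between two module partitions."""
    if universe is None:
        universe = sorted(set(partition_a.node_ids) | set(partition_b.node_ids))
    rows = []
    for la in range(1, partition_a.k + 1):
        ga = partition_a.members(la)
        for lb in range(1, partition_b.k + 1):
            gb = partition_b.members(lb)
            t = overlap_fisher(ga, gb, universe)
            rows.append((f"M{la}", f"M{lb}", t.overlap_count, t.p_value))
    return pd.DataFrame(rows, columns=["module_a", "module_b", "overlap", "p_value"])
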
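"""Tabular I/O and expression prefiltering.

All files are tab-separated UTF-8 with a mandatory header row and ``.`` as
the decimal separator.  Expression tables are genes x samples with gene
identifiers in the first column; node-mass tables are two columns
(gene id, mass); survival tables are three columns
(sample id, time, event).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import EmptyResultError, ParseError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "prefilter_expression",
    "read_node_masses",
    "read_survival",
    "read_weight_matrix",
    "write_modules",
    "read_modules",
]


@dataclass
class ExpressionMatrix:
    """A genes x samples numeric expression table.

    Parameters
    ----------
    gene_ids : list of str
        Unique gene identifiers, one per row of ``values``.
    sample_ids : list of str
        Unique sample identifiers, one per column of ``values``.
    values : ndarray of shape (n_genes, n_samples)
        Expression values in whatever (pre-normalized) units the input
        provided.  No missing entries.
    """

    gene_ids: list = field(default_factory=list)
    sample_ids: list = field(default_factory=list)
    values: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dup = pd.Index(ids)[pd.Index(ids).duplicated()]
            if len(dup):
                raise ValidationError(f"duplicate {name} ids: {sorted(set(dup))}")
        if not np.isfinite(self.values).all():
            raise ValidationError("expression matrix contains non-finite entries")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, genes) -> "ExpressionMatrix":
        """Return the submatrix restricted to ``genes`` (order preserved)."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise ValidationError(f"genes not in matrix: {missing[:5]}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[rows])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


def read_expression(path, missing: str = "error") -> ExpressionMatrix:
    """Read a genes x samples expression TSV.

    Parameters
    ----------
    path : str or Path
        TSV file; first column gene ids, header row sample ids.
    missing : {"error", "drop-gene"}
        Policy for missing/non-numeric cells.  ``"error"`` (default)
        raises; ``"drop-gene"`` silently removes affected gene rows.
    """
    if missing not in ("error", "drop-gene"):
        raise ValidationError(f"unknown missing policy {missing!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    body = df.apply(pd.to_numeric, errors="coerce")
    bad = body.isna()
    if bad.values.any():
        if missing == "error":
            r, c = np.argwhere(bad.values)[0]
            raise ParseError(
                f"non-numeric cell at gene {df.index[r]!r}, sample {df.columns[c]!r}"
            )
        keep = ~bad.any(axis=1)
        logger.warning("dropping %d genes with missing values", int((~keep).sum()))
        body = body.loc[keep]
    if body.shape[0] == 0 or body.shape[1] == 0:
        raise EmptyResultError(f"no usable expression data in {path}")
    return ExpressionMatrix(
        [str(g) for g in body.index], [str(s) for s in body.columns], body.values
    )


def prefilter_expression(
    expr: ExpressionMatrix,
    zero_frac: float = 0.5,
    mean_pct: float = 0.20,
    var_pct: float = 0.10,
) -> ExpressionMatrix:
    """Apply the three expression prefilters, in sequence.

    1. drop genes whose expression is zero in *strictly more than*
       ``zero_frac`` of samples;
    2. of the survivors, drop genes whose mean is strictly below the
       ``mean_pct`` empirical quantile of survivor means;
    3. of those survivors, drop genes whose variance is strictly below
       the ``var_pct`` quantile of survivor variances.

    Quantiles use linear interpolation (numpy default); genes tied with
    the quantile value are kept, so the filters are conservative and
    deterministic.
    """
    if expr.n_genes == 0:
        raise EmptyResultError("empty expression matrix")
    for name, q in (("mean_pct", mean_pct), ("var_pct", var_pct)):
        if not 0 <= q < 1:
            raise ValidationError(f"{name} must be in [0, 1), got {q}")
    if not 0 <= zero_frac <= 1:
        raise ValidationError(f"zero_frac must be in [0, 1], got {zero_frac}")

    X = expr.values
    keep = (X == 0).mean(axis=1) <= zero_frac
    X, genes = X[keep], [g for g, k in zip(expr.gene_ids, keep) if k]
    if len(genes) == 0:
        raise EmptyResultError("zero-fraction filter removed every gene")

    for stat_fn, q in ((lambda M: M.mean(axis=1), mean_pct),
                       (lambda M: M.var(axis=1, ddof=1), var_pct)):
        stat = stat_fn(X)
        cut = np.quantile(stat, q)
        keep = stat >= cut
        X, genes = X[keep], [g for g, k in zip(genes, keep) if k]
        if len(genes) == 0:
            raise EmptyResultError("quantile filter removed every gene")

    logger.info("prefilter kept %d of %d genes", len(genes), expr.n_genes)
    return ExpressionMatrix(genes, list(expr.sample_ids), X)


def read_node_masses(path, genes) -> tuple:
    """Read a gene -> mass table and align it to ``genes``.

    Masses must be in (0, 1]; genes absent from the table or with
    non-positive mass are excluded (logged).  Returns
    ``(kept_genes, mass_vector)`` with the two aligned.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ParseError(f"node-mass table {path} needs >= 2 columns")
    ids = df.iloc[:, 0].astype(str)
    if ids.duplicated().any():
        raise ValidationError("duplicate gene ids in node-mass table")
    mass = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    if mass.isna().any():
        raise ParseError("non-numeric mass value in node-mass table")
    table = dict(zip(ids, mass))

    kept, values = [], []
    n_dropped = 0
    for g in genes:
        m = table.get(g)
        if m is None or m <= 0:
            n_dropped += 1
            continue
        kept.append(g)
        values.append(float(m))
    if n_dropped:
        logger.warning(
            "%d genes excluded from TPSC-w run (absent or mass <= 0)", n_dropped
        )
    if not kept:
        raise ValidationError("no overlap between node-mass table and gene list")
    return kept, np.asarray(values)


def read_survival(path) -> pd.DataFrame:
    """Read a survival TSV (sample id, time, event) into a DataFrame.

    Returns a frame indexed by sample id with columns ``time``
    (nonnegative float) and ``event`` (0 censored / 1 death).
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 3:
        raise ParseError(f"survival table {path} needs >= 3 columns")
    out = pd.DataFrame(
        {
            "time": pd.to_numeric(df.iloc[:, 1], errors="coerce").to_numpy(),
            "event": pd.to_numeric(df.iloc[:, 2], errors="coerce").to_numpy(),
        },
        index=pd.Index(df.iloc[:, 0].astype(str)),
    )
    if out.index.duplicated().any():
        raise ValidationError("duplicate sample ids in survival table")
    if out.isna().values.any():
        raise ParseError("non-numeric time/event in survival table")
    if (out["time"] < 0).any():
        raise ValidationError("negative survival times")
    if not out["event"].isin([0, 1]).all():
        raise ValidationError("event indicator must be 0 or 1")
    out["event"] = out["event"].astype(int)
    return out


def read_weight_matrix(path) -> tuple:
    """Read a symmetric node x node weight matrix TSV.

    Header row and first column both carry node ids and must agree.
    Returns ``(node_ids, W)``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(i) for i in df.index]
    if ids != [str(c) for c in df.columns]:
        raise ValidationError("weight matrix row and column ids differ")
    W = df.values.astype(float)
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValidationError("weight matrix is not symmetric")
    return ids, W


def write_modules(partition, path) -> None:
    """Write a module-membership TSV (columns gene_id, module_label)."""
    partition.to_frame().to_csv(path, sep="\t", index=False)


def read_modules(path) -> pd.DataFrame:
    """Read a module-membership TSV back into a DataFrame."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["gene_id", "module_label"]:
        raise ParseError(f"unexpected module table header in {path}")
    return df
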
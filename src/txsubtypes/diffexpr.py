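"""Per-gene two-group differential expression with FDR control, and the
core/unique partition of significant genes.

The test is the two-sample t test (pooled variance by default — the
classical "Student" form; Welch by flag) with Benjamini–Hochberg step-up
q-values.  Significance gating defaults to q < 0.05.  Given two
significant sets against a common control, genes split into a *core*
(significant in both contrasts) and sets *unique* to either contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix

__all__ = [
    "DEResult",
    "GenePartition",
    "t_test_two_group",
    "bh_fdr",
    "differential_genes",
    "partition_genes",
]


def t_test_two_group(values: np.ndarray, idx1, idx2,
                     variance_mode: str = "pooled"
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise two-sample t test between the columns *idx1* and *idx2*.

    Returns ``(t, p, degenerate)``.  Rows where both groups have zero
    variance are degenerate: equal means give ``t = 0, p = 1``; unequal
    means are infinitely separated and get ``p = 0`` with the degenerate
    flag set (t carries the sign of the difference as +/-inf).
    """
    if variance_mode not in ("pooled", "welch"):
        raise ValueError(f"variance_mode must be 'pooled' or 'welch', got {variance_mode!r}")
    a = np.asarray(values, dtype=float)[:, list(idx1)]
    b = np.asarray(values, dtype=float)[:, list(idx2)]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-constant rows are handled explicitly below; silence scipy's
        # precision-loss warning for them
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=(variance_mode == "pooled"))
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    zero_var = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    diff = a.mean(axis=1) - b.mean(axis=1)
    degenerate = zero_var & (diff != 0)
    t[zero_var & (diff == 0)] = 0.0
    p[zero_var & (diff == 0)] = 1.0
    t[degenerate] = np.sign(diff[degenerate]) * np.inf
    p[degenerate] = 0.0
    # zero variance in only one group: scipy already yields finite t/p for
    # welch? it yields nan when pooled variance is 0; treat any residual nan
    # from exactly-equal data as "no evidence".
    residual = np.isnan(p)
    t[residual] = 0.0
    p[residual] = 1.0
    return t, p, degenerate


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, input order preserved.

    q_(i) = min_{j >= i} (m * p_(j) / j), clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


@dataclass
class DEResult:
    """Per-gene statistics for one two-group contrast."""

    group1: str
    group2: str
    table: pd.DataFrame = field(repr=False)  # mean_group1, mean_group2, t, p, q, direction
    alpha: float = 0.05
    gate: str = "q"  # significance gated on q-values ("q") or raw p ("p")

    @property
    def significant(self) -> set[str]:
        col = self.table["q"] if self.gate == "q" else self.table["p"]
        return set(self.table.index[col < self.alpha])


def differential_genes(matrix: ExpressionMatrix, group1_samples, group2_samples,
                       alpha: float = 0.05, variance_mode: str = "pooled",
                       gate: str = "q",
                       group1: str = "group1", group2: str = "group2"
                       ) -> DEResult:
    """Test every gene between two sample groups; gate significance at
    q < *alpha* (or raw p with ``gate="p"``).

    Direction is "up" when group1's mean exceeds group2's.
    """
    if gate not in ("q", "p"):
        raise ValueError("gate must be 'q' or 'p'")
    col = {s: i for i, s in enumerate(matrix.sample_ids)}
    idx1 = [col[s] for s in group1_samples]
    idx2 = [col[s] for s in group2_samples]
    if set(idx1) & set(idx2):
        raise ValueError("the two groups share samples")
    t, p, degenerate = t_test_two_group(matrix.values, idx1, idx2, variance_mode)
    q = bh_fdr(p)
    mean1 = matrix.values[:, idx1].mean(axis=1)
    mean2 = matrix.values[:, idx2].mean(axis=1)
    table = pd.DataFrame(
        {
            "mean_group1": mean1,
            "mean_group2": mean2,
            "t": t,
            "p": p,
            "q": q,
            "direction": np.where(mean1 >= mean2, "up", "down"),
            "degenerate": degenerate,
        },
        index=pd.Index(matrix.gene_ids, name="gene_id"),
    )
    return DEResult(group1, group2, table, alpha=alpha, gate=gate)


@dataclass
class GenePartition:
    """Core/unique split of two significant gene sets over one universe.

    core = significant in both contrasts; unique_a/unique_b = significant
    in exactly one.  The three sets are pairwise disjoint by construction.
    """

    core: set[str]
    unique_a: set[str]
    unique_b: set[str]

    def as_dict(self) -> dict[str, list[str]]:
        return {
            "core": sorted(self.core),
            "unique_a": sorted(self.unique_a),
            "unique_b": sorted(self.unique_b),
        }


def partition_genes(significant_a: set[str], significant_b: set[str]
                    ) -> GenePartition:
    """Set algebra: core = A ∩ B, unique_a = A \\ B, unique_b = B \\ A."""
    a = set(significant_a)
    b = set(significant_b)
    return GenePartition(core=a & b, unique_a=a - b, unique_b=b - a)
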
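"""Expression-matrix normalization and variance/intensity filtering.

The filter mirrors the classic two-criterion gate used for array data:
keep genes whose min–max-scaled mean intensity exceeds a floor (high
expression) and whose coefficient of variation exceeds a floor (high
variability).  Both statistics are computed on the original log2 scale;
z-scoring comes after filtering, since every per-gene CV is undefined once
row means are zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix

__all__ = [
    "FilterConfig",
    "FilterReport",
    "ZeroVarianceError",
    "zscore_normalize",
    "compute_gene_stats",
    "filter_genes",
]


class ZeroVarianceError(ValueError):
    """A gene row has zero variance, so it cannot be z-scored."""

    def __init__(self, gene_ids):
        self.gene_ids = list(gene_ids)
        preview = ", ".join(map(repr, self.gene_ids[:10]))
        more = "" if len(self.gene_ids) <= 10 else f" (+{len(self.gene_ids) - 10} more)"
        super().__init__(
            f"zero-variance gene rows cannot be z-scored: {preview}{more}; "
            "drop them (e.g. with filter_genes) first")


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the expression/variability gene filter.

    scaled_expression_min : floor on the min–max-scaled per-gene mean
        (unitless, in [0, 1]); default 0.12.
    cv_min : floor on the per-gene coefficient of variation sd/mean
        (unitless); default 0.12.

    Gates are strict (statistic > threshold).  A threshold of exactly 0
    disables its criterion: with a strict gate a zero floor would still
    drop the minimum-mean gene (scaled mean exactly 0) or constant genes,
    which is not what "no filtering" means.
    """

    scaled_expression_min: float = 0.12
    cv_min: float = 0.12

    def __post_init__(self) -> None:
        if self.scaled_expression_min < 0 or self.cv_min < 0:
            raise ValueError("filter thresholds must be >= 0")


@dataclass
class FilterReport:
    """Per-gene statistics and pass flags from :func:`filter_genes`."""

    n_input_genes: int
    n_retained_genes: int
    stats: pd.DataFrame = field(repr=False)
    config: FilterConfig = field(default_factory=FilterConfig)

    @property
    def retained_gene_ids(self) -> list[str]:
        return list(self.stats.index[self.stats["retained"]])


def compute_gene_stats(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene mean, sample sd (n-1 denominator), CV = sd/mean, and the
    min–max-scaled mean across genes.

    CV is undefined for genes with mean <= 0; those rows get ``cv = NaN``
    and automatically fail any positive CV threshold.
    """
    values = matrix.values
    means = values.mean(axis=1)
    sds = values.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cvs = np.where(means > 0, sds / means, np.nan)
    span = means.max() - means.min()
    if span > 0:
        scaled = (means - means.min()) / span
    else:
        scaled = np.zeros_like(means)
    return pd.DataFrame(
        {"mean": means, "sd": sds, "cv": cvs, "scaled_mean": scaled},
        index=pd.Index(matrix.gene_ids, name="gene_id"),
    )


def filter_genes(matrix: ExpressionMatrix, config: FilterConfig | None = None
                 ) -> tuple[ExpressionMatrix, FilterReport]:
    """Keep genes with scaled mean and CV strictly above their thresholds.

    Returns the filtered matrix and a :class:`FilterReport` recording both
    criteria independently per gene.

    Raises
    ------
    ValueError
        If no gene survives; the thresholds are then too strict for the
        data at hand.
    """
    config = config or FilterConfig()
    stats = compute_gene_stats(matrix)
    n = len(stats)
    if config.scaled_expression_min > 0:
        pass_expr = stats["scaled_mean"].to_numpy() > config.scaled_expression_min
    else:
        pass_expr = np.ones(n, dtype=bool)
    if config.cv_min > 0:
        pass_cv = np.nan_to_num(stats["cv"].to_numpy(), nan=-np.inf) > config.cv_min
    else:
        pass_cv = np.ones(n, dtype=bool)
    retained = pass_expr & pass_cv
    stats = stats.assign(pass_expression=pass_expr, pass_cv=pass_cv,
                         retained=retained)
    if not retained.any():
        raise ValueError(
            "no genes pass the filter; lower scaled_expression_min "
            f"({config.scaled_expression_min}) and/or cv_min ({config.cv_min})")
    kept = [g for g, keep in zip(matrix.gene_ids, retained) if keep]
    report = FilterReport(
        n_input_genes=matrix.n_genes,
        n_retained_genes=int(retained.sum()),
        stats=stats,
        config=config,
    )
    return matrix.subset_genes(kept), report


def zscore_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Z-score every gene row to mean 0, sample sd 1 (n-1 denominator).

    Raises
    ------
    ZeroVarianceError
        Listing the offending gene ids if any row is constant.
    """
    values = matrix.values
    means = values.mean(axis=1, keepdims=True)
    sds = values.std(axis=1, ddof=1, keepdims=True)
    zero = np.flatnonzero(sds.ravel() == 0)
    if zero.size:
        raise ZeroVarianceError([matrix.gene_ids[i] for i in zero])
    return ExpressionMatrix(matrix.gene_ids, matrix.sample_ids,
                            (values - means) / sds, matrix.groups)
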
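"""Median-split stratification and clustering concordance.

The cohort is divided at the sample median of a single marker gene's log2
expression: samples strictly above the cutoff are HIGH, the rest LOW (ties at
the median go to LOW, so an odd cohort with distinct values splits
(n+1)/2 LOW vs (n-1)/2 HIGH).  A median-absolute-deviation filter selects
variably expressed genes, and hierarchical clustering over those genes
quantifies how well unsupervised structure recapitulates the strata.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import DegenerateDataError, ValidationError
from .io import ExpressionMatrix
from .simulate import HIGH, LOW


@dataclass
class StratificationResult:
    label_of: pd.Series  # sample id -> HIGH | LOW
    cutoff: float
    marker_gene: str

    def samples(self, label: str) -> list[str]:
        return list(self.label_of.index[self.label_of == label])

    @property
    def n_high(self) -> int:
        return int((self.label_of == HIGH).sum())

    @property
    def n_low(self) -> int:
        return int((self.label_of == LOW).sum())


@dataclass
class ConcordanceReport:
    concordant_fraction: dict[str, float]  # per stratum
    cluster_sizes: tuple[int, int]
    n_genes_used: int


def median_split(expr: ExpressionMatrix, marker: str) -> StratificationResult:
    """Label samples HIGH/LOW at the sample median of the marker gene."""
    marker = marker.upper()
    if marker not in expr.values.index:
        raise ValidationError(f"marker gene {marker!r} not in expression matrix")
    vals = expr.values.loc[marker]
    if float(vals.max()) == float(vals.min()):
        raise DegenerateDataError(f"marker {marker!r} is constant; split is degenerate")
    cutoff = float(np.median(vals.values))
    labels = pd.Series(np.where(vals.values > cutoff, HIGH, LOW), index=vals.index)
    return StratificationResult(label_of=labels, cutoff=cutoff, marker_gene=marker)


def mad_filter(
    expr: ExpressionMatrix, threshold: float, scale: float = 1.0
) -> list[str]:
    """Genes whose median absolute deviation exceeds ``threshold``.

    Raw MAD (median |x - median(x)|) by default; a consistency constant
    (e.g. 1.4826) can be supplied via ``scale``.  Input gene order preserved.
    """
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    X = expr.values.values
    med = np.median(X, axis=1, keepdims=True)
    mad = scale * np.median(np.abs(X - med), axis=1)
    return [g for g, m in zip(expr.genes, mad) if m > threshold]


def cluster_concordance(
    expr: ExpressionMatrix,
    genes: list[str],
    strat: StratificationResult,
) -> ConcordanceReport:
    """Cluster samples into k=2 and measure agreement with the strata.

    Hierarchical agglomeration with average linkage on 1 - Pearson
    correlation over the supplied genes.  The two clusters are matched to
    the two strata by the assignment that maximizes the total number of
    concordant samples (each stratum gets a distinct cluster); the report
    carries the per-stratum concordant fraction under that matching.
    """
    if len(genes) < 2:
        raise ValidationError("need >=2 genes for clustering")
    if expr.n_samples < 4:
        raise ValidationError("need >=4 samples for clustering")
    if strat.n_high == 0 or strat.n_low == 0:
        raise ValidationError("both strata must be non-empty")
    sub = expr.values.loc[genes].values  # genes x samples
    corr = np.corrcoef(sub.T)
    if np.isnan(corr).any():
        raise DegenerateDataError("constant sample profile: correlation undefined")
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0  # enforce exact symmetry for squareform
    Z = linkage(squareform(dist, checks=False), method="average")
    clusters = fcluster(Z, t=2, criterion="maxclust")
    sizes = (int((clusters == 1).sum()), int((clusters == 2).sum()))
    labels = strat.label_of.loc[expr.samples].values
    for stratum in (HIGH, LOW):
        if (labels == stratum).sum() == 0:
            raise ValidationError(f"stratum {stratum} has no members in the matrix")
    counts = {
        (s, c): int(((labels == s) & (clusters == c)).sum())
        for s in (HIGH, LOW) for c in (1, 2)
    }
    if counts[(HIGH, 1)] + counts[(LOW, 2)] >= counts[(HIGH, 2)] + counts[(LOW, 1)]:
        match = {HIGH: 1, LOW: 2}
    else:
        match = {HIGH: 2, LOW: 1}
    frac = {
        s: counts[(s, match[s])] / int((labels == s).sum()) for s in (HIGH, LOW)
    }
    return ConcordanceReport(
        concordant_fraction=frac, cluster_sizes=sizes, n_genes_used=len(genes)
    )
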
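"""Permutation t-test differential expression and signature construction.

Per gene, the observed statistic is a Welch (unequal-variance) t between the
HIGH and LOW strata on log2 values; the log2 fold change is the difference of
group means (mean HIGH - mean LOW).  The null distribution is built by
relabeling samples with fixed group sizes.  With ``pooled_null=True`` the
null statistics of all genes are pooled, which resolves p-values far below
1/n_perm (the regime the very stringent signature threshold lives in) at a
modest permutation count; gene-wise nulls are available for strict exchange-
ability per gene.  p-values carry the +1 correction, so p >= 1/(n_null + 1).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ExpressionMatrix, GeneSet
from .simulate import HIGH
from .stratify import StratificationResult

logger = logging.getLogger(__name__)


@dataclass
class SignaturePair:
    """Directional signature: genes up in HIGH and genes up in LOW."""

    up_in_high: GeneSet | None  # None when no gene passes on that side
    up_in_low: GeneSet | None
    stats: pd.DataFrame  # index gene; columns t, fc, p_perm
    p_max: float
    fc_min: float

    @property
    def all_genes(self) -> frozenset[str]:
        up = self.up_in_high.genes if self.up_in_high else frozenset()
        down = self.up_in_low.genes if self.up_in_low else frozenset()
        return up | down


def _welch_t(X: np.ndarray, mask_high: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Welch t and mean difference (HIGH - LOW) per gene row."""
    A, B = X[:, mask_high], X[:, ~mask_high]
    nA, nB = A.shape[1], B.shape[1]
    mA, mB = A.mean(axis=1), B.mean(axis=1)
    vA, vB = A.var(axis=1, ddof=1), B.var(axis=1, ddof=1)
    fc = mA - mB
    denom = np.sqrt(vA / nA + vB / nB)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, fc / np.where(denom > 0, denom, 1.0), 0.0)
    return t, fc


def permutation_t_stats(
    expr: ExpressionMatrix,
    strat: StratificationResult,
    n_perm: int = 1000,
    pooled_null: bool = True,
    seed: int = 0,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Welch t, log2 FC and permutation p per gene.

    Returns a DataFrame indexed by gene with columns ``t``, ``fc``,
    ``p_perm``.  With ``exhaustive=True`` all distinct relabelings are
    enumerated instead of sampled (only feasible for small cohorts) and the
    null is gene-wise.
    """
    if not exhaustive and n_perm < 10:
        raise ValidationError("n_perm must be >= 10")
    labels = strat.label_of.loc[expr.samples].values
    mask_high = labels == HIGH
    n_high = int(mask_high.sum())
    n = mask_high.size
    if n_high < 2 or n - n_high < 2:
        raise ValidationError("both strata need >= 2 samples")
    X = expr.values.values
    t_obs, fc = _welch_t(X, mask_high)
    if np.any((X.var(axis=1) == 0)):
        logger.warning("constant genes present; their t is 0 and p is 1")
    abs_obs = np.abs(t_obs)
    n_genes = X.shape[0]

    if exhaustive:
        combos = list(combinations(range(n), n_high))
        counts = np.zeros(n_genes, dtype=np.int64)
        for idx in combos:
            m = np.zeros(n, dtype=bool)
            m[list(idx)] = True
            t_null, _ = _welch_t(X, m)
            counts += np.abs(t_null) >= abs_obs
        p = (1.0 + counts) / (1.0 + len(combos))
    else:
        rng = np.random.default_rng(seed)
        order = np.arange(n)
        if pooled_null:
            pooled = np.empty((n_perm, n_genes))
            for i in range(n_perm):
                perm = rng.permutation(order)
                m = np.zeros(n, dtype=bool)
                m[perm[:n_high]] = True
                pooled[i], _ = _welch_t(X, m)
            flat = np.sort(np.abs(pooled).ravel())
            n_null = flat.size
            # count of |t_null| >= |t_obs| via sorted search
            counts = n_null - np.searchsorted(flat, abs_obs, side="left")
            p = (1.0 + counts) / (1.0 + n_null)
        else:
            counts = np.zeros(n_genes, dtype=np.int64)
            for _ in range(n_perm):
                perm = rng.permutation(order)
                m = np.zeros(n, dtype=bool)
                m[perm[:n_high]] = True
                t_null, _ = _welch_t(X, m)
                counts += np.abs(t_null) >= abs_obs
            p = (1.0 + counts) / (1.0 + n_perm)

    return pd.DataFrame({"t": t_obs, "fc": fc, "p_perm": p}, index=expr.genes)


def build_signature(
    stats: pd.DataFrame,
    p_max: float,
    fc_min: float,
    name: str = "SIG",
) -> SignaturePair:
    """Threshold per-gene stats into a directional signature pair.

    up_in_high = {p < p_max and fc > fc_min};
    up_in_low  = {p < p_max and fc < -fc_min}.  Either side may be empty.
    """
    if stats.empty:
        raise ValidationError("stats table is empty")
    if not (0.0 < p_max <= 1.0):
        raise ValidationError("p_max must be in (0, 1]")
    if fc_min < 0:
        raise ValidationError("fc_min must be >= 0")
    sig = stats["p_perm"] < p_max
    up_high = frozenset(stats.index[sig & (stats["fc"] > fc_min)])
    up_low = frozenset(stats.index[sig & (stats["fc"] < -fc_min)])
    gs_high = GeneSet(f"{name}_UP_IN_HIGH", up_high, "up") if up_high else None
    gs_low = GeneSet(f"{name}_UP_IN_LOW", up_low, "down") if up_low else None
    return SignaturePair(
        up_in_high=gs_high, up_in_low=gs_low, stats=stats, p_max=p_max, fc_min=fc_min
    )
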
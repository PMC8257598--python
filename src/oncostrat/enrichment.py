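"""Running-sum (weighted Kolmogorov-Smirnov) enrichment scoring.

Three views of the same statistic:

* two-group GSEA: genes ranked by a group-contrast metric (signal-to-noise or
  Welch t), ES normalized against a phenotype-permutation null (NES, nominal
  p of matching sign);
* per-sample ES: genes ranked by their expression within one sample, with a
  rank-based hit weight, so each sample's score is independent of the rest of
  the cohort and invariant to within-sample monotone shifts;
* oncoactivity: per-sample ES over an oncogene set minus per-sample ES over a
  tumor-suppressor set — positive when oncogene-like genes crowd the top of
  the sample's expression ranking while suppressor-like genes sink.

The running sum increments at set members by |metric|^weight_exp (normalized
by the total hit weight) and decrements at non-members by 1/(N - n_hits);
the ES is the signed extremum of the running sum, so ES is in [-1, 1].
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError, ValidationError
from .diffexpr import _welch_t
from .io import ExpressionMatrix, GeneSet
from .simulate import HIGH
from .stratify import StratificationResult

logger = logging.getLogger(__name__)


@dataclass
class RankedList:
    genes: np.ndarray  # descending metric, ties broken by symbol
    metric: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.metric):
            raise ValidationError("genes and metric must have equal length")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("ranked genes must be unique")


@dataclass
class GseaResult:
    es: float
    nes: float
    p_nominal: float
    n_perm: int
    running_sum: np.ndarray


@dataclass
class OncoactivityResult:
    scores: pd.DataFrame  # index sample; columns es_onco, es_tsg, oncoactivity

    @property
    def oncoactivity(self) -> pd.Series:
        return self.scores["oncoactivity"]


def _rank_order(metric: np.ndarray, genes: np.ndarray) -> np.ndarray:
    """Indices sorting by descending metric, gene symbol as tiebreak."""
    return np.lexsort((genes, -metric))


def rank_by_group_metric(
    expr: ExpressionMatrix,
    strat: StratificationResult,
    metric: str = "snr",
) -> RankedList:
    """Rank genes by a HIGH-vs-LOW contrast (descending).

    ``snr`` is (mu_H - mu_L) / (s_H + s_L) with each SD floored at
    max(0.2 * |mu|, 0.2), the classic GSEA stabilization; ``tstat`` is the
    Welch t.
    """
    labels = strat.label_of.loc[expr.samples].values
    mask_high = labels == HIGH
    if mask_high.sum() < 2 or (~mask_high).sum() < 2:
        raise ValidationError("both strata need >= 2 samples")
    X = expr.values.values
    if metric == "snr":
        A, B = X[:, mask_high], X[:, ~mask_high]
        mA, mB = A.mean(axis=1), B.mean(axis=1)
        sA, sB = A.std(axis=1, ddof=1), B.std(axis=1, ddof=1)
        sA = np.maximum(sA, np.maximum(0.2 * np.abs(mA), 0.2))
        sB = np.maximum(sB, np.maximum(0.2 * np.abs(mB), 0.2))
        m = (mA - mB) / (sA + sB)
    elif metric == "tstat":
        m, _ = _welch_t(X, mask_high)
    else:
        raise ValidationError(f"unknown metric {metric!r}")
    genes = np.asarray(expr.genes)
    order = _rank_order(m, genes)
    return RankedList(genes=genes[order], metric=m[order])


def enrichment_score(
    ranked: RankedList, gs: GeneSet, weight_exp: float = 1.0
) -> tuple[float, np.ndarray]:
    """Signed extremum of the weighted running sum for one gene set."""
    hits = np.isin(ranked.genes, list(gs.genes))
    n_hits = int(hits.sum())
    N = len(ranked.genes)
    if n_hits == 0:
        raise DegenerateDataError(f"empty overlap between {gs.name!r} and ranking")
    if n_hits == N:
        raise DegenerateDataError(f"gene set {gs.name!r} equals the ranked universe")
    w = np.where(hits, np.abs(ranked.metric) ** weight_exp, 0.0)
    total = w.sum()
    if total == 0:
        raise DegenerateDataError("all hit weights are zero")
    steps = np.where(hits, w / total, -1.0 / (N - n_hits))
    running = np.cumsum(steps)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def gsea_two_group(
    expr: ExpressionMatrix,
    strat: StratificationResult,
    gs: GeneSet,
    n_perm: int = 1000,
    weight_exp: float = 1.0,
    metric: str = "snr",
    seed: int = 0,
) -> GseaResult:
    """Two-group GSEA with phenotype-permutation NES and nominal p.

    NES = ES / mean(|null ES| of the matching sign); nominal p is the
    +1-corrected one-sided tail among null ES of the matching sign.
    """
    if n_perm < 10:
        raise ValidationError("n_perm must be >= 10")
    if np.allclose(expr.values.values.var(axis=1), 0.0):
        raise DegenerateDataError("expression matrix is constant per gene")
    ranked = rank_by_group_metric(expr, strat, metric=metric)
    es, running = enrichment_score(ranked, gs, weight_exp)

    labels = strat.label_of.loc[expr.samples].values
    n_high = int((labels == HIGH).sum())
    n = len(labels)
    rng = np.random.default_rng(seed)
    null_es = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        mask = np.zeros(n, dtype=bool)
        mask[perm[:n_high]] = True
        fake = StratificationResult(
            label_of=pd.Series(np.where(mask, "HIGH", "LOW"), index=expr.samples),
            cutoff=float("nan"),
            marker_gene=strat.marker_gene,
        )
        r = rank_by_group_metric(expr, fake, metric=metric)
        null_es[i], _ = enrichment_score(r, gs, weight_exp)

    sign = 1.0 if es >= 0 else -1.0
    same = null_es * sign > 0
    if not same.any() or np.all(null_es[same] == 0):
        raise DegenerateDataError("no null ES of matching sign; NES undefined")
    nes = es / float(np.mean(np.abs(null_es[same])))
    more_extreme = int((np.abs(null_es[same]) >= abs(es)).sum())
    p = (1.0 + more_extreme) / (1.0 + int(same.sum()))
    return GseaResult(es=es, nes=nes, p_nominal=p, n_perm=n_perm, running_sum=running)


def sample_enrichment(
    expr: ExpressionMatrix, gs: GeneSet, weight_exp: float = 0.25
) -> pd.Series:
    """Per-sample ES: rank genes within each sample, score the set.

    The hit metric is the rank weight (N - rank + 1), so the score depends
    only on the within-sample ordering — adding a constant to a sample or
    applying any monotone transform leaves it unchanged.
    """
    genes = np.asarray(expr.genes)
    member = np.isin(genes, list(gs.genes))
    n_hits = int(member.sum())
    N = len(genes)
    if n_hits == 0:
        raise DegenerateDataError(f"empty overlap between {gs.name!r} and matrix")
    if n_hits == N:
        raise DegenerateDataError(f"gene set {gs.name!r} equals the gene universe")
    X = expr.values.values
    out = np.empty(expr.n_samples)
    rank_weight = np.arange(N, 0, -1, dtype=float)  # N at top rank, 1 at bottom
    miss_step = -1.0 / (N - n_hits)
    for j in range(expr.n_samples):
        order = _rank_order(X[:, j], genes)
        hits = member[order]
        w = np.where(hits, rank_weight**weight_exp, 0.0)
        steps = np.where(hits, w / w.sum(), miss_step)
        running = np.cumsum(steps)
        out[j] = running[np.argmax(np.abs(running))]
    return pd.Series(out, index=expr.samples, name=gs.name)


def oncoactivity_scores(
    expr: ExpressionMatrix,
    onco: GeneSet,
    tsg: GeneSet,
    weight_exp: float = 0.25,
) -> OncoactivityResult:
    """Per-sample oncoactivity = ES(oncogene set) - ES(TSG set)."""
    es_onco = sample_enrichment(expr, onco, weight_exp)
    es_tsg = sample_enrichment(expr, tsg, weight_exp)
    df = pd.DataFrame(
        {"es_onco": es_onco, "es_tsg": es_tsg, "oncoactivity": es_onco - es_tsg}
    )
    return OncoactivityResult(scores=df)


def compare_group_scores(
    scores: pd.Series, strat: StratificationResult
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of per-sample scores.

    Exact enumeration when both groups have <= 10 samples and no ties;
    normal approximation otherwise.  Returns (statistic, p).
    """
    labels = strat.label_of.loc[scores.index].values
    x = scores.values[labels == HIGH]
    y = scores.values[labels != HIGH]
    if x.size == 0 or y.size == 0:
        raise ValidationError("both strata must be non-empty")
    if np.all(scores.values == scores.values[0]):
        logger.warning("all scores tied; p set to 1")
        return 0.0, 1.0
    pooled = np.concatenate([x, y])
    small = x.size <= 10 and y.size <= 10
    no_ties = len(np.unique(pooled)) == pooled.size
    if small and no_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)
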
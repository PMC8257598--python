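"""Nearest-template prediction (NTP) for two-class signature calls.

Each sample is represented by its cross-sample z-scored expression over the
signature genes and compared, by cosine distance, with two mirror-image
templates: +1 on the genes up in class A, -1 on the genes up in class B, and
the elementwise negation for class B.  Significance of the nearest match is
assessed against random templates with the same +/- composition, and calls
are thresholded on a Benjamini-Hochberg FDR across samples; samples whose
best match is not significant are reported as N.D. (not determined).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDataError, ValidationError
from .diffexpr import SignaturePair
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

ND = "ND"


@dataclass
class TemplateMatrix:
    genes: list[str]
    template_a: np.ndarray  # +1 on up-in-A genes, -1 on up-in-B genes

    @property
    def template_b(self) -> np.ndarray:
        return -self.template_a


@dataclass
class NTPCalls:
    calls: pd.DataFrame  # index sample; columns label, distance, p, fdr
    fdr_threshold: float

    @property
    def labels(self) -> pd.Series:
        return self.calls["label"]

    def counts(self) -> dict[str, int]:
        return self.calls["label"].value_counts().to_dict()


def build_templates(
    sig: SignaturePair, expr: ExpressionMatrix, min_overlap: float = 0.5
) -> TemplateMatrix:
    """Signed +/-1 templates over the signature genes present in ``expr``."""
    up = sig.up_in_high.genes if sig.up_in_high else frozenset()
    down = sig.up_in_low.genes if sig.up_in_low else frozenset()
    if not up and not down:
        raise ValidationError("signature is empty; cannot build templates")
    universe = set(expr.genes)
    present_up = sorted(up & universe)
    present_down = sorted(down & universe)
    total = len(up) + len(down)
    frac = (len(present_up) + len(present_down)) / total
    if frac < min_overlap:
        raise ValidationError(
            f"only {frac:.1%} of signature genes present (min {min_overlap:.0%})"
        )
    genes = present_up + present_down
    template = np.concatenate(
        [np.ones(len(present_up)), -np.ones(len(present_down))]
    )
    return TemplateMatrix(genes=genes, template_a=template)


def ntp_classify(
    expr: ExpressionMatrix,
    tmpl: TemplateMatrix,
    n_null: int = 1000,
    fdr_threshold: float = 0.05,
    seed: int = 0,
) -> NTPCalls:
    """Classify every sample as A, B or N.D. by nearest signed template.

    Expression over the template genes is z-scored across samples; distance
    is 1 - cosine similarity (in [0, 2]).  The per-sample p is the
    +1-corrected fraction of ``n_null`` random sign-permuted templates at
    least as close as the nearest real template; FDR is Benjamini-Hochberg
    across samples.
    """
    if n_null < 100:
        raise ValidationError("n_null must be >= 100")
    if not 0 < fdr_threshold < 1:
        raise ValidationError("fdr_threshold must be in (0, 1)")
    sub = expr.values.loc[[g for g in tmpl.genes if g in set(expr.genes)]]
    missing = len(tmpl.genes) - sub.shape[0]
    if missing:
        logger.warning("%d template genes absent from matrix", missing)
    keep = [g for g in sub.index]
    template = tmpl.template_a[[tmpl.genes.index(g) for g in keep]]
    X = sub.values
    sd = X.std(axis=1, ddof=0)
    nonzero = sd > 0
    if not nonzero.all():
        logger.warning("dropping %d zero-variance template genes", int((~nonzero).sum()))
        X, template = X[nonzero], template[nonzero]
    if X.shape[0] == 0:
        raise DegenerateDataError("no usable template genes (all zero variance)")
    Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=0, keepdims=True)

    G = Z.shape[0]
    norm_z = np.linalg.norm(Z, axis=0)
    if np.any(norm_z == 0):
        raise DegenerateDataError("a sample has zero norm after z-scoring")
    cos_a = (template @ Z) / (np.sqrt(G) * norm_z)
    dist_a = 1.0 - cos_a
    dist_b = 1.0 + cos_a
    nearest_a = dist_a <= dist_b
    dist = np.where(nearest_a, dist_a, dist_b)

    rng = np.random.default_rng(seed)
    # null templates: permutations of the signed template (same composition)
    null_T = np.empty((n_null, G))
    for i in range(n_null):
        null_T[i] = template[rng.permutation(G)]
    null_cos = (null_T @ Z) / (np.sqrt(G) * norm_z)  # n_null x n_samples
    null_dist = np.where(nearest_a[None, :], 1.0 - null_cos, 1.0 + null_cos)
    counts = (null_dist <= dist[None, :]).sum(axis=0)
    p = (1.0 + counts) / (1.0 + n_null)
    fdr = multipletests(p, method="fdr_bh")[1]
    labels = np.where(fdr < fdr_threshold, np.where(nearest_a, "A", "B"), ND)
    calls = pd.DataFrame(
        {"label": labels, "distance": dist, "p": p, "fdr": fdr},
        index=expr.samples,
    )
    return NTPCalls(calls=calls, fdr_threshold=fdr_threshold)
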
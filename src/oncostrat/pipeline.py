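"""End-to-end orchestration: stratify -> signatures -> enrichment -> NTP ->
survival, from a single YAML-able configuration, with deterministic seeding
and a run manifest.

In simulation mode the synthetic cohort module provides the inputs; in file
mode the expression/clinical/gene-set paths are read.  Every stochastic stage
derives its own seed from ``config.seed`` via named substreams, so outputs
are byte-identical across reruns of the same config.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ValidationError
from .diffexpr import SignaturePair, build_signature, permutation_t_stats
from .enrichment import (
    GseaResult,
    OncoactivityResult,
    compare_group_scores,
    gsea_two_group,
    oncoactivity_scores,
)
from .io import (
    read_clinical,
    read_expression_matrix,
    read_gmt,
    write_clinical,
    write_expression_matrix,
    write_gmt,
)
from .ntp import NTPCalls, build_templates, ntp_classify
from .simulate import HIGH, LOW, SimulationConfig, simulate_cohort, simulate_gene_sets
from .stratify import (
    ConcordanceReport,
    StratificationResult,
    cluster_concordance,
    mad_filter,
    median_split,
)
from .survival import (
    ContingencyTable2x2,
    cox_fit,
    fisher_exact,
    km_curve,
    logrank_test,
    prepare_survival,
    t_test,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of a full run (exactly one input mode)."""

    # file mode
    expression_path: str | None = None
    clinical_path: str | None = None
    gene_sets_path: str | None = None  # GMT with ONCOGENES and TSGS sets
    # simulation mode
    simulation: SimulationConfig | None = None

    marker_gene: str = "ESR1"
    mad_threshold: float = 0.5
    p_max: float = 1e-3
    fc_min: float = 0.5
    n_perm: int = 1000
    pooled_null: bool = True
    weight_exp_gsea: float = 1.0
    weight_exp_sample: float = 0.25
    n_null_ntp: int = 1000
    fdr_threshold: float = 0.05
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        file_mode = self.expression_path is not None
        sim_mode = self.simulation is not None
        if file_mode == sim_mode:
            raise ValidationError(
                "exactly one of expression_path / simulation must be given"
            )
        if not (0 < self.p_max <= 1) or self.fc_min < 0:
            raise ValidationError("invalid signature thresholds")
        if not (0 < self.fdr_threshold < 1):
            raise ValidationError("fdr_threshold must be in (0, 1)")
        if self.mad_threshold < 0:
            raise ValidationError("mad_threshold must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(simulation=SimulationConfig(**sim) if sim else None, **raw)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("out_dir")  # where results land is not part of the analysis
        return d


@dataclass
class ResultBundle:
    stratification: StratificationResult
    concordance: ConcordanceReport | None
    signature: SignaturePair
    oncoactivity: OncoactivityResult | None
    oncoactivity_test: tuple[float, float] | None
    gsea: dict[str, GseaResult]
    ntp: NTPCalls | None
    survival_tables: dict[str, pd.DataFrame]
    association_tables: dict[str, dict]
    manifest: dict = field(default_factory=dict)


def _stage_seeds(seed: int) -> dict[str, int]:
    names = ("diffexpr", "gsea", "ntp")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(ss.generate_state(1)[0] % (2**31)) for n, ss in zip(names, children)}


def run_pipeline(config: PipelineConfig) -> ResultBundle:
    """Execute the full analysis; write artifacts if ``out_dir`` is set."""
    seeds = _stage_seeds(config.seed)
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    # ---- inputs -----------------------------------------------------------
    if config.simulation is not None:
        logger.info("stage simulate: %s", config.simulation)
        expr, clinical, truth = simulate_cohort(config.simulation)
        onco, tsg = simulate_gene_sets(truth, config.simulation)
        marker = config.simulation.marker_gene
        if out:
            write_expression_matrix(expr, out / "expression.tsv")
            write_clinical(clinical, out / "clinical.csv")
            write_gmt([onco, tsg], out / "gene_sets.gmt")
    else:
        expr = read_expression_matrix(config.expression_path)
        clinical = (read_clinical(config.clinical_path)
                    if config.clinical_path else None)
        onco = tsg = None
        if config.gene_sets_path:
            sets = {g.name.upper(): g for g in read_gmt(config.gene_sets_path)}
            onco = sets.get("ONCOGENES")
            tsg = sets.get("TSGS")
        marker = config.marker_gene

    # ---- stratify ---------------------------------------------------------
    strat = median_split(expr, marker)
    logger.info("stage stratify: cutoff=%.4g HIGH=%d LOW=%d",
                strat.cutoff, strat.n_high, strat.n_low)
    variable_genes = mad_filter(expr, config.mad_threshold)
    concordance = None
    if len(variable_genes) >= 2 and expr.n_samples >= 4:
        concordance = cluster_concordance(expr, variable_genes, strat)
        logger.info("stage concordance: %s", concordance.concordant_fraction)

    # ---- differential expression -----------------------------------------
    stats = permutation_t_stats(
        expr, strat, n_perm=config.n_perm, pooled_null=config.pooled_null,
        seed=seeds["diffexpr"],
    )
    signature = build_signature(stats, config.p_max, config.fc_min)
    n_up = len(signature.up_in_high) if signature.up_in_high else 0
    n_down = len(signature.up_in_low) if signature.up_in_low else 0
    logger.info("stage diffexpr: up_in_high=%d up_in_low=%d", n_up, n_down)

    # ---- enrichment -------------------------------------------------------
    onco_res = onco_test = None
    gsea_results: dict[str, GseaResult] = {}
    if onco is not None and tsg is not None:
        onco_res = oncoactivity_scores(expr, onco, tsg, config.weight_exp_sample)
        onco_test = compare_group_scores(onco_res.oncoactivity, strat)
        logger.info("stage oncoactivity: rank-sum p=%.3g", onco_test[1])
        gsea_results["ONCOGENES"] = gsea_two_group(
            expr, strat, onco, n_perm=max(100, config.n_perm // 10),
            weight_exp=config.weight_exp_gsea, seed=seeds["gsea"],
        )

    # ---- nearest template prediction --------------------------------------
    ntp_calls = None
    if signature.up_in_high and signature.up_in_low:
        templates = build_templates(signature, expr)
        ntp_calls = ntp_classify(
            expr, templates, n_null=config.n_null_ntp,
            fdr_threshold=config.fdr_threshold, seed=seeds["ntp"],
        )
        logger.info("stage ntp: %s", ntp_calls.counts())

    # ---- survival & associations ------------------------------------------
    survival_tables: dict[str, pd.DataFrame] = {}
    association_tables: dict[str, dict] = {}
    if clinical is not None and {"time", "event"} <= set(clinical.data.columns):
        records = clinical.data.copy()
        records["stratum_low"] = (
            strat.label_of.reindex(records.index) == LOW
        ).astype(int)
        records = prepare_survival(records)
        chi2, p = logrank_test(records, "stratum_low")
        survival_tables["logrank"] = pd.DataFrame(
            {"chi2": [chi2], "p": [p]}, index=["stratum"]
        )
        for label, flag in ((HIGH, 0), (LOW, 1)):
            curve = km_curve(records[records["stratum_low"] == flag])
            survival_tables[f"km_{label}"] = pd.DataFrame(
                {"time": curve.times, "survival": curve.survival,
                 "at_risk": curve.at_risk}
            )
        covars = ["stratum_low"] + [
            c for c in ("age", "mvi", "afp_high")
            if c in records.columns and records[c].nunique() > 1
        ]
        univariate = []
        for c in covars:
            m = cox_fit(records, [c])
            univariate.append(m.summary.loc[c])
        survival_tables["cox_univariate"] = pd.DataFrame(univariate)
        survival_tables["cox_multivariate"] = cox_fit(records, covars).summary

        labels = strat.label_of.reindex(clinical.data.index)
        for c, kind in clinical.schema.items():
            if c in ("time", "event") or c not in clinical.data.columns:
                continue
            col = clinical.data[c]
            if kind == "binary":
                tab = ContingencyTable2x2(
                    a=int(((labels == HIGH) & (col == 1)).sum()),
                    b=int(((labels == HIGH) & (col == 0)).sum()),
                    c=int(((labels == LOW) & (col == 1)).sum()),
                    d=int(((labels == LOW) & (col == 0)).sum()),
                )
                orr, p = fisher_exact(tab)
                association_tables[c] = {
                    "test": "fisher", "odds_ratio": orr, "p": p,
                    "rate_high": tab.row1_rate, "rate_low": tab.row2_rate,
                }
            elif kind == "continuous":
                x = col[labels == HIGH].dropna()
                y = col[labels == LOW].dropna()
                t, p = t_test(x, y)
                association_tables[c] = {
                    "test": "t", "t": t, "p": p,
                    "mean_high": float(x.mean()), "mean_low": float(y.mean()),
                }

    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "stage_seeds": seeds,
        "version": __version__,
    }
    bundle = ResultBundle(
        stratification=strat,
        concordance=concordance,
        signature=signature,
        oncoactivity=onco_res,
        oncoactivity_test=onco_test,
        gsea=gsea_results,
        ntp=ntp_calls,
        survival_tables=survival_tables,
        association_tables=association_tables,
        manifest=manifest,
    )
    if out:
        _write_bundle(bundle, out)
    return bundle


def _write_bundle(bundle: ResultBundle, out: Path) -> None:
    strat = bundle.stratification
    strat.label_of.rename("label").to_csv(out / "labels.tsv", sep="\t",
                                          index_label="sample_id")
    bundle.signature.stats.to_csv(out / "gene_stats.tsv", sep="\t",
                                  index_label="gene", float_format="%.10g")
    sig_sets = [s for s in (bundle.signature.up_in_high,
                            bundle.signature.up_in_low) if s]
    if sig_sets:
        write_gmt(sig_sets, out / "signature.gmt")
    if bundle.oncoactivity is not None:
        bundle.oncoactivity.scores.to_csv(out / "oncoactivity.tsv", sep="\t",
                                          index_label="sample_id",
                                          float_format="%.10g")
    if bundle.gsea:
        payload = {
            name: {"es": r.es, "nes": r.nes, "p_nominal": r.p_nominal,
                   "n_perm": r.n_perm}
            for name, r in bundle.gsea.items()
        }
        (out / "gsea.json").write_text(json.dumps(payload, indent=2,
                                                  sort_keys=True))
    if bundle.ntp is not None:
        bundle.ntp.calls.to_csv(out / "ntp.tsv", sep="\t",
                                index_label="sample_id", float_format="%.10g")
    for name, df in bundle.survival_tables.items():
        df.to_csv(out / f"{name}.tsv", sep="\t", float_format="%.10g")
    if bundle.association_tables:
        (out / "associations.json").write_text(
            json.dumps(bundle.association_tables, indent=2, sort_keys=True)
        )
    summary = {
        "n_high": strat.n_high,
        "n_low": strat.n_low,
        "cutoff": strat.cutoff,
        "marker_gene": strat.marker_gene,
        "n_signature_up_in_high": (len(bundle.signature.up_in_high)
                                   if bundle.signature.up_in_high else 0),
        "n_signature_up_in_low": (len(bundle.signature.up_in_low)
                                  if bundle.signature.up_in_low else 0),
    }
    if bundle.concordance is not None:
        summary["cluster_concordance"] = bundle.concordance.concordant_fraction
        summary["n_variable_genes"] = bundle.concordance.n_genes_used
    if bundle.oncoactivity_test is not None:
        stat, p = bundle.oncoactivity_test
        summary["oncoactivity_ranksum"] = {"statistic": stat, "p": p}
    if bundle.ntp is not None:
        summary["ntp_counts"] = bundle.ntp.counts()
    (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                 sort_keys=True))
    (out / "manifest.json").write_text(
        json.dumps(bundle.manifest, indent=2, sort_keys=True)
    )
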
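"""Synthetic tumor-cohort generator.

Emulates the statistical structure the stratification analysis assumes: two
latent expression subtypes separated by a single marker gene, a configurable
fraction of differentially expressed genes, oncogene-like sets enriched among
genes up in the aggressive (marker-LOW) subtype and tumor-suppressor-like
sets among genes up in the indolent (marker-HIGH) subtype, optional additive
per-dataset batch shifts, and exponential survival with a subtype-dependent
hazard under administrative censoring.

Every random quantity is drawn from a named child stream of one global seed,
so changing e.g. the survival parameters never perturbs the expression draw.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ClinicalTable, ExpressionMatrix, GeneSet

HIGH, LOW = "HIGH", "LOW"

# sample-level streams (per cohort) and structure streams (shared biology)
_COHORT_STREAMS = ("assignment", "expression", "survival", "clinical")
_STRUCTURE_STREAMS = ("genes", "sets")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort.

    Expression is on the log2 scale throughout: gene baselines are uniform on
    [2, 12], ``delta`` is the log2 mean shift of differentially expressed
    genes between subtypes, ``sigma`` the within-group SD.  Survival times
    are in months; the marker-LOW subtype has hazard ``baseline_hazard * hr``.
    """

    n_samples: int = 200
    n_genes: int = 2000
    frac_deg: float = 0.08
    delta: float = 1.0
    sigma: float = 0.5
    marker_gene: str = "ESR1"
    marker_delta: float = 1.5
    # gene-set sizes default to the genome-wide proportions of curated
    # oncogene (~3.5%) and tumor-suppressor (~5.5%) lists
    n_onco: int | None = None
    n_tsg: int | None = None
    onco_frac_up_in_low: float = 0.5
    batch_shifts: dict[str, float] | None = None
    hr: float = 2.0
    baseline_hazard: float = 0.02
    censor_time: float = 120.0
    seed: int = 0
    # seed of the shared gene "biology" (baselines, DEG identities, gene-set
    # membership); defaults to `seed`.  Give two cohorts the same
    # structure_seed but different seeds to emulate an external validation
    # cohort drawn from the same disease biology.
    structure_seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("frac_deg", "onco_frac_up_in_low"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.n_samples < 4:
            raise ValidationError("n_samples must be >= 4")
        if self.hr <= 0:
            raise ValidationError("hr must be positive")
        if self.sigma <= 0:
            raise ValidationError("sigma must be positive")
        if self.baseline_hazard <= 0 or self.censor_time <= 0:
            raise ValidationError("baseline_hazard and censor_time must be positive")
        if self.n_onco is None:
            self.n_onco = max(2, round(0.035 * self.n_genes))
        if self.n_tsg is None:
            self.n_tsg = max(2, round(0.055 * self.n_genes))


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort, for parameter-recovery tests."""

    subtype_of: pd.Series  # sample id -> HIGH | LOW
    deg_up_in_low: frozenset[str]
    deg_up_in_high: frozenset[str]
    marker_gene: str
    true_hr: float
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.deg_up_in_low & self.deg_up_in_high:
            raise ValidationError("DEG sets must be disjoint")


def _streams(config: SimulationConfig) -> dict[str, np.random.Generator]:
    rngs = {}
    cohort_children = np.random.SeedSequence(config.seed).spawn(
        len(_COHORT_STREAMS))
    rngs.update({n: np.random.default_rng(s)
                 for n, s in zip(_COHORT_STREAMS, cohort_children)})
    structure_seed = (config.seed if config.structure_seed is None
                      else config.structure_seed)
    structure_children = np.random.SeedSequence((structure_seed, 1)).spawn(
        len(_STRUCTURE_STREAMS))
    rngs.update({n: np.random.default_rng(s)
                 for n, s in zip(_STRUCTURE_STREAMS, structure_children)})
    return rngs


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ClinicalTable, CohortTruth]:
    """Draw a cohort: expression matrix, clinical table and ground truth.

    Identical configs (including seed) produce bitwise-identical output.
    """
    n_deg = int(round(config.frac_deg * config.n_genes))
    if n_deg < 2:
        raise ValidationError(
            f"frac_deg * n_genes = {n_deg} < 2: cannot form both signatures"
        )
    rng = _streams(config)

    marker = config.marker_gene.upper()
    width = max(5, len(str(config.n_genes)))
    gene_ids = [f"G{i:0{width}d}" for i in range(1, config.n_genes)]
    genes = [marker] + gene_ids
    sample_ids = [f"S{i:04d}" for i in range(1, config.n_samples + 1)]

    # balanced subtype assignment, randomly shuffled
    n_high = config.n_samples // 2
    labels = np.array([HIGH] * n_high + [LOW] * (config.n_samples - n_high))
    rng["assignment"].shuffle(labels)
    is_low = labels == LOW

    # gene structure (baselines, DEG identities) from the structure stream
    # so cohorts sharing structure_seed share their biology
    mu = rng["genes"].uniform(2.0, 12.0, size=config.n_genes)
    deg_idx = rng["genes"].choice(
        np.arange(1, config.n_genes), size=n_deg, replace=False
    )
    half = n_deg // 2
    up_low_idx = deg_idx[:half]
    up_high_idx = deg_idx[half:]

    X = rng["expression"].normal(0.0, config.sigma,
                                 size=(config.n_genes, config.n_samples))
    X += mu[:, None]
    X[np.ix_(up_low_idx, np.where(is_low)[0])] += config.delta
    X[np.ix_(up_high_idx, np.where(~is_low)[0])] += config.delta
    X[0, ~is_low] += config.marker_delta  # marker high in the HIGH subtype

    dataset_of = None
    if config.batch_shifts:
        tags = list(config.batch_shifts)
        assign = np.array([tags[i % len(tags)] for i in range(config.n_samples)])
        for tag in tags:
            X[:, assign == tag] += config.batch_shifts[tag]
        dataset_of = dict(zip(sample_ids, assign))

    expr = ExpressionMatrix(
        pd.DataFrame(X, index=genes, columns=sample_ids), dataset_of=dataset_of
    )

    # survival: exponential with subtype hazard, administrative censoring
    rate = np.where(is_low, config.baseline_hazard * config.hr,
                    config.baseline_hazard)
    t_event = rng["survival"].exponential(1.0 / rate)
    event = (t_event <= config.censor_time).astype(int)
    time = np.minimum(t_event, config.censor_time)

    # clinical covariates echoing the usual tumor-registry variables: the
    # indolent (HIGH) stratum is older with less vascular invasion and lower
    # serum-marker positivity
    age = rng["clinical"].normal(55.0, 10.0, size=config.n_samples) + 4.0 * (~is_low)
    mvi = (rng["clinical"].uniform(size=config.n_samples)
           < np.where(is_low, 0.6, 0.4)).astype(int)
    afp_high = (rng["clinical"].uniform(size=config.n_samples)
                < np.where(is_low, 0.5, 0.2)).astype(int)
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "time": time,
                "event": event,
                "age": age,
                "mvi": mvi,
                "afp_high": afp_high,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        ),
        schema={
            "time": "continuous",
            "event": "binary",
            "age": "continuous",
            "mvi": "binary",
            "afp_high": "binary",
        },
    )

    gene_arr = np.array(genes)
    truth = CohortTruth(
        subtype_of=pd.Series(labels, index=sample_ids),
        deg_up_in_low=frozenset(gene_arr[up_low_idx]),
        deg_up_in_high=frozenset(gene_arr[up_high_idx]),
        marker_gene=marker,
        true_hr=config.hr,
        genes=genes,
    )
    return expr, clinical, truth


def simulate_gene_sets(
    truth: CohortTruth, config: SimulationConfig
) -> tuple[GeneSet, GeneSet]:
    """Draw oncogene-like and tumor-suppressor-like sets from the truth.

    A fraction ``onco_frac_up_in_low`` of the oncogene set comes from genes
    truly up in the LOW subtype (the aggressive one), the rest from null
    genes; the TSG set is built symmetrically from genes up in HIGH.
    """
    rng = _streams(config)["sets"]
    deg_low = sorted(truth.deg_up_in_low)
    deg_high = sorted(truth.deg_up_in_high)
    degs = set(deg_low) | set(deg_high)
    null_genes = sorted(g for g in truth.genes
                        if g not in degs and g != truth.marker_gene)

    def draw(n_total: int, frac: float, informative: list[str], label: str) -> GeneSet:
        k = int(round(frac * n_total))
        if k > len(informative):
            raise ValidationError(
                f"{label}: requested {k} informative members, only "
                f"{len(informative)} DEGs available"
            )
        if n_total - k > len(null_genes):
            raise ValidationError(f"{label}: not enough null genes")
        chosen = list(rng.choice(informative, size=k, replace=False)) if k else []
        chosen += list(rng.choice(null_genes, size=n_total - k, replace=False))
        return GeneSet(label, frozenset(chosen))

    onco = draw(config.n_onco, config.onco_frac_up_in_low, deg_low, "ONCOGENES")
    tsg = draw(config.n_tsg, config.onco_frac_up_in_low, deg_high, "TSGS")
    return onco, tsg
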
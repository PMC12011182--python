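"""Synthetic cohorts with the statistical structure the analysis assumes.

Three generators share a :class:`SimulationConfig`: a pathway collection with
a star-topology genecentric neighborhood of known activator/repressor
composition (plus decoy pathways on disjoint genes); a negative-binomial
expression cohort in which an "activated" sample stratum has activator-gene
means multiplied (and repressor-gene means divided) by ``2**pal_effect_logfc``;
and clinical follow-up in which the activated stratum carries an
``exp(survival_beta)``-fold hazard and response odds shifted by
``response_logit_slope`` on a proportional-odds scale.  The effect is injected
at the gene-mean level, never at the score level, so the full chain
(normalization → reference → CNR → PAL → statistics) is exercised.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pathway_graph import Edge, GenecentricPathway, InteractionType, PathwayCollection
from .survival_stats import SurvivalData

__all__ = [
    "SimulationConfig",
    "simulate_pathway_collection",
    "simulate_expression_cohort",
    "simulate_clinical",
]

_ACTIVATING = [InteractionType.ACTIVATION, InteractionType.PHOSPHORYLATION]
_INHIBITING = [
    InteractionType.INHIBITION,
    InteractionType.REPRESSION,
    InteractionType.DEPHOSPHORYLATION,
    InteractionType.UBIQUITINATION,
]
_NEUTRAL = [
    InteractionType.COUPLING,
    InteractionType.BINDING_ASSOCIATION,
    InteractionType.DISSOCIATION,
]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohorts.

    Defaults describe a mid-sized tumor expression cohort: 200 samples over
    500 genes with negative-binomial counts (dispersion 0.1, baseline mean
    500 with log-normal gene-level variation), a 40-member genecentric
    pathway that is 70% activators, a one-log2-unit expression shift in the
    activated half of the cohort, a 2-fold hazard for activated samples,
    30% censoring, and a 2-unit response logit shift.
    """

    seed: int = 0
    n_genes: int = 500
    n_pathway_members: int = 40
    frac_activators: float = 0.7
    n_decoy_pathways: int = 3
    n_samples: int = 200
    nb_dispersion: float = 0.1
    baseline_mean: float = 500.0
    pal_effect_logfc: float = 1.0
    frac_activated_samples: float = 0.5
    survival_beta: float = float(np.log(2.0))
    baseline_hazard: float = 1.0 / 365.0
    censor_rate: float = 0.3
    response_logit_slope: float = 2.0
    central_gene: str = "CENTRAL"

    def __post_init__(self) -> None:
        for name in ("frac_activators", "frac_activated_samples", "censor_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")


def _member_names(config: SimulationConfig) -> list[str]:
    return [f"G{i:04d}" for i in range(config.n_pathway_members)]


def simulate_pathway_collection(
    config: SimulationConfig,
) -> tuple[PathwayCollection, dict[str, float]]:
    """Star-topology genecentric neighborhood plus decoy pathways.

    The first ``frac_activators`` share of members are wired to the central
    gene with activating edge types, the rest with inhibiting types; edge
    direction is random.  Decoy pathways are stars over disjoint background
    genes with uniformly random interaction types.  Returns the collection
    and the ground-truth ARR map (central +1, activators +1, repressors -1).
    """
    rng = np.random.default_rng(config.seed)
    members = _member_names(config)
    n_act = int(round(config.frac_activators * len(members)))
    truth: dict[str, float] = {config.central_gene: 1.0}
    edges: list[Edge] = []
    for i, m in enumerate(members):
        if i < n_act:
            itype = _ACTIVATING[rng.integers(len(_ACTIVATING))]
            truth[m] = 1.0
        else:
            itype = _INHIBITING[rng.integers(len(_INHIBITING))]
            truth[m] = -1.0
        if rng.random() < 0.5:
            edges.append(Edge(config.central_gene, m, itype))
        else:
            edges.append(Edge(m, config.central_gene, itype))
    pathways = {"TRUE_PATHWAY": edges}

    all_types = list(InteractionType)
    used = config.n_pathway_members
    for d in range(config.n_decoy_pathways):
        hub = f"DECOY_HUB_{d}"
        decoy_edges = []
        for _ in range(config.n_pathway_members):
            if used >= config.n_genes - config.n_decoy_pathways:
                break
            g = f"G{used:04d}"
            used += 1
            itype = all_types[rng.integers(len(all_types))]
            if rng.random() < 0.5:
                decoy_edges.append(Edge(hub, g, itype))
            else:
                decoy_edges.append(Edge(g, hub, itype))
        if decoy_edges:
            pathways[f"DECOY_{d}"] = decoy_edges
    return PathwayCollection(pathways), truth


def simulate_expression_cohort(
    config: SimulationConfig, arr_truth: dict[str, float]
) -> tuple["pd.DataFrame", pd.Series]:
    """Negative-binomial counts with a pathway-activation stratum.

    Gene means are ``baseline_mean`` scaled by a log-normal gene-level factor
    (sd 1 on the natural-log scale).  In the activated stratum, genes with
    ARR > 0 have their mean multiplied by ``2**pal_effect_logfc`` and genes
    with ARR < 0 divided by it.  Counts are NB with variance
    ``mu + dispersion * mu**2``.  Returns the genes × samples count matrix
    (wrapped downstream into an :class:`~palscreen.pal_engine.ExpressionCohort`)
    and the boolean activated-stratum labels.
    """
    rng = np.random.default_rng(config.seed + 1)
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    hubs = sorted(h for h in arr_truth if not h.startswith("G"))
    hubs += [f"DECOY_HUB_{d}" for d in range(config.n_decoy_pathways)]
    genes = hubs + genes
    samples = [f"S{j:03d}" for j in range(config.n_samples)]
    n_activated = int(round(config.frac_activated_samples * config.n_samples))
    activated = pd.Series(
        [j < n_activated for j in range(config.n_samples)], index=samples, name="activated"
    )

    gene_factor = rng.lognormal(mean=0.0, sigma=1.0, size=len(genes))
    mu = np.tile((config.baseline_mean * gene_factor)[:, None], (1, config.n_samples))
    fold = 2.0**config.pal_effect_logfc
    for i, g in enumerate(genes):
        w = arr_truth.get(g, 0.0)
        if w > 0:
            mu[i, :n_activated] *= fold
        elif w < 0:
            mu[i, :n_activated] /= fold

    # NB(mean mu, var mu + a*mu^2): shape r = 1/a, p = r/(r+mu)
    r = 1.0 / config.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    matrix = pd.DataFrame(counts, index=genes, columns=samples)
    return matrix, activated


def simulate_clinical(
    config: SimulationConfig, activated: pd.Series
) -> tuple[dict[str, SurvivalData], pd.DataFrame]:
    """Survival and RECIST response records linked to the activated stratum.

    Event times are exponential with hazard
    ``baseline_hazard * exp(survival_beta * activated)``; censoring times are
    independent exponential with rate chosen so that a fraction
    ``censor_rate`` of baseline-hazard patients is censored.  OS and PFS are
    drawn independently with the same law (PFS with a 1.5-fold hazard, as
    progression precedes death).  RECIST classes come from a
    proportional-odds model whose linear predictor is
    ``response_logit_slope * activated`` — higher activation pushes toward
    Progressive Disease.  All patients get the same therapy label, lines
    drawn from 1-3 with a few later-line extra records to exercise the
    cohort filter.
    """
    rng = np.random.default_rng(config.seed + 2)
    samples = activated.index
    act = activated.values.astype(float)
    clinical: dict[str, SurvivalData] = {}
    for endpoint, hazard_scale in (("OS", 1.0), ("PFS", 1.5)):
        lam = config.baseline_hazard * hazard_scale * np.exp(config.survival_beta * act)
        event_time = rng.exponential(1.0 / lam)
        if config.censor_rate > 0:
            mu_c = (config.censor_rate / (1 - config.censor_rate)) * config.baseline_hazard * hazard_scale
            censor_time = rng.exponential(1.0 / mu_c, size=len(samples))
            time = np.minimum(event_time, censor_time)
            event = (event_time <= censor_time).astype(int)
        else:
            time, event = event_time, np.ones(len(samples), dtype=int)
        clinical[endpoint] = SurvivalData(
            time=pd.Series(time, index=samples, name="time"),
            event=pd.Series(event, index=samples, name="event"),
            endpoint=endpoint,
        )

    # proportional odds over CR < PR < SD < PD with activation pushing toward PD
    cuts = np.array([-1.5, 0.0, 1.5])  # latent thresholds CR|PR, PR|SD, SD|PD
    eta = config.response_logit_slope * act
    latent = eta + rng.logistic(size=len(samples))
    labels = np.array(["Complete Response", "Partial Response", "Stable Disease", "Progressive Disease"])
    recist = labels[np.searchsorted(cuts, latent)]
    rows = [
        {"sample_id": s, "therapy": "therapy_A", "line": int(rng.integers(1, 4)), "recist": r}
        for s, r in zip(samples, recist)
    ]
    # a few later-line records that the line-1-3 filter must ignore
    for s in samples[: max(1, len(samples) // 20)]:
        rows.append({"sample_id": s, "therapy": "therapy_A", "line": int(rng.integers(4, 9)), "recist": "Complete Response"})
    response = pd.DataFrame(rows)
    return clinical, response
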
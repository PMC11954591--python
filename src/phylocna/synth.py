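"""Synthetic data generation with known ground truth.

Generates pure-birth trees, tree-correlated overdispersed copy-number
matrices (latent Brownian motion mapped through ``exp`` to a Poisson mean),
gene-set definitions with planted linear effects on chosen phenotypes, and
binomially sampled necropsy phenotypes — everything needed to exercise the
screens, nulls, and enrichment stages end to end without external data.

Also ships :func:`nr_tgfb_fixture`, the bundled per-gene PGLS worked-example
table for the negative-regulation-of-TGF-beta-production gene set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (
    CopyNumberMatrix,
    GeneSetCollection,
    PhenotypeTable,
    derive_cancer_phenotypes,
)
from .tree import Phylogeny, bm_covariance, lambda_transform, parse_newick

__all__ = [
    "PlantedSet",
    "SimulationConfig",
    "generate_tree",
    "simulate_copy_numbers",
    "simulate_phenotypes",
    "simulate_dataset",
    "nr_tgfb_fixture",
]


@dataclass
class PlantedSet:
    """A gene set with a planted per-aggregate-unit effect on one phenotype.

    ``effect`` is the slope of the phenotype (on its model scale: log for
    body size / longevity, logit for rates) per unit of aggregate copy
    number.
    """

    name: str
    size: int
    phenotype: str | None = None
    effect: float = 0.0


@dataclass
class SimulationConfig:
    n_species: int
    n_orthogroups: int
    seed: int
    sets: list[PlantedSet] = field(default_factory=list)
    lambda_true: float = 1.0
    dispersion: float = 0.5
    base_log_mean: float = 0.7
    base_log_sd: float = 0.8
    annotated_fraction: float = 0.9
    necropsy_range: tuple[int, int] = (20, 80)
    mean_neoplasia_prevalence: float = 0.3
    mean_malignancy_rate: float = 0.4
    #: plant effects on the observed aggregate ("counts") or on the latent
    #: expected dosage ("latent"); the latter spreads signal across the set
    #: so no single gene's sampling noise carries it
    planted_on: str = "counts"

    def __post_init__(self):
        if self.n_species < 4:
            raise ValueError("n_species must be >= 4")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for s in self.sets:
            if not np.isfinite(s.effect):
                raise ValueError(f"non-finite effect for set {s.name!r}")


# ---------------------------------------------------------------------------
# tree
# ---------------------------------------------------------------------------


def generate_tree(n_species: int, seed: int) -> Phylogeny:
    """Pure-birth (Yule) tree with ``n_species`` tips rescaled to unit
    height; deterministic given the seed.

    The root splits at time zero into two lineages; thereafter a uniformly
    chosen lineage splits after an Exp(1/k) wait, until ``n_species`` tips
    exist, plus a final Exp(1/n) stretch to the present.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(seed)

    def new_node(t: float) -> dict:
        return {"t": t, "t_split": None, "children": [], "label": None}

    root = new_node(0.0)
    root["t_split"] = 0.0
    active = []
    for _ in range(2):
        child = new_node(0.0)
        root["children"].append(child)
        active.append(child)
    t = 0.0
    while len(active) < n_species:
        k = len(active)
        t += rng.exponential(1.0 / k)
        parent = active.pop(int(rng.integers(k)))
        parent["t_split"] = t
        for _ in range(2):
            child = new_node(t)
            parent["children"].append(child)
            active.append(child)
    T = t + rng.exponential(1.0 / n_species)
    for i, leaf in enumerate(active):
        leaf["label"] = f"sp{i + 1:03d}"

    def newick(node: dict) -> str:
        if not node["children"]:
            return f"{node['label']}:{(T - node['t']) / T:.17g}"
        inner = ",".join(newick(c) for c in node["children"])
        return f"({inner}):{(node['t_split'] - node['t']) / T:.17g}"

    text = "(" + ",".join(newick(c) for c in root["children"]) + ");"
    return parse_newick(text)


# ---------------------------------------------------------------------------
# copy numbers
# ---------------------------------------------------------------------------


def simulate_copy_numbers(
    tree: Phylogeny,
    n_orthogroups: int,
    dispersion: float = 0.5,
    seed: int = 0,
    annotated_fraction: float = 0.9,
    base_log_mean: float = 0.7,
    base_log_sd: float = 0.8,
    return_latent: bool = False,
):
    """Tree-correlated overdispersed copy numbers.

    Per orthogroup: a base log-mean is drawn from a normal with sd
    ``base_log_sd`` (long-tailed on the count scale, so cross-orthogroup
    variance heterogeneity supports variance-decile matching); a latent BM
    with rate ``dispersion**2`` evolves on the tree; counts are Poisson with
    mean ``exp(base + BM)``.  A fraction of orthogroups receive synthetic
    reference-gene symbols ``g<No>``.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    rng = np.random.default_rng(seed)
    V = bm_covariance(tree)
    n = len(V)
    L = np.linalg.cholesky(
        V.values + 1e-12 * np.trace(V.values) * np.eye(n)
    )
    base = rng.normal(base_log_mean, base_log_sd, size=n_orthogroups)
    z = rng.standard_normal((n_orthogroups, n))
    latent = base[:, None] + dispersion * (z @ L.T)
    mu = np.exp(np.clip(latent, -20, 8))
    counts = rng.poisson(mu)
    ids = [f"OG{i + 1:06d}" for i in range(n_orthogroups)]
    df = pd.DataFrame(counts, index=ids, columns=list(V.labels))
    annotated = rng.random(n_orthogroups) < annotated_fraction
    annotation = {
        og: (f"g{i + 1:05d}",)
        for i, og in enumerate(ids)
        if annotated[i]
    }
    M = CopyNumberMatrix(counts=df, annotation=annotation)
    if return_latent:
        mu_df = pd.DataFrame(mu, index=ids, columns=list(V.labels))
        return M, mu_df
    return M


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _structured_noise(V, lambda_true, sd, rng, n_draws=1):
    from .tree import CovarianceMatrix, sample_mvn_bm

    Vlam = lambda_transform(CovarianceMatrix(V.labels, V.values), lambda_true)
    scale = sd**2 / float(np.mean(np.diag(V.values)))
    return sample_mvn_bm(Vlam.values, scale, 0.0, rng, n_draws)


def simulate_phenotypes(
    tree: Phylogeny,
    config: SimulationConfig,
    aggregates: dict[str, pd.Series] | None = None,
) -> PhenotypeTable:
    """Phenotypes with phylogenetic structure and planted aggregate effects.

    Log body size and log longevity are generated positively correlated via
    a shared lambda-structured component.  Cancer phenotypes arise from
    latent lambda-structured liabilities passed through a logistic link,
    then sampled: ``n_neoplasia ~ Binomial(n_necropsies, prevalence)`` and
    ``n_malignant ~ Binomial(n_neoplasia, rate)`` — so the count invariants
    hold by construction.  Each planted set adds ``effect * aggregate`` to
    its phenotype on the model scale.
    """
    rng = np.random.default_rng(config.seed + 1)
    V = bm_covariance(tree)
    species = list(V.labels)
    n = len(species)
    lam = config.lambda_true

    z_shared, z_body, z_long, z_neo, z_mal = _structured_noise(
        V, lam, 1.0, rng, 5
    )

    effects = {name: np.zeros(n) for name in (
        "body_size", "longevity", "neoplasia_prev", "malignancy_rate",
        "malignancy_prev",
    )}
    if aggregates:
        for planted in config.sets:
            if planted.phenotype is None or planted.effect == 0:
                continue
            agg = aggregates[planted.name].reindex(species).to_numpy(float)
            # centered so the planted slope shifts covariance, not the trait
            # mean (which would saturate the logistic link for rates)
            effects[planted.phenotype] += planted.effect * (agg - agg.mean())

    log_body = 10.0 + 1.5 * z_shared + 0.8 * z_body + effects["body_size"]
    log_long = 4.5 + 0.5 * z_shared + 0.4 * z_long + effects["longevity"]

    import scipy.special as sps

    lat_neo = sps.logit(config.mean_neoplasia_prevalence) + 0.8 * z_neo
    lat_neo = lat_neo + effects["neoplasia_prev"]
    lat_mal = sps.logit(config.mean_malignancy_rate) + 0.8 * z_mal
    lat_mal = lat_mal + effects["malignancy_rate"]
    prevalence = _expit(lat_neo)
    rate = _expit(lat_mal)

    lo, hi = config.necropsy_range
    n_necropsies = rng.integers(lo, hi + 1, size=n)
    n_neoplasia = rng.binomial(n_necropsies, prevalence)
    n_malignant = rng.binomial(n_neoplasia, rate)

    raw = pd.DataFrame(
        {
            "body_size_g": np.exp(log_body),
            "longevity_months": np.exp(log_long),
            "n_necropsies": n_necropsies,
            "n_neoplasia": n_neoplasia,
            "n_malignant": n_malignant,
        },
        index=pd.Index(species, name="species"),
    )
    return derive_cancer_phenotypes(raw)


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------


def simulate_dataset(config: SimulationConfig) -> dict:
    """Generate a coherent dataset: tree, counts, gene sets (planted sets
    drawn from annotated orthogroups), aggregates, and phenotypes.

    Returns a dict with keys ``tree``, ``counts``, ``gene_sets``,
    ``mapping``, ``aggregates``, ``phenotypes``, ``truth``.
    """
    tree = generate_tree(config.n_species, config.seed)
    M, latent_mu = simulate_copy_numbers(
        tree,
        config.n_orthogroups,
        dispersion=config.dispersion,
        seed=config.seed + 10,
        annotated_fraction=config.annotated_fraction,
        base_log_mean=config.base_log_mean,
        base_log_sd=config.base_log_sd,
        return_latent=True,
    )
    rng = np.random.default_rng(config.seed + 20)
    annotated = [og for og in M.orthogroup_ids if M.annotation.get(og)]
    mapping: dict[str, list[str]] = {}
    gene_sets: dict[str, list[str]] = {}
    available = list(annotated)
    for planted in config.sets:
        if planted.size > len(available):
            raise ValueError(
                f"not enough annotated orthogroups for set {planted.name!r}"
            )
        idx = rng.choice(len(available), size=planted.size, replace=False)
        chosen = [available[i] for i in sorted(idx)]
        for og in chosen:
            available.remove(og)
        mapping[planted.name] = chosen
        gene_sets[planted.name] = [M.annotation[og][0] for og in chosen]
    aggregates = {
        name: M.counts.loc[ogs].sum(axis=0) for name, ogs in mapping.items()
    }
    if config.planted_on == "latent":
        effect_aggregates = {
            name: latent_mu.loc[ogs].sum(axis=0)
            for name, ogs in mapping.items()
        }
    elif config.planted_on == "counts":
        effect_aggregates = aggregates
    else:
        raise ValueError(
            f"planted_on must be 'counts' or 'latent', got {config.planted_on!r}"
        )
    phenotypes = simulate_phenotypes(tree, config, effect_aggregates)
    truth = {
        "planted": [
            {
                "name": s.name,
                "orthogroups": mapping[s.name],
                "phenotype": s.phenotype,
                "effect": s.effect,
            }
            for s in config.sets
        ],
        "lambda_true": config.lambda_true,
        "seed": config.seed,
    }
    sets = (
        GeneSetCollection(sets=gene_sets, source="synthetic")
        if gene_sets
        else None
    )
    return {
        "tree": tree,
        "counts": M,
        "gene_sets": sets,
        "mapping": mapping,
        "aggregates": aggregates,
        "phenotypes": phenotypes,
        "truth": truth,
    }


# ---------------------------------------------------------------------------
# bundled worked-example table
# ---------------------------------------------------------------------------

_NR_TGFB_ROWS = [
    # gene, estimate, se, t, p, p_adjusted
    ("Cd24a", -0.046, 0.029, -1.5, 0.11, 0.55),
    ("Cd2ap", -0.067, 0.032, -2.0, 0.039, 0.41),
    ("Cdh3", -0.058, 0.036, -1.6, 0.11, 0.54),
    ("Fbln1", -0.082, 0.035, -2.3, 0.021, 0.36),
    ("Fn1", -0.011, 0.0049, -2.2, 0.025, 0.36),
    ("Furin", -0.047, 0.015, -3.0, 0.0034, 0.11),
    ("Gata6", -0.033, 0.014, -2.2, 0.024, 0.21),
    ("Il13", 0.037, 0.041, 0.89, 0.37, 0.77),
    ("Laptm4b", -0.015, 0.043, -0.36, 0.71, 0.97),
    ("Met", -0.091, 0.025, -3.6, 0.00041, 0.12),
    ("Tsku", -0.049, 0.013, -3.7, 0.0003, 0.063),
    ("Tyrobp", -0.097, 0.041, -2.3, 0.019, 0.36),
]


def nr_tgfb_fixture() -> pd.DataFrame:
    """Bundled per-gene PGLS results (vs. malignancy rate) for the
    negative-regulation-of-TGF-beta-production gene set, used as a worked
    example for directionality counting."""
    return pd.DataFrame(
        _NR_TGFB_ROWS,
        columns=["gene", "estimate", "se", "t", "p", "p_adjusted"],
    )
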
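"""Simulation-based robustness nulls for an aggregate gene-set association.

Two nulls are provided:

* :func:`variance_matched_set_null` — resample replicate gene sets whose
  per-orthogroup cross-species copy-number variance matches the target set
  (same-decile matching with adjacent-decile fallback), refit the gene-set
  PGLS on each replicate aggregate, and compare p-values.
* :func:`bm_phenotype_null` — keep the observed aggregate fixed, replace the
  phenotype with Brownian-motion draws on the tree, and refit.

Both return a :class:`NullDistribution` of replicate p-values with the
observed p, summarized by :func:`empirical_p`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CopyNumberMatrix, PhenotypeTable
from .pgls import LambdaProfiler
from .screens import _profiled_fit, _screen_workspace, model_inputs
from .tree import Phylogeny

__all__ = [
    "NullDistribution",
    "variance_matched_set_null",
    "bm_phenotype_null",
    "empirical_p",
]


@dataclass
class NullDistribution:
    """Replicate p-values from a simulation null plus the observed p."""

    replicate_pvalues: np.ndarray
    observed_p: float
    n_reps: int
    seed: int
    kind: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.replicate_pvalues = np.asarray(self.replicate_pvalues, dtype=float)
        if len(self.replicate_pvalues) != self.n_reps:
            raise ValueError(
                f"expected {self.n_reps} replicate p-values, got "
                f"{len(self.replicate_pvalues)}"
            )
        if np.any((self.replicate_pvalues < 0) | (self.replicate_pvalues > 1)):
            raise ValueError("replicate p-values must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replicate": np.arange(1, self.n_reps + 1),
                "p": self.replicate_pvalues,
            }
        )


def empirical_p(null: NullDistribution) -> float:
    """Empirical p with the add-one convention: (r + 1) / (n_reps + 1)
    where r counts replicates with p <= observed."""
    if null.n_reps < 1:
        raise ValueError("need at least one replicate")
    r = int(np.sum(null.replicate_pvalues <= null.observed_p))
    return (r + 1) / (null.n_reps + 1)


def _fit_setup(
    phenotypes: PhenotypeTable,
    phenotype_name: str,
    tree: Phylogeny,
    covariate: pd.Series | None,
):
    """Shared model scaffolding: aligned response, covariate block, weights,
    and a cached lambda profiler for the species actually modeled."""
    y, covs, weights = model_inputs(
        phenotypes, phenotype_name, include_paired_covariate=False
    )
    if covariate is not None:
        covs = covs.join(
            pd.Series(covariate, dtype=float).rename("covariate"), how="inner"
        )
        common = covs.dropna().index.intersection(y.index)
        y, covs = y.loc[common], covs.loc[common]
    species, prof = _screen_workspace(tree, y.index, weights)
    yv = y.loc[species].to_numpy()
    C = covs.loc[species].to_numpy()
    return species, prof, yv, C, list(covs.columns)


def _aggregate_p(prof, ystar, x, C, cov_names) -> float:
    X = np.column_stack([np.ones(len(x)), x, C])
    names = ["intercept", "aggregate_count", *cov_names]
    fit = _profiled_fit(prof, ystar, X, names)
    return float(fit.pvalues["aggregate_count"])


def variance_matched_set_null(
    target_orthogroups,
    M: CopyNumberMatrix,
    phenotypes: PhenotypeTable,
    tree: Phylogeny,
    phenotype_name: str = "malignancy_rate",
    covariate: pd.Series | None = None,
    n_reps: int = 1000,
    seed: int = 0,
    n_deciles: int = 10,
    keep_sets: bool = False,
) -> NullDistribution:
    """Null over random gene sets with variance-matched orthogroups.

    Per replicate, each target orthogroup is replaced (without replacement
    within the replicate) by a random orthogroup from the same
    cross-species-variance decile of the filtered matrix; deciles with no
    candidates fall back to adjacent deciles with a warning.  The target's
    own orthogroups are excluded from the candidate pool.
    """
    target = list(dict.fromkeys(target_orthogroups))
    missing = [og for og in target if og not in M.counts.index]
    if missing:
        raise KeyError(f"target orthogroups not in matrix: {missing}")
    pool = M.counts.index.difference(target)
    if len(pool) < 10 * len(target):
        raise ValueError(
            f"candidate pool ({len(pool)}) smaller than 10x set size "
            f"({len(target)})"
        )

    species, prof, yv, C, cov_names = _fit_setup(
        phenotypes, phenotype_name, tree, covariate
    )
    ystar = prof.transform(yv)
    counts = M.counts[species]

    variances = counts.var(axis=1, ddof=1)
    edges = np.quantile(
        variances.to_numpy(), np.linspace(0, 1, n_deciles + 1)
    )
    edges[0], edges[-1] = -np.inf, np.inf

    def decile_of(v: float) -> int:
        return int(np.clip(np.searchsorted(edges, v, side="right") - 1, 0,
                           n_deciles - 1))

    pool_by_decile: dict[int, np.ndarray] = {}
    pool_deciles = np.array([decile_of(variances[og]) for og in pool])
    pool_arr = np.asarray(pool)
    for d in range(n_deciles):
        pool_by_decile[d] = pool_arr[pool_deciles == d]

    target_deciles = [decile_of(variances[og]) for og in target]

    def candidates_for(d: int) -> np.ndarray:
        cand = pool_by_decile[d]
        width = 1
        while len(cand) == 0 and width < n_deciles:
            lo, hi = max(0, d - width), min(n_deciles - 1, d + width)
            cand = np.concatenate(
                [pool_by_decile[k] for k in range(lo, hi + 1)]
            )
            warnings.warn(
                f"variance decile {d} empty; widened to [{lo}, {hi}]",
                UserWarning,
                stacklevel=3,
            )
            width += 1
        if len(cand) == 0:
            raise ValueError(f"no candidate orthogroups for decile {d}")
        return cand

    cand_by_decile = {d: candidates_for(d) for d in set(target_deciles)}
    rng = np.random.default_rng(seed)
    count_rows = {og: counts.loc[og].to_numpy(dtype=float) for og in pool}

    # observed p for the target set itself
    x_obs = counts.loc[target].sum(axis=0).to_numpy(dtype=float)
    observed_p = _aggregate_p(prof, ystar, x_obs, C, cov_names)

    reps = np.empty(n_reps)
    replicate_sets: list[list[str]] = []
    for r in range(n_reps):
        chosen: list[str] = []
        used: set[str] = set()
        for d in target_deciles:
            cand = cand_by_decile[d]
            og = cand[rng.integers(len(cand))]
            tries = 0
            while og in used:
                og = cand[rng.integers(len(cand))]
                tries += 1
                if tries > 1000:  # decile nearly exhausted
                    remaining = [c for c in cand if c not in used]
                    if not remaining:
                        raise ValueError(
                            f"decile {d} exhausted during replicate sampling"
                        )
                    og = remaining[int(rng.integers(len(remaining)))]
                    break
            used.add(og)
            chosen.append(og)
        x = np.sum([count_rows[og] for og in chosen], axis=0)
        reps[r] = _aggregate_p(prof, ystar, x, C, cov_names)
        if keep_sets:
            replicate_sets.append(chosen)
    meta = {"target_size": len(target), "n_species": len(species)}
    if keep_sets:
        meta["replicate_sets"] = replicate_sets
    return NullDistribution(
        replicate_pvalues=reps,
        observed_p=observed_p,
        n_reps=n_reps,
        seed=seed,
        kind="variance_matched_sets",
        meta=meta,
    )


def bm_phenotype_null(
    aggregate: pd.Series,
    tree: Phylogeny,
    covariate: pd.Series | None = None,
    weights: pd.Series | None = None,
    observed_phenotype: pd.Series | None = None,
    n_reps: int = 1000,
    seed: int = 0,
) -> NullDistribution:
    """Null over Brownian-motion phenotypes with the aggregate held fixed.

    Each replicate draws a BM phenotype on the tree (sigma2 scaled to unit
    tip variance at the mean depth, root 0 — the PGLS p is invariant to this
    scale), fits the same weighted PGLS of phenotype on aggregate (+
    covariate), and records the aggregate-term p.  When
    ``observed_phenotype`` is given its p populates ``observed_p``.
    """
    from .tree import bm_covariance, sample_mvn_bm
    from .tree import CovarianceMatrix as _CM

    agg = pd.Series(aggregate, dtype=float).dropna()
    mapping = tree.match_tips(agg.index)
    species = [s for s in agg.index if s in mapping]
    if len(species) < len(agg):
        missing = sorted(set(agg.index) - set(species))
        raise KeyError(f"aggregate species not in tree: {missing}")
    V = bm_covariance(tree).subset([mapping[s] for s in species])
    Vloc = _CM(tuple(species), V.values)

    w = None
    if weights is not None:
        w = pd.Series(weights, dtype=float).reindex(species).to_numpy()
        if np.isnan(w).any():
            raise ValueError("weights missing for some species")
    prof = LambdaProfiler(Vloc, w)

    x = agg.loc[species].to_numpy()
    cols = [np.ones(len(species)), x]
    names = ["intercept", "aggregate_count"]
    if covariate is not None:
        cv = pd.Series(covariate, dtype=float).reindex(species)
        if cv.isna().any():
            raise ValueError("covariate missing for some species")
        cols.append(cv.to_numpy())
        names.append("covariate")
    X = np.column_stack(cols)
    Xstar = prof.transform(X)

    sigma2 = 1.0 / float(np.mean(np.diag(Vloc.values)))
    rng = np.random.default_rng(seed)
    draws = sample_mvn_bm(Vloc.values, sigma2, 0.0, rng, n_reps)

    def p_for(yv: np.ndarray) -> float:
        ystar = prof.transform(yv)
        fit = _profiled_fit(prof, ystar, X, names)
        return float(fit.pvalues["aggregate_count"])

    reps = np.array([p_for(draws[r]) for r in range(n_reps)])
    observed_p = np.nan
    if observed_phenotype is not None:
        yobs = pd.Series(observed_phenotype, dtype=float).reindex(species)
        if yobs.isna().any():
            raise ValueError("observed phenotype missing for some species")
        observed_p = p_for(yobs.to_numpy())
    return NullDistribution(
        replicate_pvalues=reps,
        observed_p=observed_p,
        n_reps=n_reps,
        seed=seed,
        kind="bm_phenotype",
        meta={"n_species": len(species), "sigma2": sigma2},
    )
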
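"""Association screens: per-orthogroup PGLS, aggregate gene-set PGLS,
multiple-testing adjustment, and the reversed Poisson PGLM check.

Model conventions
-----------------
* Responses: ``body_size`` and ``longevity`` enter log-transformed; the
  cancer phenotypes (``neoplasia_prev``, ``malignancy_prev``,
  ``malignancy_rate``) enter on their natural [0, 1] scale and are weighted
  by the square root of the necropsy count.
* Covariates: every model includes a proteome-size covariate; body-size
  models include log longevity and vice versa.  Copy-number predictors enter
  as raw integer counts.
* Each model profiles its own Pagel's lambda; Benjamini-Hochberg adjustment
  is applied per phenotype per screen, over the testable rows only.
  Untestable rows (singular designs) are kept in the output with
  ``testable=False``.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .data import CopyNumberMatrix, PhenotypeTable, proteome_covariate
from .pgls import DesignSpec, LambdaProfiler, RankError, fit_poisson_pglm
from .tree import CovarianceMatrix, Phylogeny, bm_covariance

__all__ = [
    "PHENOTYPES",
    "adjust_pvalues",
    "model_inputs",
    "screen_orthogroups",
    "screen_gene_sets",
    "reverse_pglm_check",
    "table1_directionality",
]

logger = logging.getLogger(__name__)

#: phenotype name -> (source column, log-transform?, weighted?)
PHENOTYPES: dict[str, tuple[str, bool, bool]] = {
    "body_size": ("body_size_g", True, False),
    "longevity": ("longevity_months", True, False),
    "neoplasia_prev": ("neoplasia_prevalence", False, True),
    "malignancy_prev": ("malignancy_prevalence", False, True),
    "malignancy_rate": ("malignancy_rate", False, True),
}

_PAIRED_COVARIATE = {
    "body_size": ("longevity_months", "log_longevity"),
    "longevity": ("body_size_g", "log_body_size"),
}


# ---------------------------------------------------------------------------
# p-value adjustment
# ---------------------------------------------------------------------------


def adjust_pvalues(p, method: str = "BH") -> np.ndarray:
    """Adjust p-values for multiple testing.

    ``BH`` is the Benjamini-Hochberg step-up FDR adjustment, ``bonferroni``
    is ``min(1, m*p)``, and ``hommel`` is the closed-testing (Simes-based)
    adjustment.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    if method == "bonferroni":
        return np.minimum(1.0, m * p)
    if method == "BH":
        order = np.argsort(p, kind="mergesort")
        ranked = p[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.minimum(adj, 1.0)
        out = np.empty(m)
        out[order] = adj
        return out
    if method == "hommel":
        return _hommel(p)
    raise ValueError(f"unknown adjustment method {method!r}")


def _hommel(p: np.ndarray) -> np.ndarray:
    """Hommel adjustment via the standard O(m^2) algorithm (equivalent to
    exhaustive Simes closed testing)."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ps = p[order]
    q = np.full(m, np.min(m * ps / np.arange(1, m + 1)))
    pa = q.copy()
    for k in range(m - 1, 1, -1):
        i1 = np.arange(m - k + 1)
        i2 = np.arange(m - k + 1, m)
        q1 = np.min(k * ps[i2] / np.arange(2, k + 1))
        q[i1] = np.minimum(k * ps[i1], q1)
        q[i2] = q[m - k]
        pa = np.maximum(pa, q)
    adj = np.minimum(np.maximum(pa, ps), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# model assembly
# ---------------------------------------------------------------------------


def model_inputs(
    phenotypes: PhenotypeTable,
    phenotype_name: str,
    include_paired_covariate: bool = True,
) -> tuple[pd.Series, pd.DataFrame, pd.Series | None]:
    """Response, shared covariates, and weights for one phenotype model.

    Species with a missing response (e.g. malignancy rate with zero
    neoplasms) or missing covariate are dropped listwise.
    """
    if phenotype_name not in PHENOTYPES:
        raise KeyError(
            f"unknown phenotype {phenotype_name!r}; expected one of "
            f"{sorted(PHENOTYPES)}"
        )
    column, log_response, weighted = PHENOTYPES[phenotype_name]
    df = phenotypes.table
    y = df[column].astype(float)
    if log_response:
        y = np.log(y)
    y.name = phenotype_name
    covs = pd.DataFrame(index=df.index)
    if include_paired_covariate and phenotype_name in _PAIRED_COVARIATE:
        src, name = _PAIRED_COVARIATE[phenotype_name]
        covs[name] = np.log(df[src].astype(float))
    keep = y.notna() & covs.notna().all(axis=1)
    y = y[keep]
    covs = covs.loc[keep]
    weights = None
    if weighted:
        weights = df.loc[keep, "weight"].astype(float)
    return y, covs, weights


def _screen_workspace(
    tree: Phylogeny, species: pd.Index, weights: pd.Series | None
):
    mapping = tree.match_tips(species)
    keep = [s for s in species if s in mapping]
    V = bm_covariance(tree).subset([mapping[s] for s in keep])
    w = None if weights is None else weights.loc[keep].to_numpy()
    return keep, LambdaProfiler(CovarianceMatrix(tuple(keep), V.values), w)


def _screen(
    units: Mapping[str, pd.Series],
    y: pd.Series,
    covs: pd.DataFrame,
    weights: pd.Series | None,
    tree: Phylogeny,
    phenotype_name: str,
    unit_col: str,
) -> pd.DataFrame:
    """Shared driver: one lambda-PGLS per unit (orthogroup or gene set),
    with the unit's values as the tested predictor."""
    species, prof = _screen_workspace(tree, y.index, weights)
    if not species:
        raise ValueError("no species shared between phenotype table and tree")
    yv = y.loc[species].to_numpy()
    C = covs.loc[species].to_numpy()
    cov_names = list(covs.columns)
    ystar = prof.transform(yv)
    rows = []
    for unit_id, values in units.items():
        x = values.reindex(species).to_numpy(dtype=float)
        if np.isnan(x).any():
            rows.append(_untestable_row(unit_id, phenotype_name, "missing values"))
            continue
        X = np.column_stack([np.ones(len(yv)), x, C])
        names = ["intercept", unit_col, *cov_names]
        try:
            fit = _profiled_fit(prof, ystar, X, names)
        except (RankError, np.linalg.LinAlgError, ValueError) as exc:
            logger.debug("unit %s untestable: %s", unit_id, exc)
            rows.append(_untestable_row(unit_id, phenotype_name, str(exc)))
            continue
        logger.debug(
            "unit %s: lambda_hat=%.4f loglik=%.3f", unit_id, fit.lambda_hat,
            fit.loglik,
        )
        rows.append(
            {
                "unit_id": unit_id,
                "phenotype": phenotype_name,
                "estimate": fit.beta[unit_col],
                "se": fit.se[unit_col],
                "t": fit.tstats[unit_col],
                "p": fit.pvalues[unit_col],
                "lambda_hat": fit.lambda_hat,
                "n_species": fit.n,
                "testable": True,
                "note": "",
            }
        )
    table = pd.DataFrame(rows)
    return _finalize_screen(table)


def _profiled_fit(prof, ystar, X, names):
    from .pgls import PGLSFit  # local import to keep module load light

    _rank_check_columns(X, names)
    Xstar = prof.transform(X)

    from scipy.optimize import minimize_scalar

    def neg_ll(lam):
        return -prof.profile_loglik(ystar, Xstar, lam)

    res = minimize_scalar(
        neg_ll, bounds=(0.0, 1.0), method="bounded", options={"xatol": 1e-6}
    )
    candidates = [(0.0, -neg_ll(0.0)), (1.0, -neg_ll(1.0))]
    if np.isfinite(res.fun):
        candidates.append((float(res.x), -float(res.fun)))
    best_lam, _ = max(
        candidates, key=lambda c: (round(c[1] / 1e-6), c[0] in (0.0, 1.0))
    )
    return prof.fit_at(ystar, Xstar, best_lam, names)


def _rank_check_columns(X, names):
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise RankError(
            f"design matrix is rank deficient; columns: {names}"
        )


def _untestable_row(unit_id: str, phenotype_name: str, note: str) -> dict:
    return {
        "unit_id": unit_id,
        "phenotype": phenotype_name,
        "estimate": np.nan,
        "se": np.nan,
        "t": np.nan,
        "p": np.nan,
        "lambda_hat": np.nan,
        "n_species": 0,
        "testable": False,
        "note": note,
    }


def _finalize_screen(table: pd.DataFrame) -> pd.DataFrame:
    table = table.copy()
    table["p_adjusted"] = np.nan
    mask = table["testable"].to_numpy(dtype=bool)
    if mask.any():
        table.loc[mask, "p_adjusted"] = adjust_pvalues(
            table.loc[mask, "p"].to_numpy(), "BH"
        )
    table = table.sort_values(
        ["p", "unit_id"], na_position="last", kind="mergesort"
    ).reset_index(drop=True)
    cols = [
        "unit_id", "phenotype", "estimate", "se", "t", "p", "p_adjusted",
        "lambda_hat", "n_species", "testable", "note",
    ]
    return table[cols]


# ---------------------------------------------------------------------------
# public screens
# ---------------------------------------------------------------------------


def screen_orthogroups(
    M: CopyNumberMatrix,
    phenotypes: PhenotypeTable,
    phenotype_name: str,
    tree: Phylogeny,
    include_paired_covariate: bool = True,
    proteome: pd.Series | None = None,
) -> pd.DataFrame:
    """One lambda-PGLS per orthogroup: phenotype ~ copy number + covariates.

    ``M`` should already be filtered (see
    :func:`phylocna.data.filter_orthogroups`).  Cancer phenotypes default to
    the proteome covariate only; body size / longevity additionally include
    the paired life-history covariate.  ``proteome`` overrides the
    proteome-size covariate (by default the column sums of ``M``).
    """
    paired = include_paired_covariate and phenotype_name in _PAIRED_COVARIATE
    y, covs, weights = model_inputs(
        phenotypes, phenotype_name, include_paired_covariate=paired
    )
    if proteome is None:
        proteome = proteome_covariate(M, "all")
    proteome = proteome.astype(float)
    covs = covs.join(proteome.rename("proteome_size"), how="inner")
    common = covs.dropna().index.intersection(y.index)
    y, covs = y.loc[common], covs.loc[common]
    units = {og: M.counts.loc[og].astype(float) for og in M.counts.index}
    return _screen(
        units, y, covs, weights, tree, phenotype_name, unit_col="copy_number"
    )


def screen_gene_sets(
    aggregates: Mapping[str, pd.Series],
    phenotypes: PhenotypeTable,
    phenotype_name: str,
    tree: Phylogeny,
    covariate: pd.Series,
    include_paired_covariate: bool = True,
    familywise: bool = True,
) -> pd.DataFrame:
    """One lambda-PGLS per gene set using its aggregate copy number as the
    predictor and the annotated-proteome covariate.

    Adds ``p_bonferroni`` and ``p_hommel`` columns alongside the BH
    adjustment when ``familywise`` is True.
    """
    paired = include_paired_covariate and phenotype_name in _PAIRED_COVARIATE
    y, covs, weights = model_inputs(
        phenotypes, phenotype_name, include_paired_covariate=paired
    )
    covs = covs.join(
        covariate.rename("proteome_annotated").astype(float), how="inner"
    )
    common = covs.dropna().index.intersection(y.index)
    y, covs = y.loc[common], covs.loc[common]
    table = _screen(
        dict(aggregates), y, covs, weights, tree, phenotype_name,
        unit_col="aggregate_count",
    )
    if familywise:
        mask = table["testable"].to_numpy(dtype=bool)
        for method, col in (("bonferroni", "p_bonferroni"), ("hommel", "p_hommel")):
            table[col] = np.nan
            if mask.any():
                table.loc[mask, col] = adjust_pvalues(
                    table.loc[mask, "p"].to_numpy(), method
                )
    return table


def reverse_pglm_check(
    set_names,
    aggregates: Mapping[str, pd.Series],
    phenotypes: PhenotypeTable,
    tree: Phylogeny,
    covariate: pd.Series | None = None,
) -> pd.DataFrame:
    """Reversed model: aggregate count ~ malignancy rate (+ covariate) as a
    Poisson phylogenetic GLM; reports the rate-term p per set."""
    rows = []
    rate = phenotypes.table["malignancy_rate"]
    for name in set_names:
        agg = aggregates[name]
        df = pd.DataFrame(
            {"count": agg, "malignancy_rate": rate.reindex(agg.index)}
        )
        if covariate is not None:
            df["proteome_annotated"] = covariate.reindex(agg.index).astype(float)
        df = df.dropna()
        counts = df["count"].round().astype(int)
        predictors = df.drop(columns="count")
        fit = fit_poisson_pglm(counts, predictors, tree)
        rows.append(
            {
                "unit_id": name,
                "phenotype": "malignancy_rate",
                "estimate": fit.beta["malignancy_rate"],
                "se": fit.se["malignancy_rate"],
                "t": fit.beta["malignancy_rate"] / fit.se["malignancy_rate"]
                if fit.se["malignancy_rate"] > 0 else np.nan,
                "p": fit.pvalues["malignancy_rate"],
                "lambda_hat": fit.lambda_work,
                "n_species": fit.n,
                "testable": True,
                "note": fit.method,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "unit_id", "phenotype", "estimate", "se", "t", "p",
                "p_adjusted", "lambda_hat", "n_species", "testable", "note",
            ]
        )
    return _finalize_screen(pd.DataFrame(rows))


def table1_directionality(fixture: pd.DataFrame) -> int:
    """Count rows of a per-gene PGLS table with a negative coefficient."""
    if "estimate" not in fixture.columns:
        raise ValueError("fixture table requires an 'estimate' column")
    return int((fixture["estimate"] < 0).sum())
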